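"""Shared fixtures: synthetic study bundles and a full pipeline run."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from droughtnc.pipeline import PipelineConfig, run_pipeline
from droughtnc.simulate import generate_bundle

#: seed used for all session-wide synthetic fixtures
SESSION_SEED = 11


@pytest.fixture(scope="session")
def default_bundle():
    """A full-size synthetic study with the default planted proportions."""
    return generate_bundle(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced study for fast end-to-end runs."""
    return generate_bundle(
        seed=SESSION_SEED,
        n_coding=24,
        n_premirna=10,
        n_lncrna=10,
        n_inducible=3,
        n_repressible=4,
        n_lnc_up=4,
        n_lnc_down=5,
        n_sites=6,
        n_guiding_mirnas=4,
        lncrna_category_counts={
            "antisense": 4,
            "bidirectional": 2,
            "intergenic": 2,
            "sense": 1,
            "intronic": 1,
        },
    )


@pytest.fixture(scope="session")
def pipeline_run(default_bundle, tmp_path_factory):
    """Write the default bundle, run the full pipeline once, return everything."""
    root = tmp_path_factory.mktemp("pipeline")
    paths = default_bundle.write(root / "data")
    config = PipelineConfig.from_yaml(paths["config"], outdir=str(root / "out"))
    summary = run_pipeline(config)
    return {
        "bundle": default_bundle,
        "paths": paths,
        "config": config,
        "summary": summary,
        "outdir": root / "out",
    }
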