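"""Determinism, planted-truth consistency and noise model of the generator."""

from __future__ import annotations

import filecmp
import math

import numpy as np
import pytest

from droughtnc.annotation import revcomp_rna
from droughtnc.degradome import map_tags, validate_cleavage
from droughtnc.expression import build_records
from droughtnc.simulate import (
    CONDITIONS,
    SimulationTruth,
    generate_annotation,
    generate_bundle,
    generate_counts,
    generate_degradome,
    generate_mirna_sites,
    generate_mirnas,
)
from droughtnc.targets import ScoringParams, align_duplex


class TestDeterminism:
    def test_same_seed_writes_byte_identical_bundles(self, tmp_path, small_bundle):
        a = generate_bundle(seed=42, n_coding=20, n_premirna=6, n_lncrna=8,
                            n_inducible=2, n_repressible=2, n_lnc_up=3, n_lnc_down=4,
                            n_sites=4, n_guiding_mirnas=3,
                            lncrna_category_counts={"antisense": 3, "bidirectional": 1,
                                                    "intergenic": 2, "sense": 1,
                                                    "intronic": 1})
        b = generate_bundle(seed=42, n_coding=20, n_premirna=6, n_lncrna=8,
                            n_inducible=2, n_repressible=2, n_lnc_up=3, n_lnc_down=4,
                            n_sites=4, n_guiding_mirnas=3,
                            lncrna_category_counts={"antisense": 3, "bidirectional": 1,
                                                    "intergenic": 2, "sense": 1,
                                                    "intronic": 1})
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in ("annotation", "transcripts", "mirnas", "counts", "degradome",
                    "truth"):
            assert filecmp.cmp(pa[key], pb[key], shallow=False), key

    def test_different_seeds_differ(self):
        a = generate_annotation(10, 2, 4, seed=1)[1]
        b = generate_annotation(10, 2, 4, seed=2)[1]
        assert a != b

    def test_truth_round_trips_through_json(self, small_bundle):
        truth = small_bundle.truth
        again = SimulationTruth.from_json(truth.to_json())
        assert again.to_json() == truth.to_json()
        assert again == truth


class TestAnnotation:
    def test_no_lncrnas_when_none_requested(self):
        transcripts, _, truth = generate_annotation(10, 4, 0, seed=3)
        assert all(t.biotype != "lncRNA" for t in transcripts)
        assert truth.lncrna_categories == {}

    def test_every_planted_item_references_a_generated_feature(self, default_bundle):
        ids = {t.id for t in default_bundle.transcripts}
        truth = default_bundle.truth
        assert set(truth.de) <= ids
        assert set(truth.lncrna_categories) <= ids
        for site in truth.mirna_sites:
            assert site["target_id"] in ids
        for pair in truth.nat_configurations:
            assert {pair["id_a"], pair["id_b"]} <= ids

    def test_sequences_match_spliced_lengths(self):
        transcripts, seqs, _ = generate_annotation(15, 5, 10, seed=4)
        for t in transcripts:
            assert len(seqs[t.id]) == t.length_nt


class TestCounts:
    def make_truth(self, effects, baseline=10**6):
        truth = SimulationTruth(seed=0)
        truth.de["f"] = {
            "class": "planted",
            "effects": {c: effects for c in CONDITIONS[1:]},
            "baseline": baseline,
        }
        return truth

    def test_null_effect_with_huge_baseline_converges(self):
        counts = generate_counts(["f"], self.make_truth(0.0), dispersion=0.0, seed=5)
        row = counts.loc["f"]
        for c in CONDITIONS[1:]:
            assert abs(math.log2(row[c] / row["C"])) < 0.1

    def test_planted_effect_recovered_by_classifier(self):
        truth = self.make_truth(3.0, baseline=5000)
        counts = generate_counts(["f"], truth, dispersion=0.05, seed=6)
        records = build_records(
            counts, {"f": 1000}, control="C",
            library_sizes={c: 10**6 for c in CONDITIONS},
        )
        assert records["f"].overall_class == "inducible"

    def test_seed_determinism(self):
        t = self.make_truth(1.0, baseline=100)
        a = generate_counts(["f"], t, dispersion=0.1, seed=7)
        b = generate_counts(["f"], t, dispersion=0.1, seed=7)
        assert a.equals(b)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            generate_counts(["f"], self.make_truth(0.0), dispersion=-1)


class TestSites:
    def setup_sites(self, seed=8, max_edits=2, n_sites=10):
        transcripts, seqs, truth = generate_annotation(30, 2, 0, seed=seed)
        mirnas = generate_mirnas(5, seed=seed)
        seqs = generate_mirna_sites(
            transcripts, seqs, mirnas, truth,
            n_sites=n_sites, n_guiding_mirnas=5, seed=seed, max_edits=max_edits,
        )
        return seqs, truth, {m.id: m for m in mirnas}

    def test_zero_edit_sites_found_at_expectation_zero(self):
        seqs, truth, mirnas = self.setup_sites(max_edits=0)
        for site in truth.mirna_sites:
            alns = align_duplex(
                mirnas[site["mirna_id"]], seqs[site["target_id"]],
                params=ScoringParams(max_expectation=0.0),
            )
            assert any(
                a.window == (site["window_start"], site["window_end"])
                and a.expectation == 0.0
                and a.t10 == site["t10"]
                for a in alns
            )

    def test_edited_sites_found_at_recorded_price(self):
        """An n-edit site prices at n; it passes cutoff 3 and fails below n."""
        seqs, truth, mirnas = self.setup_sites(max_edits=2)
        edited = [s for s in truth.mirna_sites if s["n_edits"] == 2]
        assert edited, "generator planted no 2-edit site under this seed"
        for site in edited:
            mirna = mirnas[site["mirna_id"]]
            window = (site["window_start"], site["window_end"])
            found = [
                a.window
                for a in align_duplex(mirna, seqs[site["target_id"]],
                                      params=ScoringParams(max_expectation=3.0))
            ]
            assert window in found
            strict = [
                a.window
                for a in align_duplex(mirna, seqs[site["target_id"]],
                                      params=ScoringParams(max_expectation=1.0))
            ]
            assert window not in strict

    def test_planted_site_expectation_matches_search(self):
        seqs, truth, mirnas = self.setup_sites()
        for site in truth.mirna_sites:
            alns = align_duplex(mirnas[site["mirna_id"]], seqs[site["target_id"]])
            best = {a.window: a for a in alns}
            window = (site["window_start"], site["window_end"])
            assert best[window].expectation <= site["expectation"]


class TestDegradome:
    def test_zero_background_tags_all_validate_planted_sites(self):
        transcripts, seqs, truth = generate_annotation(25, 2, 0, seed=9)
        mirnas = generate_mirnas(4, seed=9)
        seqs = generate_mirna_sites(transcripts, seqs, mirnas, truth,
                                    n_sites=8, n_guiding_mirnas=4, seed=9)
        tags = generate_degradome(seqs, truth, background_per_kb=0.0, seed=9)
        planted = {(s["target_id"], s["t10"]) for s in truth.cleavage_sites}
        for tag in tags:
            hits = [
                (tid, pos)
                for tid in seqs
                for pos in map_tags([tag], seqs[tid])
            ]
            assert any(h in planted for h in hits)

    def test_signal_counts_recorded_per_library(self):
        transcripts, seqs, truth = generate_annotation(25, 2, 0, seed=10)
        mirnas = generate_mirnas(4, seed=10)
        seqs = generate_mirna_sites(transcripts, seqs, mirnas, truth,
                                    n_sites=5, n_guiding_mirnas=4, seed=10)
        generate_degradome(seqs, truth, signal_tags_per_site=4,
                           background_per_kb=0.0, seed=10)
        for site in truth.cleavage_sites:
            assert sum(site["per_library_signal"].values()) == 4
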