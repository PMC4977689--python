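"""End-to-end orchestration: config, stage wiring, reports and summary.

``run_pipeline`` chains the stages — expression screening, target
prediction, degradome validation, anti-correlation, lncRNA/NAT
classification — over one consistent input bundle and writes a
miRNA/target report (RPKM columns, 2-dp log2 ratios, duplex window,
per-library degradome support, Pearson r), an expression table, an lncRNA
report and a machine-readable JSON summary. All inputs are validated before
any output is written, so a failing run leaves nothing behind.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    read_counts_tsv,
    read_degradome_table,
    read_fasta,
    read_gff3,
    read_mirna_table,
)
from .correlation import screen_pairs
from .degradome import map_tags, summarize_validations, validate_cleavage
from .expression import (
    THRESHOLD_PROFILES,
    build_records,
    de_sets,
    format_log2,
    intersect_de_sets,
    records_to_frame,
)
from .lncrna import classify_all_lncrnas, filter_lncrna_candidates, find_cis_nat_pairs
from .targets import ScoringParams, align_duplex


class PipelineInputError(ValueError):
    """Unresolvable or inconsistent pipeline inputs (exit code 1)."""


@dataclass
class PipelineConfig:
    """Paths, condition panel and every stage threshold in one place."""

    annotation: str
    transcripts: str
    mirnas: str
    counts: str
    degradome: str
    outdir: str
    conditions: tuple[str, ...] = ("C", "1d", "2d", "3d")
    control: str = "C"
    gene_log2: float = 1.0
    premirna_log2: float = 1.0
    lncrna_log2: float = 2.0
    const_high_rpkm: float = 10_000.0
    const_low_rpkm: float = 1_000.0
    max_expectation: float = 3.0
    cleavage_window: int = 0
    count_mode: str = "distinct"
    r_threshold: float = -0.5
    bidirectional_max_tss_distance: int = 1000
    lncrna_min_length: int = 1000
    library_sizes: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.conditions:
            raise PipelineInputError(
                f"control {self.control!r} is not one of the conditions "
                f"{list(self.conditions)}"
            )
        for name in ("gene_log2", "premirna_log2", "lncrna_log2"):
            if getattr(self, name) <= 0:
                raise PipelineInputError(f"{name} must be positive")
        if self.cleavage_window < 0:
            raise PipelineInputError("cleavage_window must be >= 0")
        if self.lncrna_min_length < 0:
            raise PipelineInputError("lncrna_min_length must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def thresholds(self) -> dict[str, tuple[float, float]]:
        return {
            "coding": (self.gene_log2, self.gene_log2),
            "pre_miRNA": (self.premirna_log2, self.premirna_log2),
            "lncRNA": (self.lncrna_log2, self.lncrna_log2),
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    transcripts = read_gff3(config.annotation)
    seqs = read_fasta(config.transcripts, alphabet="rna")
    mirnas = read_mirna_table(config.mirnas)
    counts = read_counts_tsv(config.counts)
    tags = read_degradome_table(config.degradome)

    # --- resolve ids before writing anything
    by_id = {t.id: t for t in transcripts}
    missing_seq = sorted(set(by_id) - set(seqs))
    if missing_seq:
        raise PipelineInputError(f"no sequence for transcript(s) {missing_seq[:5]}")
    missing_counts = sorted(set(by_id) - set(counts.index))
    if missing_counts:
        raise PipelineInputError(f"no counts for feature(s) {missing_counts[:5]}")
    if tuple(counts.columns) != tuple(config.conditions):
        raise PipelineInputError(
            f"count table conditions {list(counts.columns)} do not match the "
            f"configured panel {list(config.conditions)}"
        )
    precursor_of = {}
    for m in mirnas:
        if m.precursor_id and m.precursor_id not in by_id:
            raise PipelineInputError(
                f"miRNA {m.id} names unknown precursor {m.precursor_id!r}"
            )
        precursor_of[m.id] = m.precursor_id or m.id

    t_start = time.time()

    # --- expression
    lengths = {t.id: t.length_nt for t in transcripts}
    biotypes = {t.id: t.biotype for t in transcripts}
    records = build_records(
        counts.loc[list(by_id)],
        lengths,
        control=config.control,
        library_sizes=config.library_sizes,
        thresholds=config.thresholds(),
        biotypes=biotypes,
        const_high_rpkm=config.const_high_rpkm,
        const_low_rpkm=config.const_low_rpkm,
    )
    gene_records = [r for r in records.values() if biotypes[r.feature_id] == "coding"]
    ups, downs = de_sets(gene_records)
    treatment_order = [c for c in config.conditions if c != config.control]
    always_up, always_down = intersect_de_sets(
        [ups.get(c, set()) for c in treatment_order],
        [downs.get(c, set()) for c in treatment_order],
    )

    # --- responsive miRNAs and their candidate targets
    responsive_premirnas = {
        fid
        for fid, rec in records.items()
        if biotypes[fid] == "pre_miRNA"
        and rec.overall_class in ("inducible", "repressible")
    }
    responsive_mirnas = [
        m for m in mirnas if precursor_of[m.id] in responsive_premirnas
    ]
    params = ScoringParams(max_expectation=config.max_expectation)
    coding_ids = sorted(t.id for t in transcripts if t.biotype == "coding")
    tag_maps = {
        tid: map_tags(tags, seqs[tid], count_mode=config.count_mode)
        for tid in coding_ids
    }
    mirna_rows = []
    evidences = []
    pairs = []
    for m in sorted(responsive_mirnas, key=lambda m: m.id):
        for tid in coding_ids:
            # overlapping windows (e.g. a bulged variant one start earlier)
            # can predict the same cleavage position: keep the best duplex
            # per distinct (miRNA, target, t10)
            best_per_site: dict[object, object] = {}
            for aln in align_duplex(m, seqs[tid], tid, params):
                key = aln.t10
                prev = best_per_site.get(key)
                if prev is None or aln.expectation < prev.expectation:
                    best_per_site[key] = aln
            for aln in sorted(
                best_per_site.values(), key=lambda a: a.window[0]
            ):
                ev = validate_cleavage(aln, tag_maps[tid], config.cleavage_window)
                evidences.append(ev)
                pairs.append((m.id, tid))
                mirna_rows.append((m, tid, aln, ev))

    correlations = {
        (pc.mirna_id, pc.target_id): pc
        for pc in screen_pairs(
            pairs, records, config.r_threshold, mirna_to_expression_id=precursor_of
        )
    }
    n_validated, n_distinct = summarize_validations(evidences)

    # --- lncRNAs and NATs
    lnc_transcripts = [t for t in transcripts if t.biotype == "lncRNA"]
    categories = classify_all_lncrnas(
        transcripts, config.bidirectional_max_tss_distance
    )
    nat_pairs = find_cis_nat_pairs(transcripts)
    lnc_up, lnc_down = filter_lncrna_candidates(
        lnc_transcripts, records, config.lncrna_min_length, config.lncrna_log2
    )

    summary = {
        "n_features": len(transcripts),
        "n_inducible_premirna": sum(
            1
            for fid in records
            if biotypes[fid] == "pre_miRNA"
            and records[fid].overall_class == "inducible"
        ),
        "n_repressible_premirna": sum(
            1
            for fid in records
            if biotypes[fid] == "pre_miRNA"
            and records[fid].overall_class == "repressible"
        ),
        "n_genes_up_all_timepoints": len(always_up),
        "n_genes_down_all_timepoints": len(always_down),
        "n_target_candidates": len(mirna_rows),
        "n_validated_cleavages": n_validated,
        "n_distinct_mirnas_validated": n_distinct,
        "n_anticorrelated_pairs": sum(
            1 for pc in correlations.values() if pc.anticorrelated
        ),
        "n_lncrna_up": len(lnc_up),
        "n_lncrna_down": len(lnc_down),
        "n_cis_nat_pairs": len(nat_pairs),
    }

    # --- reports (inputs validated: safe to write now)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(outdir / "expression_table.tsv", sep="\t",
                                     index=False)

    report_rows = []
    for m, tid, aln, ev in mirna_rows:
        pc = correlations[(m.id, tid)]
        rec_m = records[precursor_of[m.id]]
        rec_t = records[tid]
        row: dict[str, object] = {
            "mirna_id": m.id,
            "precursor_id": precursor_of[m.id],
            "mirna_class": rec_m.overall_class,
            "target_id": tid,
            "window_start": aln.window[0],
            "window_end": aln.window[1],
            "expectation": aln.expectation,
            "t10": aln.t10 if aln.t10 is not None else "-",
        }
        for c in config.conditions:
            row[f"mirna_rpkm_{c}"] = round(rec_m.rpkm[c])
            row[f"target_rpkm_{c}"] = round(rec_t.rpkm[c])
        for c in treatment_order:
            row[f"mirna_log2_{c}"] = format_log2(rec_m.log2[c])
            row[f"target_log2_{c}"] = format_log2(rec_t.log2[c])
        for lib in sorted({t.library_id for t in tags}):
            row[f"pare_{lib}"] = ev.per_library_counts.get(lib, 0)
        row["validated"] = ev.validated
        row["r"] = "-" if pc.r is None else f"{pc.r:.3f}"
        row["anticorrelated"] = pc.anticorrelated
        report_rows.append(row)
    pd.DataFrame(report_rows).to_csv(outdir / "mirna_report.tsv", sep="\t",
                                     index=False)

    lnc_rows = []
    nat_by_id: dict[str, list] = {}
    for p in nat_pairs:
        nat_by_id.setdefault(p.id_a, []).append(p)
        nat_by_id.setdefault(p.id_b, []).append(p)
    for t in lnc_transcripts:
        cls = categories[t.id]
        nats = nat_by_id.get(t.id, [])
        rec = records[t.id]
        lnc_rows.append(
            {
                "lnc_id": t.id,
                "length_nt": t.length_nt,
                "category": cls.category,
                "partner_id": cls.partner_id or "-",
                "tss_distance_nt": (
                    cls.tss_distance_nt if cls.tss_distance_nt is not None else "-"
                ),
                "nat_configuration": nats[0].configuration if nats else "-",
                "nat_overlap_nt": nats[0].overlap_nt if nats else "-",
                "responsive": (
                    "up" if t.id in lnc_up else "down" if t.id in lnc_down else "no"
                ),
                **{
                    f"log2_{c}": format_log2(rec.log2[c]) for c in treatment_order
                },
            }
        )
    pd.DataFrame(lnc_rows).to_csv(outdir / "lncrna_report.tsv", sep="\t",
                                  index=False)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log = {
        "version": __version__,
        "seed": config.seed,
        "runtime_s": round(time.time() - t_start, 3),
        "config": {k: v for k, v in asdict(config).items()},
    }
    (outdir / "run_log.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in log.items()) + "\n"
    )
    return summary
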