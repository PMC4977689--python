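"""RPKM, log2 drought/control ratios and fold-change expression classes.

The screen is deliberately threshold-based (no dispersion model, no p-values):
a feature is differentially expressed at a timepoint when its log2
RPKM ratio versus the well-watered control crosses a fold-change cutoff.
Different feature classes use different stringencies (genes and pre-miRNAs
2-fold, lncRNAs 4-fold by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: per-feature-class (up, down) log2 thresholds
THRESHOLD_PROFILES: dict[str, tuple[float, float]] = {
    "coding": (1.0, 1.0),
    "pre_miRNA": (1.0, 1.0),
    "lncRNA": (2.0, 2.0),
}


def compute_rpkm(count: int, feature_length_nt: int, library_size_reads: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if feature_length_nt <= 0:
        raise ValueError(f"non-positive feature length {feature_length_nt}")
    if library_size_reads <= 0:
        raise ValueError(f"non-positive library size {library_size_reads}")
    if count < 0:
        raise ValueError(f"negative count {count}")
    return count / (feature_length_nt / 1000.0) / (library_size_reads / 1e6)


def log2_ratio(treatment_rpkm: float, control_rpkm: float) -> float | None:
    """log2(treatment / control); ``None`` (undefined) when either side is 0.

    No pseudocount is applied by default — tabular reports print ``-`` for
    undefined cells.
    """
    if treatment_rpkm < 0 or control_rpkm < 0:
        raise ValueError("RPKM values must be non-negative")
    if treatment_rpkm == 0 or control_rpkm == 0:
        return None
    return math.log2(treatment_rpkm / control_rpkm)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed reports)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if x < 0 else d)


def format_log2(value: float | None) -> str:
    """2-dp report formatting; undefined ratios print as ``-``."""
    if value is None:
        return "-"
    return f"{round_half_away(value, 2):.2f}"


@dataclass
class ExpressionRecord:
    """Per-feature expression summary across an ordered condition panel."""

    feature_id: str
    conditions: tuple[str, ...]
    control: str
    counts: dict[str, int]
    rpkm: dict[str, float]
    log2: dict[str, float | None]  # treatment condition -> ratio vs control
    de_class: dict[str, str]  # treatment condition -> up/down/unchanged/undefined
    overall_class: str = "mixed"

    @property
    def profile(self) -> list[float]:
        """RPKM profile in condition order (for correlation screens)."""
        return [self.rpkm[c] for c in self.conditions]

    def max_abs_log2(self) -> float | None:
        defined = [v for v in self.log2.values() if v is not None]
        return max((abs(v) for v in defined), default=None)


def classify_feature(
    record: ExpressionRecord,
    up_log2: float = 1.0,
    down_log2: float = 1.0,
    const_high_rpkm: float = 10_000.0,
    const_low_rpkm: float = 1_000.0,
) -> ExpressionRecord:
    """Assign per-timepoint DE classes and the overall class, in place.

    Per timepoint: ``up`` iff log2 >= up_log2, ``down`` iff log2 <= -down_log2,
    ``undefined`` when the ratio is undefined, else ``unchanged``. Overall:
    ``inducible`` if up somewhere and never down, ``repressible`` for the
    mirror, ``constitutive_high``/``constitutive_low`` when unchanged at every
    timepoint with mean RPKM above/below the cutoffs, else ``mixed``.
    """
    if up_log2 <= 0 or down_log2 <= 0:
        raise ValueError("DE thresholds must be positive")
    de: dict[str, str] = {}
    for cond, lr in record.log2.items():
        if lr is None:
            de[cond] = "undefined"
        elif lr >= up_log2:
            de[cond] = "up"
        elif lr <= -down_log2:
            de[cond] = "down"
        else:
            de[cond] = "unchanged"
    record.de_class = de
    states = set(de.values())
    if "up" in states and "down" in states:
        overall = "mixed"
    elif "up" in states:
        overall = "inducible"
    elif "down" in states:
        overall = "repressible"
    elif states == {"unchanged"} and de:
        mean_rpkm = sum(record.rpkm.values()) / len(record.rpkm)
        if mean_rpkm >= const_high_rpkm:
            overall = "constitutive_high"
        elif mean_rpkm <= const_low_rpkm:
            overall = "constitutive_low"
        else:
            overall = "mixed"
    else:
        overall = "mixed"
    record.overall_class = overall
    return record


def build_records(
    counts: pd.DataFrame,
    lengths: Mapping[str, int],
    control: str,
    library_sizes: Mapping[str, int] | None = None,
    thresholds: Mapping[str, tuple[float, float]] | None = None,
    biotypes: Mapping[str, str] | None = None,
    const_high_rpkm: float = 10_000.0,
    const_low_rpkm: float = 1_000.0,
) -> dict[str, ExpressionRecord]:
    """Turn a count table into classified :class:`ExpressionRecord` objects.

    ``library_sizes`` defaults to the column sums of the count table (reads
    mapped to the annotation); pass explicit totals to use total mapped reads
    instead. ``thresholds`` maps biotype -> (up, down) log2 cutoffs and
    defaults to :data:`THRESHOLD_PROFILES`.
    """
    conditions = tuple(counts.columns)
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not in count table columns")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).to_dict()
    thresholds = dict(THRESHOLD_PROFILES) if thresholds is None else dict(thresholds)
    records: dict[str, ExpressionRecord] = {}
    for fid, row in counts.iterrows():
        if fid not in lengths:
            raise KeyError(f"no length for feature {fid!r}")
        rpkm = {
            c: compute_rpkm(int(row[c]), int(lengths[fid]), int(library_sizes[c]))
            for c in conditions
        }
        lr = {
            c: log2_ratio(rpkm[c], rpkm[control]) for c in conditions if c != control
        }
        rec = ExpressionRecord(
            feature_id=str(fid),
            conditions=conditions,
            control=control,
            counts={c: int(row[c]) for c in conditions},
            rpkm=rpkm,
            log2=lr,
            de_class={},
        )
        biotype = (biotypes or {}).get(str(fid), "coding")
        up, down = thresholds.get(biotype, (1.0, 1.0))
        classify_feature(rec, up, down, const_high_rpkm, const_low_rpkm)
        records[str(fid)] = rec
    return records


def intersect_de_sets(
    up_sets: Sequence[set[str]], down_sets: Sequence[set[str]]
) -> tuple[set[str], set[str]]:
    """Features up (resp. down) at every timepoint; the outputs are disjoint."""
    if len(up_sets) < 2 or len(down_sets) < 2:
        raise ValueError("need at least 2 timepoints to intersect DE sets")
    all_up = set.intersection(*map(set, up_sets))
    all_down = set.intersection(*map(set, down_sets))
    return all_up, all_down


def de_sets(
    records: Iterable[ExpressionRecord],
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-timepoint up/down feature-id sets from classified records."""
    ups: dict[str, set[str]] = {}
    downs: dict[str, set[str]] = {}
    for rec in records:
        for cond, de in rec.de_class.items():
            ups.setdefault(cond, set())
            downs.setdefault(cond, set())
            if de == "up":
                ups[cond].add(rec.feature_id)
            elif de == "down":
                downs[cond].add(rec.feature_id)
    return ups, downs


def records_to_frame(records: Mapping[str, ExpressionRecord]) -> pd.DataFrame:
    """Flatten records into a report table (RPKM columns, 2-dp log2, class)."""
    rows = []
    for fid in records:
        rec = records[fid]
        row: dict[str, object] = {"id": fid}
        for c in rec.conditions:
            row[f"rpkm_{c}"] = rec.rpkm[c]
        for c, lr in rec.log2.items():
            row[f"log2_{c}_vs_{rec.control}"] = format_log2(lr)
        for c, de in rec.de_class.items():
            row[f"de_{c}"] = de
        row["class"] = rec.overall_class
        rows.append(row)
    return pd.DataFrame(rows)
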