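"""miRNA / target expression anti-correlation screen.

A cleavage-competent miRNA should deplete its target: across the condition
panel the two RPKM profiles should run in opposite directions. With only a
handful of conditions a raw Pearson cutoff is noisy, so a pair is flagged
*anticorrelated* only when r falls below the (negative) threshold AND the
two features carry opposed overall expression classes (one inducible, the
other repressible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expression import ExpressionRecord


@dataclass(frozen=True)
class PairCorrelation:
    mirna_id: str
    target_id: str
    r: float | None  # None when a profile has zero variance
    direction_opposed: bool
    anticorrelated: bool


def correlate_profiles(
    profile_a: Sequence[float], profile_b: Sequence[float]
) -> float | None:
    """Pearson correlation of two matched profiles; None for zero variance."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch ({a.size} vs {b.size})")
    if a.size < 3:
        raise ValueError(f"need >= 3 matched conditions, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def _opposed(class_a: str, class_b: str) -> bool:
    return {class_a, class_b} == {"inducible", "repressible"}


def screen_pairs(
    candidates: Iterable[tuple[str, str]],
    records: Mapping[str, ExpressionRecord],
    r_threshold: float = -0.5,
    mirna_to_expression_id: Mapping[str, str] | None = None,
) -> list[PairCorrelation]:
    """Score every (mirna_id, target_id) candidate for anti-correlation.

    Expression of a mature miRNA is read from its precursor via
    ``mirna_to_expression_id`` (identity by default). A missing record is an
    error naming the feature; pairs with undefined r are reported unflagged.
    """
    out: list[PairCorrelation] = []
    seen: set[tuple[str, str]] = set()
    for mirna_id, target_id in candidates:
        if (mirna_id, target_id) in seen:
            continue
        seen.add((mirna_id, target_id))
        expr_id = (mirna_to_expression_id or {}).get(mirna_id, mirna_id)
        if expr_id not in records:
            raise KeyError(f"no expression record for miRNA feature {expr_id!r}")
        if target_id not in records:
            raise KeyError(f"no expression record for target {target_id!r}")
        rec_m, rec_t = records[expr_id], records[target_id]
        r = correlate_profiles(rec_m.profile, rec_t.profile)
        opposed = _opposed(rec_m.overall_class, rec_t.overall_class)
        out.append(
            PairCorrelation(
                mirna_id=mirna_id,
                target_id=target_id,
                r=r,
                direction_opposed=opposed,
                anticorrelated=r is not None and r <= r_threshold and opposed,
            )
        )
    return out
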