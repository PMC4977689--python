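"""Plant miRNA target search with expectation scoring.

A miRNA pairs antiparallel to a target window: miRNA base 1 (5' end) pairs
the window's 3'-most base. The expectation score accumulates mispairing
penalties — Watson-Crick match 0, G:U wobble 0.5, mismatch 1, bulged base 2 —
with every penalty doubled in the seed region (miRNA positions 2–13). Lower
is better; 0 is perfect complementarity. At most one bulge per duplex is
allowed by default and bulges may not sit at the miRNA ends.

``t10`` is the target position paired with miRNA base 10; slicer cleavage
falls between the targets of bases 10 and 11, so the degradome 3' fragment
starts at ``t10``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import RNA_BASES, MatureMiRNA

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

MATCH = "match"
GU = "GU"
MISMATCH = "mismatch"
MIRNA_BULGE = "mirna_bulge"
TARGET_BULGE = "target_bulge"


@dataclass(frozen=True)
class ScoringParams:
    """Penalty scheme for duplex expectation scoring (all configurable)."""

    match: float = 0.0
    gu: float = 0.5
    mismatch: float = 1.0
    bulge: float = 2.0
    seed_start: int = 2
    seed_end: int = 13
    seed_multiplier: float = 2.0
    max_bulges: int = 1
    max_expectation: float = 3.0


DEFAULT_PARAMS = ScoringParams()


def pair_state(mirna_base: str, target_base: str) -> str:
    pair = (mirna_base, target_base)
    if pair in _WC:
        return MATCH
    if pair in _GU:
        return GU
    return MISMATCH


def score_pair(
    mirna_base: str,
    target_base: str,
    mirna_position: int,
    params: ScoringParams = DEFAULT_PARAMS,
) -> float:
    """Penalty for pairing one miRNA base against one target base."""
    if mirna_base not in RNA_BASES or target_base not in RNA_BASES:
        raise ValueError(f"invalid base in pair ({mirna_base!r}, {target_base!r})")
    if mirna_position < 1:
        raise ValueError(f"miRNA position {mirna_position} < 1")
    state = pair_state(mirna_base, target_base)
    penalty = {MATCH: params.match, GU: params.gu, MISMATCH: params.mismatch}[state]
    if params.seed_start <= mirna_position <= params.seed_end:
        penalty *= params.seed_multiplier
    return penalty


def _bulge_penalty(effective_position: int, params: ScoringParams) -> float:
    penalty = params.bulge
    if params.seed_start <= effective_position <= params.seed_end:
        penalty *= params.seed_multiplier
    return penalty


@dataclass(frozen=True)
class PairStep:
    """One rung of the duplex ladder, ordered from the miRNA 5' end.

    Bulges carry ``None`` on the unpaired side.
    """

    state: str
    mirna_pos: int | None
    target_pos: int | None


@dataclass(frozen=True)
class DuplexAlignment:
    mirna_id: str
    target_id: str
    window: tuple[int, int]  # 1-based inclusive, transcript-local
    pairing: tuple[PairStep, ...]
    expectation: float
    t10: int | None  # None when miRNA base 10 is bulged
    n_bulges: int = 0


def _build_alignment(
    mirna: MatureMiRNA,
    target_id: str,
    target_seq: str,
    window_start: int,
    mirna_bulge_at: int | None,
    target_bulge_after: int | None,
    params: ScoringParams,
) -> DuplexAlignment | None:
    """Score one explicit duplex configuration; None if it does not fit."""
    m = mirna.sequence
    L = len(m)
    wlen = L + (1 if target_bulge_after is not None else 0) - (
        1 if mirna_bulge_at is not None else 0
    )
    window_end = window_start + wlen - 1
    if window_start < 1 or window_end > len(target_seq):
        return None
    steps: list[PairStep] = []
    expectation = 0.0
    n_bulges = 0
    # Antiparallel: miRNA base 1 pairs window_end; later bases walk 3'->5'
    # along the target. A miRNA bulge skips a miRNA base (no target consumed);
    # a target bulge consumes an extra target base between two miRNA bases.
    tpos = window_end
    for k in range(1, L + 1):
        if mirna_bulge_at == k:
            expectation += _bulge_penalty(k, params)
            n_bulges += 1
            steps.append(PairStep(MIRNA_BULGE, k, None))
            continue
        mb = m[k - 1]
        tb = target_seq[tpos - 1]
        state = pair_state(mb, tb)
        expectation += score_pair(mb, tb, k, params)
        steps.append(PairStep(state, k, tpos))
        tpos -= 1
        if target_bulge_after == k:
            # bulged target base between miRNA bases k and k+1; seed status
            # follows the downstream miRNA position k+1
            expectation += _bulge_penalty(k + 1, params)
            n_bulges += 1
            steps.append(PairStep(TARGET_BULGE, None, tpos))
            tpos -= 1
    t10 = next(
        (s.target_pos for s in steps if s.mirna_pos == 10 and s.state != MIRNA_BULGE),
        None,
    )
    return DuplexAlignment(
        mirna_id=mirna.id,
        target_id=target_id,
        window=(window_start, window_end),
        pairing=tuple(steps),
        expectation=expectation,
        t10=t10,
        n_bulges=n_bulges,
    )


def _tie_key(aln: DuplexAlignment) -> tuple:
    return (
        aln.expectation,
        aln.n_bulges,
        aln.t10 if aln.t10 is not None else float("inf"),
    )


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def _penalty_lookup(params: ScoringParams) -> np.ndarray:
    """4x4 penalty table indexed by (miRNA base, target base) codes."""
    table = np.empty((4, 4))
    for mb, i in _BASE_INDEX.items():
        for tb, j in _BASE_INDEX.items():
            state = pair_state(mb, tb)
            table[i, j] = {
                MATCH: params.match, GU: params.gu, MISMATCH: params.mismatch
            }[state]
    return table


def _config_scores(
    mirna_seq: str, target_seq: str, params: ScoringParams
) -> tuple[np.ndarray, list[tuple[int | None, int | None]]]:
    """Expectation of every duplex configuration at every window start.

    Returns ``scores[config, start0]`` (inf where the window does not fit)
    plus the (mirna_bulge_at, target_bulge_after) descriptor per config.
    The three families of configurations differ only in where the
    antiparallel register shifts by one target base, so each is a pair of
    prefix/suffix sums over penalty "diagonals" P[k, s + o - k].
    """
    L = len(mirna_seq)
    N = len(target_seq)
    m = np.fromiter((_BASE_INDEX[b] for b in mirna_seq), dtype=np.int64, count=L)
    t = np.fromiter((_BASE_INDEX[b] for b in target_seq), dtype=np.int64, count=N)
    pen = _penalty_lookup(params)[m[:, None], t[None, :]]  # (L, N)
    seed = np.ones(L)
    seed[params.seed_start - 1 : params.seed_end] = params.seed_multiplier
    pen *= seed[:, None]

    n_starts = N - L + 2  # miRNA-bulge windows reach one start further
    if n_starts <= 0:
        return np.empty((0, 0)), []

    def diagonal(offset: int) -> np.ndarray:
        """diag[k, s0] = penalty of miRNA base k+1 vs target position s0+offset-k
        (1-based start s = s0+1), inf outside the target."""
        out = np.full((L, n_starts), np.inf)
        for k in range(L):  # target index (0-based) = s0 + offset - 1 - k
            lo = offset - 1 - k  # index when s0 = 0
            src_lo = max(0, -lo)
            src_hi = min(n_starts, N - lo)
            if src_lo < src_hi:
                out[k, src_lo:src_hi] = pen[k, lo + src_lo : lo + src_hi]
        return out

    d_mid = diagonal(L)  # plain antiparallel register
    configs: list[tuple[int | None, int | None]] = [(None, None)]
    rows = [d_mid.sum(axis=0)]
    if params.max_bulges >= 1:
        d_short = diagonal(L - 1)  # register after skipping a miRNA base
        d_long = diagonal(L + 1)  # register before a bulged target base
        pre_short = np.cumsum(d_short, axis=0)
        pre_long = np.cumsum(d_long, axis=0)
        suf_mid = np.cumsum(d_mid[::-1], axis=0)[::-1]
        for b in range(2, L):  # miRNA base b unpaired (never the ends)
            score = pre_short[b - 2] + suf_mid[b] + _bulge_penalty(b, params)
            configs.append((b, None))
            rows.append(score)
        for after in range(1, L):  # target base bulged between after, after+1
            score = (
                pre_long[after - 1]
                + suf_mid[after]
                + _bulge_penalty(after + 1, params)
            )
            configs.append((None, after))
            rows.append(score)
    return np.vstack(rows), configs


def align_duplex(
    mirna: MatureMiRNA,
    target_seq: str,
    target_id: str = "",
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[DuplexAlignment]:
    """All windows admitting a duplex with expectation <= the cutoff.

    One (best) alignment per window start; ties resolved toward fewer bulges,
    then smaller ``t10``. The result is sorted by expectation, then window
    start.
    """
    L = len(mirna.sequence)
    if len(target_seq) < L:
        return []
    scores, configs = _config_scores(mirna.sequence, target_seq, params)
    if scores.size == 0:
        return []
    best: list[DuplexAlignment] = []
    passing = np.nonzero(
        np.min(scores, axis=0) <= params.max_expectation + 1e-9
    )[0]
    for s0 in passing:
        col = scores[:, s0]
        cands = []
        for ci in np.nonzero(col <= col.min() + 1e-9)[0]:
            aln = _build_alignment(
                mirna, target_id, target_seq, int(s0) + 1,
                configs[ci][0], configs[ci][1], params,
            )
            if aln is not None:
                cands.append(aln)
        if cands:
            top = min(cands, key=_tie_key)
            if top.expectation <= params.max_expectation:
                best.append(top)
    best.sort(key=lambda a: (a.expectation, a.window[0]))
    return best


def predict_targets(
    mirnas: Iterable[MatureMiRNA],
    transcriptome: Mapping[str, str],
    params: ScoringParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Candidate table over all miRNA x transcript pairs.

    Columns: mirna_id, target_id, window_start, window_end, expectation, t10;
    deterministic order (mirna_id, target_id, window_start).
    """
    rows = []
    for mirna in sorted(mirnas, key=lambda m: m.id):
        for tid in sorted(transcriptome):
            for aln in align_duplex(mirna, transcriptome[tid], tid, params):
                rows.append(
                    {
                        "mirna_id": mirna.id,
                        "target_id": tid,
                        "window_start": aln.window[0],
                        "window_end": aln.window[1],
                        "expectation": aln.expectation,
                        "t10": aln.t10,
                        "n_bulges": aln.n_bulges,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "target_id",
            "window_start",
            "window_end",
            "expectation",
            "t10",
            "n_bulges",
        ],
    )
    return df.sort_values(
        ["mirna_id", "target_id", "window_start"], ignore_index=True
    )
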