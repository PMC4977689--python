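"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the scoring/overlap definitions alone, with
no imports from the package's search or classification code paths.
"""

from __future__ import annotations

import itertools

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "U"), ("U", "G")}


def rpkm_formula(count: float, length_nt: float, library_size: float) -> float:
    """Direct evaluation of reads / (kb of transcript) / (millions of reads)."""
    return (count / (length_nt / 1000.0)) / (library_size / 1_000_000.0)


def column_penalty(mirna_base: str, target_base: str, position: int,
                   seed=(2, 13)) -> float:
    if (mirna_base, target_base) in WC:
        p = 0.0
    elif (mirna_base, target_base) in GU:
        p = 0.5
    else:
        p = 1.0
    if seed[0] <= position <= seed[1]:
        p *= 2.0
    return p


def bulge_cost(position: int, seed=(2, 13)) -> float:
    return 4.0 if seed[0] <= position <= seed[1] else 2.0


def enumerate_duplexes(mirna: str, target: str, max_expectation: float = 3.0):
    """Exhaustively score every window and single-bulge placement.

    Yields (window_start, window_end, expectation, n_bulges, t10) for the
    best configuration per window start with expectation <= cutoff,
    tie-broken toward fewer bulges then smaller t10, mirroring the scoring
    contract. Pure nested loops; no shared code with the optimised search.
    """
    L = len(mirna)
    N = len(target)
    best = {}

    def consider(start, end, expectation, n_bulges, t10):
        key = start
        entry = (expectation, n_bulges, t10 if t10 is not None else float("inf"),
                 end, t10)
        if key not in best or entry[:3] < best[key][:3]:
            best[key] = entry

    # configuration: no bulge
    for s in range(1, N - L + 2):
        e = s + L - 1
        exp = sum(
            column_penalty(mirna[k - 1], target[e - k], k) for k in range(1, L + 1)
        )
        consider(s, e, exp, 0, e - 9)
    # miRNA base b unpaired (window one shorter); b never at the ends
    for b in range(2, L):
        for s in range(1, N - (L - 1) + 2):
            e = s + L - 2
            if e > N:
                continue
            exp = bulge_cost(b)
            for k in range(1, L + 1):
                if k == b:
                    continue
                tpos = e - (k - 1) if k < b else e - (k - 2)
                exp += column_penalty(mirna[k - 1], target[tpos - 1], k)
            t10 = None if b == 10 else (e - 9 if 10 < b else e - 8)
            consider(s, e, exp, 1, t10)
    # target base bulged between miRNA positions a and a+1 (window one longer)
    for a in range(1, L):
        for s in range(1, N - (L + 1) + 2):
            e = s + L
            exp = bulge_cost(a + 1)
            for k in range(1, L + 1):
                tpos = e - (k - 1) if k <= a else e - k
                exp += column_penalty(mirna[k - 1], target[tpos - 1], k)
            t10 = e - 9 if 10 <= a else e - 10
            consider(s, e, exp, 1, t10)

    for s in sorted(best):
        exp, nb, _, e, t10 = best[s]
        if exp <= max_expectation + 1e-9:
            yield (s, e, exp, nb, t10)


def all_pairs_nat(transcripts):
    """All-pairs opposite-strand span-overlap check with configuration labels."""
    out = []
    for a, b in itertools.combinations(transcripts, 2):
        if a.chrom != b.chrom or a.strand == b.strand:
            continue
        lo, hi = max(a.start, b.start), min(a.end, b.end)
        if hi < lo:
            continue
        five = {t.start if t.strand == "+" else t.end for t in (a, b)}
        three = {t.end if t.strand == "+" else t.start for t in (a, b)}
        if all(lo <= x <= hi for x in five):
            config = "head_to_head"
        elif all(lo <= x <= hi for x in three):
            config = "tail_to_tail"
        elif (a.start <= b.start and b.end <= a.end) or (
            b.start <= a.start and a.end <= b.end
        ):
            config = "containment"
        else:
            config = "other_overlap"
        first, second = sorted([a, b], key=lambda t: (t.start, t.id))
        out.append((first.id, second.id, hi - lo + 1, config))
    return sorted(out)
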