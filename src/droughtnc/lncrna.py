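"""lncRNA classification and cis-natural-antisense-transcript detection.

lncRNAs fall into five mutually exclusive categories, resolved in precedence
order: antisense (exonic overlap with an opposite-strand transcript), sense
(exonic overlap, same strand), intronic (wholly inside another transcript's
intron, no exonic overlap anywhere), bidirectional (opposite strand, no
overlap, 5'-end distance within a cutoff), intergenic (everything else).

cis-NAT pairs are opposite-strand transcripts whose genomic spans overlap;
the overlap configuration is head-to-head (divergent: overlap holds both 5'
ends), tail-to-tail (convergent: both 3' ends), containment (one span inside
the other), or other_overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .annotation import TranscriptModel
from .expression import ExpressionRecord


@dataclass(frozen=True)
class NATPair:
    id_a: str
    id_b: str
    overlap_nt: int
    configuration: str  # head_to_head | tail_to_tail | containment | other_overlap


@dataclass(frozen=True)
class LncRNAClass:
    lnc_id: str
    category: str  # sense | antisense | bidirectional | intronic | intergenic
    partner_id: str | None = None
    tss_distance_nt: int | None = None


def nat_configuration(a: TranscriptModel, b: TranscriptModel) -> str:
    """Overlap configuration of two opposite-strand, span-overlapping loci."""
    if a.strand == b.strand:
        raise ValueError(f"{a.id} and {b.id} are on the same strand")
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if hi < lo:
        raise ValueError(f"{a.id} and {b.id} do not overlap")
    if lo <= a.five_prime <= hi and lo <= b.five_prime <= hi:
        return "head_to_head"
    if lo <= a.three_prime <= hi and lo <= b.three_prime <= hi:
        return "tail_to_tail"
    if (a.start <= b.start and b.end <= a.end) or (
        b.start <= a.start and a.end <= b.end
    ):
        return "containment"
    return "other_overlap"


def find_cis_nat_pairs(annotation: Sequence[TranscriptModel]) -> list[NATPair]:
    """All opposite-strand span-overlapping transcript pairs per chromosome.

    Deterministic order: (chrom, min start of the pair, ids). Within a pair,
    ``id_a`` is the transcript starting first (ties broken by id).
    """
    by_chrom: dict[str, dict[str, list[TranscriptModel]]] = {}
    for t in annotation:
        by_chrom.setdefault(t.chrom, {"+": [], "-": []})[t.strand].append(t)
    pairs: list[tuple[tuple, NATPair]] = []
    for chrom in by_chrom:
        plus, minus = by_chrom[chrom]["+"], by_chrom[chrom]["-"]
        if not plus or not minus:
            continue
        tree = IntervalTree()
        for t in plus:
            tree.addi(t.start, t.end + 1, t)
        for m in minus:
            for iv in tree.overlap(m.start, m.end + 1):
                p = iv.data
                overlap = min(p.end, m.end) - max(p.start, m.start) + 1
                first, second = sorted([p, m], key=lambda t: (t.start, t.id))
                pair = NATPair(
                    id_a=first.id,
                    id_b=second.id,
                    overlap_nt=overlap,
                    configuration=nat_configuration(p, m),
                )
                pairs.append(((chrom, first.start, first.id, second.id), pair))
    pairs.sort(key=lambda x: x[0])
    return [p for _, p in pairs]


class AnnotationIndex:
    """Per-chromosome exon and span interval trees over an annotation."""

    def __init__(self, annotation: Sequence[TranscriptModel]):
        self.transcripts = {t.id: t for t in annotation}
        if len(self.transcripts) != len(annotation):
            raise ValueError("duplicate transcript ids in annotation")
        self.exon_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        for t in annotation:
            et = self.exon_trees.setdefault(t.chrom, IntervalTree())
            for (s, e) in t.exons:
                et.addi(s, e + 1, t)
            self.span_trees.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end + 1, t
            )

    @property
    def chroms(self) -> set[str]:
        return set(self.span_trees)


def classify_lncrna(
    lnc: TranscriptModel,
    annotation: Sequence[TranscriptModel] | AnnotationIndex,
    bidirectional_max_tss_distance: int = 1000,
) -> LncRNAClass:
    """Assign one of the five lncRNA categories (precedence order above).

    Partner choice is deterministic regardless of annotation input order:
    largest exonic overlap (antisense/sense), then lexicographic id; nearest
    5' end for bidirectional.
    """
    index = (
        annotation
        if isinstance(annotation, AnnotationIndex)
        else AnnotationIndex(annotation)
    )
    if lnc.chrom not in index.chroms:
        raise ValueError(
            f"{lnc.id}: chromosome {lnc.chrom!r} not in the annotation universe"
        )

    def exon_overlap_nt(other: TranscriptModel) -> int:
        total = 0
        for (s1, e1) in lnc.exons:
            for (s2, e2) in other.exons:
                total += max(0, min(e1, e2) - max(s1, s2) + 1)
        return total

    overlapping: dict[str, TranscriptModel] = {}
    for (s, e) in lnc.exons:
        for iv in index.exon_trees[lnc.chrom].overlap(s, e + 1):
            if iv.data.id != lnc.id:
                overlapping[iv.data.id] = iv.data
    for wanted in ("-" if lnc.strand == "+" else "+", lnc.strand):
        hits = [t for t in overlapping.values() if t.strand == wanted]
        if hits:
            partner = max(hits, key=lambda t: (exon_overlap_nt(t), t.id))
            category = "antisense" if wanted != lnc.strand else "sense"
            return LncRNAClass(lnc.id, category, partner.id)

    # no exonic overlap with anything from here on
    for iv in sorted(
        index.span_trees[lnc.chrom].overlap(lnc.start, lnc.end + 1),
        key=lambda iv: iv.data.id,
    ):
        host = iv.data
        if host.id == lnc.id:
            continue
        for (s, e) in host.introns():
            if s <= lnc.start and lnc.end <= e:
                return LncRNAClass(lnc.id, "intronic", host.id)

    best: tuple[int, str] | None = None
    for iv in index.span_trees[lnc.chrom]:
        other = iv.data
        if other.id == lnc.id or other.strand == lnc.strand:
            continue
        if other.start <= lnc.end and lnc.start <= other.end:
            continue  # span overlap -> not bidirectional
        dist = abs(other.five_prime - lnc.five_prime)
        if dist <= bidirectional_max_tss_distance:
            if best is None or (dist, other.id) < best:
                best = (dist, other.id)
    if best is not None:
        return LncRNAClass(lnc.id, "bidirectional", best[1], tss_distance_nt=best[0])

    return LncRNAClass(lnc.id, "intergenic")


def classify_all_lncrnas(
    annotation: Sequence[TranscriptModel],
    bidirectional_max_tss_distance: int = 1000,
) -> dict[str, LncRNAClass]:
    """Classify every lncRNA in the annotation against all transcripts."""
    index = AnnotationIndex(annotation)
    return {
        t.id: classify_lncrna(t, index, bidirectional_max_tss_distance)
        for t in annotation
        if t.biotype == "lncRNA"
    }


def filter_lncrna_candidates(
    lncrnas: Sequence[TranscriptModel],
    records: Mapping[str, ExpressionRecord],
    min_length_nt: int = 1000,
    de_log2: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Drought-responsive lncRNA screen: length > cutoff AND |log2| >= cutoff.

    Returns the (up, down) partition of the retained set; a feature passing
    in both directions is assigned by its largest-magnitude ratio.
    """
    up: set[str] = set()
    down: set[str] = set()
    for lnc in lncrnas:
        if lnc.length_nt <= min_length_nt:
            continue
        rec = records.get(lnc.id)
        if rec is None:
            raise KeyError(f"no expression record for lncRNA {lnc.id!r}")
        defined = [v for v in rec.log2.values() if v is not None]
        if not defined:
            continue
        extreme = max(defined, key=abs)
        if abs(extreme) >= de_log2:
            (up if extreme > 0 else down).add(lnc.id)
    return up, down
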