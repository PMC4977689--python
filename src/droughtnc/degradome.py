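"""Degradome (PARE) tag mapping and cleavage-site validation.

miRNA-guided slicing cuts the target between the bases paired with miRNA
positions 10 and 11, so the uncapped 3' decay fragment — what a PARE tag
sequences — starts exactly at ``t10``. A predicted duplex is *validated*
when at least one library holds a tag whose 5' end maps to ``t10``
(optionally within a small window for noisy data; the default is strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .annotation import DegradomeTag, as_rna
from .targets import DuplexAlignment

#: positions -> library -> support count
TagMap = dict[int, dict[str, int]]


@dataclass(frozen=True)
class CleavageEvidence:
    mirna_id: str
    target_id: str
    cleavage_position: int | None  # t10; None when miRNA base 10 was bulged
    per_library_counts: dict[str, int]
    validated: bool


def map_tags(
    tags: Iterable[DegradomeTag],
    transcript_seq: str,
    count_mode: str = "distinct",
) -> TagMap:
    """Map tag 5' ends onto a transcript.

    A tag supports position ``p`` iff the tag (T->U) equals the transcript
    substring starting at ``p`` of the tag's length; every occurrence counts.
    ``count_mode='distinct'`` counts distinct tag sequences per library
    (the default, matching the small per-library integers of published
    validation tables); ``'reads'`` sums raw tag counts.
    """
    if count_mode not in ("distinct", "reads"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    seq = as_rna(transcript_seq)
    seen: dict[tuple[int, str], set[str]] = {}
    out: TagMap = {}
    for tag in tags:
        query = tag.sequence.replace("T", "U")
        start = seq.find(query)
        while start != -1:
            pos = start + 1  # 1-based transcript-local
            libs = out.setdefault(pos, {})
            if count_mode == "distinct":
                key = (pos, tag.library_id)
                distinct = seen.setdefault(key, set())
                if tag.sequence not in distinct:
                    distinct.add(tag.sequence)
                    libs[tag.library_id] = libs.get(tag.library_id, 0) + 1
            else:
                libs[tag.library_id] = libs.get(tag.library_id, 0) + tag.count
            start = seq.find(query, start + 1)
    return out


def validate_cleavage(
    candidate: DuplexAlignment, tag_map: TagMap, window: int = 0
) -> CleavageEvidence:
    """Evidence for a predicted duplex from a transcript's tag map.

    Per-library counts are summed over positions within ``t10 +/- window``.
    A candidate whose miRNA base 10 is bulged has no defined cleavage site
    and is reported unvalidatable (``validated=False``), not an error.
    """
    if window < 0:
        raise ValueError(f"negative window {window}")
    if candidate.t10 is None:
        return CleavageEvidence(
            mirna_id=candidate.mirna_id,
            target_id=candidate.target_id,
            cleavage_position=None,
            per_library_counts={},
            validated=False,
        )
    counts: dict[str, int] = {}
    for pos in range(candidate.t10 - window, candidate.t10 + window + 1):
        for lib, n in tag_map.get(pos, {}).items():
            counts[lib] = counts.get(lib, 0) + n
    return CleavageEvidence(
        mirna_id=candidate.mirna_id,
        target_id=candidate.target_id,
        cleavage_position=candidate.t10,
        per_library_counts=counts,
        validated=any(n >= 1 for n in counts.values()),
    )


def summarize_validations(
    evidences: Iterable[CleavageEvidence],
) -> tuple[int, int]:
    """(number of validated cleavages, number of distinct guiding miRNAs)."""
    validated = [e for e in evidences if e.validated]
    return len(validated), len({e.mirna_id for e in validated})
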