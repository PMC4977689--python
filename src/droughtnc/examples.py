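"""Canonical worked example: rice drought-responsive miRNA/target duplexes.

These are published rice RPKM profiles, duplex sequences and degradome tags
for drought-responsive miRNAs (control plus 1/2/3 days of drought), used as
a small built-in dataset for demonstrations and regression checks. Duplex
miRNA sequences are printed 3'->5' in the usual ladder orientation and are
reversed on ingestion so the package always works 5'->3'.

The fixture transcript built by :func:`mir399k_fixture_transcript` is
synthetic: only the published target window (positions 737-757) and the ten
bases after it are real; the rest is deterministic filler.
"""

from __future__ import annotations

from .annotation import DegradomeTag, MatureMiRNA

#: RPKM profiles over (C, 1d, 2d, 3d) with their published 2-dp log2 ratios.
RPKM_EXAMPLES: dict[str, dict] = {
    "miR-399k": {
        "rpkm": (119_291, 99_410, 1_530_906, 3_519_097),
        "log2": (-0.26, 3.68, 4.88),
    },
    "Os05g0557700-01": {
        "rpkm": (25_889, 23_611, 8_802, 9_104),
        "log2": (-0.13, -1.56, -1.51),
    },
    "miR-171f-3p": {
        "rpkm": (8_297, 82_972, 107_863, 207_429),
        "log2": (3.32, 3.70, 4.64),
    },
}

#: miR-399k as printed in duplex ladders (3'->5').
MIR399K_PRINTED_3TO5 = "GCCCCGUUUAAAGGAAACCGU"

#: the same mature miRNA stored 5'->3'.
MIR399K = MatureMiRNA(
    id="miR-399k", sequence=MIR399K_PRINTED_3TO5[::-1], precursor_id="pre-miR399k"
)

MIR399K_TARGET_ID = "Os05g0557700-01"
#: target window (transcript-local, 1-based inclusive) and its sequence 5'->3'
MIR399K_WINDOW = (737, 757)
MIR399K_WINDOW_SEQ = "CUGGGCAAAUCUCCUUUGGCA"
#: expected cleavage site: target base paired with miRNA base 10
MIR399K_T10 = 748

#: the published PARE tag supporting the cleavage (DNA, as sequenced), and
#: the libraries that contain it (support pattern 0/0/1/1 over A-D).
MIR399K_PARE_TAG = "TCCTTTGGCAAAATACCTAT"
MIR399K_PARE_LIBRARIES = ("C", "D")

PARE_LIBRARY_IDS = ("A", "B", "C", "D")


def mir399k_fixture_transcript(length: int = 800) -> str:
    """A synthetic transcript carrying the miR-399k site at positions 737-757.

    Positions 737-757 hold the published target window and 758-767 the
    remainder of the published PARE tag, so the tag's 5' end maps exactly to
    the cleavage position 748. Filler is a fixed 4-base repeat that cannot
    recreate the tag elsewhere.
    """
    window_start, window_end = MIR399K_WINDOW
    tail_after_window = "AAAUACCUAU"  # tag bases 11-20 (T->U)
    min_len = window_end + len(tail_after_window)
    if length < min_len:
        raise ValueError(f"fixture length must be >= {min_len}")
    filler = "AGCU"
    prefix = (filler * (window_start // 4 + 1))[: window_start - 1]
    seq = prefix + MIR399K_WINDOW_SEQ + tail_after_window
    seq += (filler * (length // 4 + 1))[: length - len(seq)]
    return seq


def mir399k_pare_tags() -> list[DegradomeTag]:
    """The published supporting tag, one record per library that holds it."""
    return [
        DegradomeTag(sequence=MIR399K_PARE_TAG, library_id=lib, count=1)
        for lib in MIR399K_PARE_LIBRARIES
    ]
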