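"""Genomic feature model and file I/O shared by every pipeline stage.

Coordinates are GFF3-style throughout: 1-based, inclusive, strand ``+``/``-``.
Transcript-local positions are 1-based from the transcript 5' end over the
spliced sequence. Transcripts and mature miRNAs are RNA (``ACGU``); degradome
tags are DNA as sequenced (``ACGT``) and are mapped T->U only at comparison
time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

RNA_BASES = frozenset("ACGU")
DNA_BASES = frozenset("ACGT")

#: GFF3 feature types accepted as transcripts, mapped to internal biotypes.
_TRANSCRIPT_TYPES = {
    "mRNA": "coding",
    "transcript": "coding",
    "pre_miRNA": "pre_miRNA",
    "miRNA_primary_transcript": "pre_miRNA",
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
}
_BIOTYPE_TO_GFF = {"coding": "mRNA", "pre_miRNA": "pre_miRNA", "lncRNA": "lnc_RNA"}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def as_rna(seq: str) -> str:
    """Uppercase and convert a DNA/RNA string to the RNA alphabet (T->U)."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - RNA_BASES
    if bad:
        raise ValueError(f"non-RNA character(s) {sorted(bad)} in sequence")
    return out


def as_dna(seq: str) -> str:
    """Uppercase and convert an RNA/DNA string to the DNA alphabet (U->T)."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - DNA_BASES
    if bad:
        raise ValueError(f"non-DNA character(s) {sorted(bad)} in sequence")
    return out


def revcomp_rna(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return as_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware transcript with exon structure.

    ``exons`` are 1-based inclusive, sorted ascending and non-overlapping;
    a single-exon transcript has ``exons == ((start, end),)``.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: unknown strand {self.strand!r}")
        if self.biotype not in ("coding", "pre_miRNA", "lncRNA"):
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript has no exons")
        prev_end = None
        for (s, e) in self.exons:
            if e < s:
                raise ValueError(f"{self.id}: exon end {e} < start {s}")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.id}: exon ({s}, {e}) outside transcript span "
                    f"({self.start}, {self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted at {s}")
            prev_end = e

    @property
    def length_nt(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the transcript 5' end."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the transcript 3' end."""
        return self.end if self.strand == "+" else self.start

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, always stored 5'->3' in the RNA alphabet."""

    id: str
    sequence: str
    precursor_id: str = ""
    arm: str = "unspecified"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_BASES
        if bad:
            raise ValueError(
                f"{self.id}: non-RNA character(s) {sorted(bad)} in miRNA sequence"
            )
        if not 19 <= len(self.sequence) <= 25:
            raise ValueError(
                f"{self.id}: mature miRNA length {len(self.sequence)} outside [19, 25]"
            )
        if self.arm not in ("5p", "3p", "unspecified"):
            raise ValueError(f"{self.id}: unknown arm {self.arm!r}")


@dataclass(frozen=True)
class DegradomeTag:
    """One degradome (PARE) tag: sequence as sequenced (DNA), library, read count."""

    sequence: str
    library_id: str
    count: int

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_BASES
        if bad:
            raise ValueError(f"non-DNA character(s) {sorted(bad)} in tag sequence")
        if len(self.sequence) < 15:
            raise ValueError(f"tag length {len(self.sequence)} < 15")
        if self.count < 0:
            raise ValueError(f"negative tag count {self.count}")


class Gff3ParseError(ValueError):
    """Raised for malformed GFF3 input; the message names the line number."""


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read transcript features (with exon children) from a GFF3 file.

    Transcript-like feature types (mRNA/transcript, pre_miRNA /
    miRNA_primary_transcript, lnc_RNA) become :class:`TranscriptModel`;
    ``exon`` features attach via their ``Parent`` attribute. Transcripts
    with no exon children get a single exon spanning their full extent.
    """
    transcripts: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise Gff3ParseError(f"line {lineno}: malformed GFF3 line ({exc})")
            if feat.strand not in ("+", "-"):
                raise Gff3ParseError(
                    f"line {lineno}: unknown strand symbol {feat.strand!r}"
                )
            if feat.end < feat.start:
                raise Gff3ParseError(
                    f"line {lineno}: end {feat.end} < start {feat.start}"
                )
            if feat.featuretype in _TRANSCRIPT_TYPES:
                fid = feat.attributes.get("ID", [None])[0]
                if fid is None:
                    raise Gff3ParseError(f"line {lineno}: transcript without ID")
                if fid in transcripts:
                    raise Gff3ParseError(f"line {lineno}: duplicate transcript {fid}")
                transcripts[fid] = {
                    "chrom": feat.seqid,
                    "start": feat.start,
                    "end": feat.end,
                    "strand": feat.strand,
                    "biotype": _TRANSCRIPT_TYPES[feat.featuretype],
                }
                order.append(fid)
            elif feat.featuretype == "exon":
                parents = feat.attributes.get("Parent", [])
                if not parents:
                    raise Gff3ParseError(f"line {lineno}: exon without Parent")
                for parent in parents:
                    exons.setdefault(parent, []).append((feat.start, feat.end))
    for parent in exons:
        if parent not in transcripts:
            raise Gff3ParseError(f"exon Parent {parent!r} matches no transcript")
    out = []
    for fid in order:
        info = transcripts[fid]
        ex = tuple(sorted(exons.get(fid, []))) or ((info["start"], info["end"]),)
        out.append(
            TranscriptModel(
                id=fid,
                chrom=info["chrom"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                exons=ex,
                biotype=info["biotype"],
            )
        )
    return out


def write_gff3(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts (+ exon children) as GFF3; inverse of :func:`read_gff3`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            ftype = _BIOTYPE_TO_GFF[t.biotype]
            fh.write(
                f"{t.chrom}\tdroughtnc\t{ftype}\t{t.start}\t{t.end}\t.\t{t.strand}"
                f"\t.\tID={t.id}\n"
            )
            for (s, e) in t.exons:
                fh.write(
                    f"{t.chrom}\tdroughtnc\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"Parent={t.id}\n"
                )


def read_fasta(path: str | Path, alphabet: str = "rna") -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict.

    ``alphabet='rna'`` normalises T->U (transcripts, miRNAs); ``'dna'`` maps
    U->T (degradome tags stored as FASTA).
    """
    conv = as_rna if alphabet == "rna" else as_dna
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        out[rec.id] = conv(str(rec.seq))
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mirna_table(path: str | Path) -> list[MatureMiRNA]:
    """Read a mature-miRNA TSV (id, sequence, orientation, precursor_id, arm).

    ``orientation`` is ``5to3`` or ``3to5``; sequences printed 3'->5' (the
    convention of duplex figures) are reversed — not complemented — so the
    stored sequence is always 5'->3'.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sequence", "orientation", "precursor_id", "arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"miRNA table missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        seq = as_rna(str(row.sequence))
        if row.orientation == "3to5":
            seq = seq[::-1]
        elif row.orientation != "5to3":
            raise ValueError(
                f"{row.id}: orientation must be 5to3 or 3to5, got {row.orientation!r}"
            )
        out.append(
            MatureMiRNA(
                id=str(row.id),
                sequence=seq,
                precursor_id="" if pd.isna(row.precursor_id) else str(row.precursor_id),
                arm="unspecified" if pd.isna(row.arm) else str(row.arm),
            )
        )
    return out


def write_mirna_table(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    rows = [
        {
            "id": m.id,
            "sequence": m.sequence,
            "orientation": "5to3",
            "precursor_id": m.precursor_id,
            "arm": m.arm,
        }
        for m in mirnas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-condition count table (first column = feature ids).

    Conditions keep file order. Duplicate ids, negative or missing cells are
    errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature id(s) {dupes} in count table")
    if df.isna().any().any():
        raise ValueError("count table has missing cell(s)")
    try:
        df = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"count table has non-integer cell(s): {exc}")
    if (df.to_numpy() < 0).any():
        raise ValueError("count table has negative count(s)")
    return df


def read_degradome_table(path: str | Path) -> list[DegradomeTag]:
    """Read degradome tags from a TSV with columns sequence, library_id, count."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "library_id": str})
    required = {"sequence", "library_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"degradome table missing column(s) {sorted(missing)}")
    return [
        DegradomeTag(
            sequence=str(r.sequence), library_id=str(r.library_id), count=int(r.count)
        )
        for r in df.itertuples(index=False)
    ]


def write_degradome_table(tags: Iterable[DegradomeTag], path: str | Path) -> None:
    rows = [
        {"sequence": t.sequence, "library_id": t.library_id, "count": t.count}
        for t in tags
    ]
    pd.DataFrame(rows, columns=["sequence", "library_id", "count"]).to_csv(
        path, sep="\t", index=False
    )
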