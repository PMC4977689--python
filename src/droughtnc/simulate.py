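"""Synthetic drought study generator with recorded ground truth.

Emulates the study design every stage of the pipeline expects: a four-library
panel (well-watered control C plus 1/2/3 days of drought), coding genes,
miRNA precursors and lncRNAs laid out on one chromosome, miRNA-complementary
sites embedded in target transcripts, and degradome tag libraries with
signal concentrated at the planted cleavage positions over a uniform
background. Default planted proportions mirror the published study: 24
inducible / 42 repressible pre-miRNAs, 31 up / 67 down lncRNAs (58 antisense
/ 6 bidirectional / 22 intergenic / 5 sense / 7 intronic), 4 degradome
libraries, 32 cleavage sites guided by 21 distinct responsive miRNAs.

Everything is deterministic for a fixed seed, and the planted truth is
serialised as JSON so recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    DegradomeTag,
    MatureMiRNA,
    TranscriptModel,
    as_dna,
    revcomp_rna,
    write_degradome_table,
    write_fasta,
    write_gff3,
    write_mirna_table,
)

CONDITIONS = ("C", "1d", "2d", "3d")
CONTROL = "C"
LIBRARIES = ("A", "B", "C", "D")

DEFAULT_LNCRNA_CATEGORY_COUNTS = {
    "antisense": 58,
    "bidirectional": 6,
    "intergenic": 22,
    "sense": 5,
    "intronic": 7,
}

_BASES = np.array(list("ACGU"))


@dataclass
class SimulationTruth:
    """Everything the generators planted, reloadable bit-identically."""

    seed: int
    de: dict[str, dict] = field(default_factory=dict)
    mirna_sites: list[dict] = field(default_factory=list)
    cleavage_sites: list[dict] = field(default_factory=list)
    lncrna_categories: dict[str, str] = field(default_factory=dict)
    nat_configurations: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        return cls(**json.loads(text))

    def features_with_class(self, cls_name: str, prefix: str = "") -> set[str]:
        return {
            fid
            for fid, info in self.de.items()
            if info["class"] == cls_name and fid.startswith(prefix)
        }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _categories_for(n: int, counts: Mapping[str, int] | None) -> dict[str, int]:
    if counts is not None:
        if sum(counts.values()) != n:
            raise ValueError("lncRNA category counts do not sum to n_lncrna")
        return dict(counts)
    total = sum(DEFAULT_LNCRNA_CATEGORY_COUNTS.values())
    out = {
        k: (v * n) // total for k, v in DEFAULT_LNCRNA_CATEGORY_COUNTS.items()
    }
    out["intergenic"] += n - sum(out.values())
    return out


def generate_annotation(
    n_coding: int = 120,
    n_premirna: int = 66,
    n_lncrna: int = 98,
    seed: int = 0,
    lncrna_category_counts: Mapping[str, int] | None = None,
) -> tuple[list[TranscriptModel], dict[str, str], SimulationTruth]:
    """Lay out coding genes, pre-miRNAs and lncRNAs with known labels.

    lncRNAs of every category are constructed geometrically (antisense ones
    additionally cycle through head-to-head / tail-to-tail / containment
    overlap configurations); the returned truth records each category and
    NAT configuration. Host genes for overlap-defined lncRNAs are drawn from
    the coding budget.
    """
    if min(n_coding, n_premirna, n_lncrna) < 0:
        raise ValueError("feature counts must be >= 0")
    rng = np.random.default_rng(seed)
    cats = _categories_for(n_lncrna, lncrna_category_counts)
    hosts_needed = cats["antisense"] + cats["sense"] + cats["intronic"] + cats[
        "bidirectional"
    ]
    if n_coding < hosts_needed:
        raise ValueError(
            f"n_coding={n_coding} < {hosts_needed} host genes required by the "
            "requested lncRNA categories"
        )
    truth = SimulationTruth(seed=int(seed))
    transcripts: list[TranscriptModel] = []
    chrom = "chr1"
    cursor = 10_000
    gene_i = lnc_i = 0

    def next_gene_id() -> str:
        nonlocal gene_i
        gene_i += 1
        return f"gene{gene_i:04d}"

    def next_lnc_id() -> str:
        nonlocal lnc_i
        lnc_i += 1
        return f"lnc{lnc_i:04d}"

    def add(t: TranscriptModel) -> None:
        transcripts.append(t)

    def advance(max_end: int) -> None:
        nonlocal cursor
        cursor = max_end + int(rng.integers(3000, 6001))

    nat_cycle = ["head_to_head", "tail_to_tail", "containment"]
    for j in range(cats["antisense"]):
        config = nat_cycle[j % 3]
        gid, lid = next_gene_id(), next_lnc_id()
        if config == "head_to_head":
            d1 = int(rng.integers(700, 1001))
            d2 = int(rng.integers(500, 801))
            g_s = cursor + d1
            g_e = g_s + 1999
            lnc = TranscriptModel(lid, chrom, g_s - d1, g_s + d2, "-",
                                  ((g_s - d1, g_s + d2),), "lncRNA")
        elif config == "tail_to_tail":
            d1 = int(rng.integers(700, 1001))
            d2 = int(rng.integers(500, 801))
            g_s = cursor
            g_e = g_s + 1999
            lnc = TranscriptModel(lid, chrom, g_e - d2, g_e + d1, "-",
                                  ((g_e - d2, g_e + d1),), "lncRNA")
        else:  # containment
            g_s = cursor
            g_e = g_s + 3499
            l_s = g_s + int(rng.integers(200, 801))
            l_e = l_s + int(rng.integers(1100, 1601)) - 1
            lnc = TranscriptModel(lid, chrom, l_s, l_e, "-",
                                  ((l_s, l_e),), "lncRNA")
        host = TranscriptModel(gid, chrom, g_s, g_e, "+", ((g_s, g_e),), "coding")
        add(host)
        add(lnc)
        first, second = sorted([host, lnc], key=lambda t: (t.start, t.id))
        truth.lncrna_categories[lid] = "antisense"
        truth.nat_configurations.append(
            {"id_a": first.id, "id_b": second.id, "configuration": config}
        )
        advance(max(host.end, lnc.end))

    for _ in range(cats["sense"]):
        gid, lid = next_gene_id(), next_lnc_id()
        g_s, g_e = cursor, cursor + 1999
        l_s = g_s + int(rng.integers(500, 901))
        l_e = l_s + int(rng.integers(1100, 1501)) - 1
        add(TranscriptModel(gid, chrom, g_s, g_e, "+", ((g_s, g_e),), "coding"))
        add(TranscriptModel(lid, chrom, l_s, l_e, "+", ((l_s, l_e),), "lncRNA"))
        truth.lncrna_categories[lid] = "sense"
        advance(max(g_e, l_e))

    for _ in range(cats["intronic"]):
        gid, lid = next_gene_id(), next_lnc_id()
        lnc_len = int(rng.integers(1100, 1501))
        margin = 50
        intron_len = lnc_len + 2 * margin
        g_s = cursor
        exon1 = (g_s, g_s + 499)
        exon2_start = g_s + 500 + intron_len
        exon2 = (exon2_start, exon2_start + 499)
        l_s = g_s + 500 + margin
        add(TranscriptModel(gid, chrom, g_s, exon2[1], "+", (exon1, exon2), "coding"))
        add(TranscriptModel(lid, chrom, l_s, l_s + lnc_len - 1, "+",
                            ((l_s, l_s + lnc_len - 1),), "lncRNA"))
        truth.lncrna_categories[lid] = "intronic"
        advance(exon2[1])

    for _ in range(cats["bidirectional"]):
        gid, lid = next_gene_id(), next_lnc_id()
        lnc_len = int(rng.integers(1100, 1501))
        l_s = cursor
        l_e = l_s + lnc_len - 1
        tss_gap = int(rng.integers(200, 801))
        g_s = l_e + tss_gap
        add(TranscriptModel(lid, chrom, l_s, l_e, "-", ((l_s, l_e),), "lncRNA"))
        add(TranscriptModel(gid, chrom, g_s, g_s + 1999, "+",
                            ((g_s, g_s + 1999),), "coding"))
        truth.lncrna_categories[lid] = "bidirectional"
        advance(g_s + 1999)

    for _ in range(cats["intergenic"]):
        lid = next_lnc_id()
        lnc_len = int(rng.integers(1100, 1601))
        strand = "+" if rng.integers(2) == 0 else "-"
        add(TranscriptModel(lid, chrom, cursor, cursor + lnc_len - 1, strand,
                            ((cursor, cursor + lnc_len - 1),), "lncRNA"))
        truth.lncrna_categories[lid] = "intergenic"
        advance(cursor + lnc_len - 1)

    for _ in range(n_coding - hosts_needed):
        gid = next_gene_id()
        length = int(rng.integers(1500, 3001))
        strand = "+" if rng.integers(2) == 0 else "-"
        add(TranscriptModel(gid, chrom, cursor, cursor + length - 1, strand,
                            ((cursor, cursor + length - 1),), "coding"))
        advance(cursor + length - 1)

    for i in range(1, n_premirna + 1):
        length = int(rng.integers(120, 181))
        strand = "+" if rng.integers(2) == 0 else "-"
        add(TranscriptModel(f"pre-miR{i:03d}", chrom, cursor, cursor + length - 1,
                            strand, ((cursor, cursor + length - 1),), "pre_miRNA"))
        advance(cursor + length - 1)

    seqs = {t.id: _random_seq(rng, t.length_nt) for t in transcripts}
    return transcripts, seqs, truth


def generate_mirnas(
    n: int = 66, seed: int = 0, length: int = 21
) -> list[MatureMiRNA]:
    """Random mature miRNAs, one per precursor (ids miR001.. / pre-miR001..)."""
    rng = np.random.default_rng(seed)
    return [
        MatureMiRNA(
            id=f"miR{i:03d}",
            sequence=_random_seq(rng, length),
            precursor_id=f"pre-miR{i:03d}",
        )
        for i in range(1, n + 1)
    ]


def plant_de_classes(
    truth: SimulationTruth,
    premirna_ids: Sequence[str],
    lncrna_ids: Sequence[str],
    coding_ids: Sequence[str],
    seed: int = 0,
    n_inducible: int = 24,
    n_repressible: int = 42,
    n_lnc_up: int = 31,
    n_lnc_down: int = 67,
    opposed_targets: Mapping[str, str] | None = None,
) -> SimulationTruth:
    """Assign planted per-timepoint log2 effects and baselines.

    Inducible features get effects of at least +2 log2 at the later
    timepoints (repressible features the mirror image), with baselines of
    500-3000 control counts so the realised ratios sit far from the
    screening thresholds. ``opposed_targets`` maps a coding target id to its
    responsive pre-miRNA id; the target is forced into the opposite
    direction (the planted regulating pairs of the anti-correlation screen).
    """
    rng = np.random.default_rng(seed)
    if n_inducible + n_repressible > len(premirna_ids):
        raise ValueError("more responsive pre-miRNAs requested than exist")
    if n_lnc_up + n_lnc_down > len(lncrna_ids):
        raise ValueError("more responsive lncRNAs requested than exist")

    def effects(sign: int, strong: bool) -> dict[str, float]:
        if strong:  # lncRNA screen uses a 2.0 threshold: stay well above it
            e = (rng.uniform(2.5, 3.0), rng.uniform(3.0, 4.0), rng.uniform(3.0, 4.5))
        else:
            e = (rng.uniform(0.5, 1.5), rng.uniform(2.2, 3.5), rng.uniform(2.5, 4.0))
        return {c: round(sign * v, 4) for c, v in zip(CONDITIONS[1:], e)}

    def baseline() -> int:
        return int(rng.integers(500, 3001))

    for i, fid in enumerate(premirna_ids):
        if i < n_inducible:
            cls, eff = "inducible", effects(+1, strong=False)
        elif i < n_inducible + n_repressible:
            cls, eff = "repressible", effects(-1, strong=False)
        else:
            cls, eff = "constitutive", {c: 0.0 for c in CONDITIONS[1:]}
        truth.de[fid] = {"class": cls, "effects": eff, "baseline": baseline()}

    for i, fid in enumerate(lncrna_ids):
        if i < n_lnc_up:
            cls, eff = "inducible", effects(+1, strong=True)
        elif i < n_lnc_up + n_lnc_down:
            cls, eff = "repressible", effects(-1, strong=True)
        else:
            cls, eff = "constitutive", {c: 0.0 for c in CONDITIONS[1:]}
        truth.de[fid] = {"class": cls, "effects": eff, "baseline": baseline()}

    opposed = dict(opposed_targets or {})
    forced = {}
    for target_id, mir_fid in opposed.items():
        mir_info = truth.de.get(mir_fid)
        if mir_info is None or mir_info["class"] == "constitutive":
            continue
        # the target mirrors its regulator: per-timepoint effects are the
        # miRNA's own, negated, so the pair is anti-correlated by design
        forced[target_id] = {
            "class": (
                "repressible" if mir_info["class"] == "inducible" else "inducible"
            ),
            "effects": {c: round(-v, 4) for c, v in mir_info["effects"].items()},
            "baseline": baseline(),
        }
    for fid in coding_ids:
        if fid in forced:
            truth.de[fid] = forced[fid]
        else:
            truth.de[fid] = {
                "class": "constitutive",
                "effects": {c: 0.0 for c in CONDITIONS[1:]},
                "baseline": int(rng.integers(100, 2001)),
            }
    return truth


def generate_counts(
    feature_ids: Sequence[str],
    truth: SimulationTruth,
    library_sizes: Mapping[str, int] | None = None,
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial counts around baseline x 2^(planted log2 effect).

    ``dispersion`` is the NB overdispersion (variance = mu + d*mu^2);
    0 falls back to Poisson. Unequal ``library_sizes`` scale the means
    relative to the control library so planted effects stay effects on the
    RPKM ratio scale.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if library_sizes is None:
        library_sizes = {c: 1 for c in CONDITIONS}
    ref = library_sizes[CONTROL]
    data = {}
    for fid in feature_ids:
        info = truth.de.get(fid)
        if info is None:
            raise KeyError(f"no planted DE info for feature {fid!r}")
        row = []
        for cond in CONDITIONS:
            effect = 0.0 if cond == CONTROL else float(info["effects"][cond])
            mu = float(info["baseline"]) * 2.0 ** effect * (
                library_sizes[cond] / ref
            )
            if dispersion == 0:
                row.append(int(rng.poisson(mu)))
            else:
                n_param = 1.0 / dispersion
                p_param = n_param / (n_param + mu)
                row.append(int(rng.negative_binomial(n_param, p_param)))
        data[fid] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(CONDITIONS)
    ).rename_axis("feature_id")


def generate_mirna_sites(
    transcripts: Sequence[TranscriptModel],
    seqs: dict[str, str],
    mirnas: Sequence[MatureMiRNA],
    truth: SimulationTruth,
    n_sites: int = 32,
    n_guiding_mirnas: int = 21,
    seed: int = 0,
    max_edits: int = 2,
) -> dict[str, str]:
    """Embed miRNA-complementary sites into coding transcripts.

    Each site is the reverse complement of its miRNA with 0..``max_edits``
    priced edits (non-seed mismatches, 1.0 expectation each); the truth
    records the window, the exact expected t10 and the priced expectation.
    One site per target transcript; sites are assigned round-robin over the
    first ``n_guiding_mirnas`` miRNAs so some guide several cleavages.
    """
    rng = np.random.default_rng(seed)
    guiding = list(mirnas[:n_guiding_mirnas])
    if not guiding:
        raise ValueError("need at least one miRNA to plant sites")
    L = len(guiding[0].sequence)
    candidates = [
        t.id
        for t in transcripts
        if t.biotype == "coding"
        and t.id not in {s["target_id"] for s in truth.mirna_sites}
        and t.length_nt >= L + 120
    ]
    if len(candidates) < n_sites:
        raise ValueError(
            f"only {len(candidates)} transcripts can host the {n_sites} sites"
        )
    chosen = list(rng.choice(np.array(candidates), size=n_sites, replace=False))
    out = dict(seqs)
    for j, target_id in enumerate(chosen):
        mirna = guiding[j % len(guiding)]
        seq = out[target_id]
        if len(seq) < len(mirna.sequence) + 120:
            raise ValueError(f"transcript {target_id} too short for a planted site")
        ws = int(rng.integers(30, len(seq) - len(mirna.sequence) - 60))
        site = list(revcomp_rna(mirna.sequence))
        n_edits = int(rng.integers(0, max_edits + 1))
        # non-seed, non-end miRNA positions -> penalty exactly 1.0 per edit
        edit_positions = rng.choice(
            np.arange(14, len(mirna.sequence)), size=n_edits, replace=False
        )
        for k in sorted(int(p) for p in edit_positions):
            # writing the miRNA's own base opposite itself is always a mismatch
            site[len(mirna.sequence) - k] = mirna.sequence[k - 1]
        site_seq = "".join(site)
        out[target_id] = seq[: ws - 1] + site_seq + seq[ws - 1 + len(site_seq):]
        truth.mirna_sites.append(
            {
                "mirna_id": mirna.id,
                "target_id": str(target_id),
                "window_start": ws,
                "window_end": ws + len(mirna.sequence) - 1,
                "t10": ws + len(mirna.sequence) - 10,
                "n_edits": n_edits,
                "expectation": float(n_edits),
            }
        )
    truth.mirna_sites.sort(key=lambda s: (s["mirna_id"], s["target_id"]))
    return out


def generate_degradome(
    seqs: Mapping[str, str],
    truth: SimulationTruth,
    libraries: Sequence[str] = LIBRARIES,
    signal_tags_per_site: int = 4,
    background_per_kb: float = 1.0,
    tag_length: int = 20,
    seed: int = 0,
) -> list[DegradomeTag]:
    """Degradome tags: signal at every planted t10 plus uniform background.

    Signal tags start exactly at the planted cleavage position and are
    spread across libraries (at least one library per site; with the default
    of 4 tags per site every site is multiply supported). Background tags
    start uniformly at random positions at ``background_per_kb`` per library
    per kb of transcript. Per-library signal counts are recorded in the
    truth.
    """
    rng = np.random.default_rng(seed)
    tags: list[DegradomeTag] = []
    for site in truth.mirna_sites:
        t10 = site["t10"]
        seq = seqs[site["target_id"]]
        if t10 + tag_length - 1 > len(seq):
            raise ValueError(f"tag at {site['target_id']}:{t10} overruns transcript")
        tag_seq = as_dna(seq[t10 - 1 : t10 - 1 + tag_length])
        lib_counts: dict[str, int] = {}
        for _ in range(max(1, signal_tags_per_site)):
            lib = str(rng.choice(np.array(libraries)))
            lib_counts[lib] = lib_counts.get(lib, 0) + 1
        for lib in sorted(lib_counts):
            tags.append(DegradomeTag(tag_seq, lib, lib_counts[lib]))
        truth.cleavage_sites.append(
            {
                "mirna_id": site["mirna_id"],
                "target_id": site["target_id"],
                "t10": t10,
                "per_library_signal": lib_counts,
            }
        )
    for tid in sorted(seqs):
        seq = seqs[tid]
        if len(seq) < tag_length:
            continue
        for lib in libraries:
            n_bg = int(rng.poisson(len(seq) / 1000.0 * background_per_kb))
            for _ in range(n_bg):
                pos = int(rng.integers(1, len(seq) - tag_length + 2))
                tags.append(
                    DegradomeTag(as_dna(seq[pos - 1 : pos - 1 + tag_length]), lib, 1)
                )
    truth.cleavage_sites.sort(key=lambda s: (s["mirna_id"], s["target_id"]))
    return tags


@dataclass
class Bundle:
    """A complete synthetic dataset plus its planted truth.

    ``library_sizes`` records the nominal per-condition sequencing depth the
    counts were generated at (equal depths by default); analyses should
    normalise RPKM against these rather than column sums, which the strong
    planted composition shift would bias.
    """

    transcripts: list[TranscriptModel]
    seqs: dict[str, str]
    mirnas: list[MatureMiRNA]
    counts: pd.DataFrame
    tags: list[DegradomeTag]
    truth: SimulationTruth
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {c: 20_000_000 for c in CONDITIONS}
    )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.gff3",
            "transcripts": outdir / "transcripts.fasta",
            "mirnas": outdir / "mirnas.tsv",
            "counts": outdir / "counts.tsv",
            "degradome": outdir / "degradome.tsv",
            "truth": outdir / "truth.json",
            "config": outdir / "config.yaml",
        }
        write_gff3(self.transcripts, paths["annotation"])
        write_fasta(self.seqs, paths["transcripts"])
        write_mirna_table(self.mirnas, paths["mirnas"])
        self.counts.to_csv(paths["counts"], sep="\t")
        write_degradome_table(self.tags, paths["degradome"])
        paths["truth"].write_text(self.truth.to_json())
        config = {
            "annotation": str(paths["annotation"]),
            "transcripts": str(paths["transcripts"]),
            "mirnas": str(paths["mirnas"]),
            "counts": str(paths["counts"]),
            "degradome": str(paths["degradome"]),
            "outdir": str(outdir / "results"),
            "conditions": list(CONDITIONS),
            "control": CONTROL,
            "library_sizes": {k: int(v) for k, v in self.library_sizes.items()},
            "seed": int(self.truth.seed),
        }
        paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
        return paths


def generate_bundle(
    seed: int = 0,
    n_coding: int = 120,
    n_premirna: int = 66,
    n_lncrna: int = 98,
    n_inducible: int = 24,
    n_repressible: int = 42,
    n_lnc_up: int = 31,
    n_lnc_down: int = 67,
    n_sites: int = 32,
    n_guiding_mirnas: int = 21,
    dispersion: float = 0.05,
    background_per_kb: float = 1.0,
    lncrna_category_counts: Mapping[str, int] | None = None,
) -> Bundle:
    """Generate a full, mutually consistent study with recorded truth."""
    s = int(seed) % (2**31 - 10)
    transcripts, seqs, truth = generate_annotation(
        n_coding, n_premirna, n_lncrna, seed=s, lncrna_category_counts=lncrna_category_counts
    )
    mirnas = generate_mirnas(n_premirna, seed=s + 1)
    seqs = generate_mirna_sites(
        transcripts, seqs, mirnas, truth,
        n_sites=n_sites, n_guiding_mirnas=n_guiding_mirnas, seed=s + 2,
    )
    premirna_ids = [t.id for t in transcripts if t.biotype == "pre_miRNA"]
    lncrna_ids = [t.id for t in transcripts if t.biotype == "lncRNA"]
    coding_ids = [t.id for t in transcripts if t.biotype == "coding"]
    precursor_of = {m.id: m.precursor_id for m in mirnas}
    opposed = {
        site["target_id"]: precursor_of[site["mirna_id"]]
        for site in truth.mirna_sites
    }
    plant_de_classes(
        truth, premirna_ids, lncrna_ids, coding_ids, seed=s + 3,
        n_inducible=n_inducible, n_repressible=n_repressible,
        n_lnc_up=n_lnc_up, n_lnc_down=n_lnc_down, opposed_targets=opposed,
    )
    counts = generate_counts(
        [t.id for t in transcripts], truth, dispersion=dispersion, seed=s + 4
    )
    tags = generate_degradome(
        seqs, truth, background_per_kb=background_per_kb, seed=s + 5
    )
    return Bundle(transcripts, seqs, mirnas, counts, tags, truth)
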