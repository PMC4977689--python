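# droughtnc

Screening drought-responsive noncoding RNAs in plant RNA-seq panels: RPKM /
log2 fold-change expression classes, plant miRNA target duplex search with
expectation scoring, degradome (PARE) validation of cleavage sites at the
duplex 10/11 position, miRNA–target anti-correlation screening, and
lncRNA / cis-natural-antisense-transcript classification.

## Who this is for

The package is aimed at transcriptomics analyses of the classic
drought-stress design: a well-watered control (C) plus several drought
timepoints (here 1d, 2d, 3d), profiled by bulk RNA-seq over coding genes,
miRNA precursors and lncRNAs, with independent degradome (PARE) libraries
available for cleavage validation. Every stage is a plain library function;
a thin `droughtnc` CLI chains them from a YAML config. A synthetic-study
generator with recorded ground truth makes the whole pipeline runnable and
testable offline.

## The screen

- **Expression.** RPKM = count / (length/1000) / (library size/10^6); a
  feature's per-timepoint response is log2(RPKM_treatment / RPKM_control),
  undefined (printed `-`) when either side is zero. A feature is *up* at a
  timepoint when log2 ≥ the class threshold (genes and pre-miRNAs 1.0,
  lncRNAs 2.0 by default), *down* in the mirror case; overall it is
  *inducible* (up somewhere, never down), *repressible*,
  *constitutive high/low*, or *mixed*.
- **Targets.** A miRNA pairs antiparallel to a transcript window (miRNA
  base 1 against the window's 3' base). The expectation score sums
  penalties — match 0, G:U wobble 0.5, mismatch 1, bulged base 2, all
  doubled at miRNA positions 2–13 — and candidates with expectation ≤ 3.0
  are kept (≤ 1 bulge, none at the miRNA ends). Lower is better; 0 is a
  perfect duplex.
- **Degradome.** Slicer cuts its target between the bases paired with
  miRNA positions 10 and 11, so the uncapped 3' decay fragment starts at
  `t10`, the target base paired with miRNA base 10. A candidate is
  *validated* when a PARE tag's 5' end maps exactly there (window 0 by
  default) in at least one library.
- **Anti-correlation.** A cleaving miRNA depletes its target, so the two
  RPKM profiles should oppose: flagged when Pearson r ≤ −0.5 *and* the two
  features carry opposite overall classes.
- **lncRNA / NAT.** lncRNAs are classified (precedence order) as antisense,
  sense, intronic, bidirectional (opposite strand, 5' ends within 1 kb, no
  overlap) or intergenic; opposite-strand span overlaps form cis-NAT pairs
  labelled head-to-head (both 5' ends inside the overlap), tail-to-tail
  (both 3' ends), containment, or other. The drought-responsive lncRNA set
  keeps features > 1 kb with |log2| ≥ 2 at some timepoint.

## Worked example

The package bundles the published rice miR-399k / Os05g0557700-01 duplex,
its PARE tag and the RPKM profiles as a built-in example:

```python
from droughtnc.examples import (MIR399K, MIR399K_WINDOW, RPKM_EXAMPLES,
                                mir399k_fixture_transcript, mir399k_pare_tags)
from droughtnc.targets import align_duplex
from droughtnc.degradome import map_tags, validate_cleavage
from droughtnc.expression import log2_ratio, round_half_away

transcript = mir399k_fixture_transcript()
aln = [a for a in align_duplex(MIR399K, transcript, "Os05g0557700-01")
       if a.window == MIR399K_WINDOW][0]
print("expectation:", aln.expectation, " t10:", aln.t10)

ev = validate_cleavage(aln, map_tags(mir399k_pare_tags(), transcript), window=0)
print("validated:", ev.validated, " per-library tags:", ev.per_library_counts)

rpkm = RPKM_EXAMPLES["miR-399k"]["rpkm"]
print("log2 3d/C:", round_half_away(log2_ratio(rpkm[3], rpkm[0]), 2))
```

prints

```
expectation: 3.0  t10: 748
validated: True  per-library tags: {'C': 1, 'D': 1}
log2 3d/C: 4.88
```

meaning: the duplex over window 737–757 costs 3.0 (one seed mismatch, one
3'-side mismatch), miRNA base 10 pairs target position 748, a degradome tag
starts exactly there in two of the four libraries — evidence of
miRNA-guided cleavage — and the miRNA's 3d response is 2^4.88 ≈ 29-fold up.

The same stages run from the shell on a synthetic study:

```bash
droughtnc simulate --outdir demo --seed 1
droughtnc run --config demo/config.yaml
```

```json
{
 "n_anticorrelated_pairs": 32,
 "n_cis_nat_pairs": 58,
 "n_distinct_mirnas_validated": 21,
 "n_features": 284,
 "n_genes_down_all_timepoints": 19,
 "n_genes_up_all_timepoints": 0,
 "n_inducible_premirna": 24,
 "n_lncrna_down": 67,
 "n_lncrna_up": 31,
 "n_repressible_premirna": 42,
 "n_target_candidates": 32,
 "n_validated_cleavages": 32
}
```

Here every planted signal was recovered: 24 inducible and 42 repressible
miRNA precursors, 31/67 responsive lncRNAs, 58 cis-NAT pairs and 32
degradome-validated cleavages guided by 21 distinct miRNAs. The run also
writes `expression_table.tsv`, `mirna_report.tsv` (RPKM, 2-dp log2 ratios,
duplex window, per-library PARE support, r), `lncrna_report.tsv` and
`summary.json` under the configured output directory.

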