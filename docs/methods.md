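# Methods

## Scope and design

The package re-implements, as a tested library, the screening logic of a
drought time-course noncoding-RNA analysis in rice: a well-watered control
(C) and three drought timepoints (1d/2d/3d) profiled by bulk RNA-seq, with
external degradome (PARE) libraries for cleavage validation. All screening
is threshold-based fold change — no dispersion model and no p-values, which
is faithful to how this kind of screen is actually run on unreplicated
time-course libraries. Coordinates are GFF3-style (1-based, inclusive)
everywhere, including transcript-local positions counted from the 5' end of
the spliced sequence; no silent 0-based conversion happens anywhere, which
is what keeps cleavage positions exact. Transcript-local positions are
interpreted on the spliced transcript, since published duplex windows fall
inside annotated mRNAs.

## Expression

RPKM is count / (length_nt/1000) / (library_size/10^6). The library-size
denominator is an explicit parameter: by default the column sums of the
count table (reads mapped to the annotation), or explicit totals when the
sequencing depth is known — the synthetic bundle records its nominal depths
and analyses should use them, because the planted composition shift
(strongly asymmetric up/down mass) biases column-sum normalisation.

log2 ratios are undefined when either RPKM is 0; no pseudocount is applied
by default (reports print `-`), with an optional epsilon left to the
caller. Reports round half-away-from-zero to 2 decimals; full precision is
kept internally.

Per-class DE thresholds (|log2|): genes 1.0, pre-miRNAs 1.0, lncRNAs 2.0 —
the screen is deliberately more stringent for lncRNAs. Overall classes:
inducible (up at ≥ 1 timepoint, never down), repressible (mirror),
constitutive_high / constitutive_low (unchanged everywhere, mean RPKM above
10,000 / below 1,000 — both cutoffs configurable; the boundary between them
is reported as mixed), mixed otherwise. Timepoints with undefined ratios
never count as unchanged, so a feature seen only under treatment cannot be
called constitutive.

## Target duplex search

The duplex model is the standard plant-miRNA expectation scheme: antiparallel
pairing with miRNA base 1 against the 3'-most window base; penalties
match 0, G:U 0.5, mismatch 1, bulged base 2; everything doubled in the seed
(miRNA positions 2–13); at most one bulge, never at the miRNA ends; default
cutoff expectation ≤ 3.0. These values are configurable
(`ScoringParams`) and are documented assumptions — the scheme reproduces
the worked miR-399k duplex (window 737–757, expectation 3.0, t10 748) but
is not a clone of any web tool's exact scores. A bulged target base between
miRNA positions i and i+1 takes its seed status from position i+1; a bulged
miRNA base from its own position. Ties within a window start prefer fewer
bulges, then smaller t10. Translational-inhibition (central-mismatch)
duplexes are deliberately not modelled: only cleavage-competent duplexes
feed the degradome stage.

The search is vectorised: per window start, each of the 1+(L-2)+(L-1)
configurations (no bulge, miRNA bulge at b, target bulge after i) is a pair
of prefix/suffix sums over penalty diagonals, computed for all starts at
once; only winning windows are reconstructed explicitly. The test suite
holds the search equal to an independently written brute-force enumerator
on short targets.

## Degradome validation

"Cleavage between duplex bases 10 and 11" is operationalised as: the 3'
decay fragment's 5' end sits at t10, the target base paired with miRNA
base 10 counted from the miRNA 5' end — standard slicer geometry, and the
convention that makes the worked example's printed tag, window and position
mutually consistent. Tags are DNA and are mapped T→U before exact substring
matching; every occurrence counts. Validation is strict (window 0) by
default; a symmetric ± window is available for noisy libraries. Per-library
support counts distinct tag sequences by default (published validation
tables print small per-library integers consistent with tag-level counts);
summed read counts are available via `count_mode="reads"`. Candidates whose
miRNA base 10 is bulged have no defined cleavage site and are reported
unvalidatable rather than erroring. Degradome category/T-plot
classification and genome-wide peak calling are out of scope.

## Anti-correlation

With only four conditions a Pearson cutoff alone is noisy, so a pair is
flagged anticorrelated only when r ≤ −0.5 (configurable) *and* the overall
classes oppose (one inducible, one repressible). Mature-miRNA expression is
read from the precursor's record. Profiles with zero variance yield an
undefined r and are reported unflagged. The same operation serves
tissue-panel profiles; nothing assumes time ordering.

## lncRNA and cis-NAT classification

Categories are assigned in precedence order — antisense (exonic overlap,
opposite strand), sense (exonic overlap, same strand), intronic (wholly
inside another transcript's intron, no exonic overlap anywhere),
bidirectional (opposite strand, no span overlap, 5'-end distance ≤ 1 kb
default), intergenic — making them mutually exclusive and exhaustive.
Exonic overlap trumps intronic containment because overlap-defined NAT
examples motivate the taxonomy; the 1 kb bidirectional distance makes
"close genomic proximity" concrete. NAT pairs are detected on transcript
spans (locus-level overlap), while sense/antisense classification uses
exons. Partner choice is deterministic under input permutation (largest
exon overlap, then id; nearest 5' end for bidirectional).

Configuration labels: head-to-head iff the overlap contains both 5' ends,
tail-to-tail iff both 3' ends, containment iff one span nests inside the
other. Note the geometry: configurations are invariant under
reverse-complementing the locus (reflecting coordinates while flipping
strands), but a bare strand flip without reflection turns a divergent pair
into a convergent one — the tests pin down both facts. Identical spans
would satisfy both definitions and are reported head-to-head. trans-NAT
detection and coding-potential assessment are out of scope; biotypes are
taken from the annotation.

The drought-responsive lncRNA filter keeps features with spliced length
> 1000 nt and any timepoint |log2| ≥ 2.0, partitioned up/down by the
largest-magnitude ratio.

## Synthetic study generator

The generator emulates the study design so that every stage can be verified
against recorded truth:

- **Layout.** One chromosome; loci separated by 3–6 kb gaps so that planted
  categories cannot collide. Antisense lncRNAs are built over dedicated
  host genes cycling through head-to-head, tail-to-tail and containment
  geometries; bidirectional lncRNAs sit 200–800 nt upstream of an
  opposite-strand host 5' end; intronic lncRNAs are placed on the host's
  own strand inside a widened intron (an opposite-strand intronic
  transcript would additionally be a span-overlap NAT, which would muddy
  the planted NAT truth); intergenic lncRNAs stand alone. All lncRNAs are
  1.1–1.6 kb so the >1 kb filter is never the discriminating factor.
- **Defaults mirror the published study structure:** 66 pre-miRNAs (24
  inducible / 42 repressible), 98 lncRNAs (31 up / 67 down; 58 antisense,
  6 bidirectional, 22 intergenic, 5 sense, and the 7 uncategorised ones
  planted intronic so all five classes are exercised), 4 degradome
  libraries, and 32 cleavage sites guided by 21 distinct miRNAs.
- **Counts.** Negative binomial around mean = baseline × 2^(planted log2),
  dispersion 0.05 by default (variance μ + dμ²; 0 → Poisson). Baselines are
  500–3000 control counts. Planted responsive effects are ≥ 2.2 log2 at the
  later timepoints (pre-miRNAs) and ≥ 2.5 at every timepoint (lncRNAs,
  screened at the stricter 2.0 cutoff), so recovery margins are several
  noise standard deviations — the point of the defaults is that a correct
  implementation recovers essentially everything, making any systematic
  loss visible. Planted regulating targets take their miRNA's own effects
  negated, which makes the anti-correlation of true pairs structural.
- **Sites and degradome.** Planted sites are reverse complements of their
  miRNA with 0–2 priced edits (non-seed mismatches, exactly 1.0 expectation
  each), one site per target transcript; truth records window, t10 and
  price. Signal tags start exactly at each planted t10 (4 per site spread
  over the libraries); background tags start uniformly at random at
  1 tag/kb/library by default.

Everything is deterministic per seed, and the truth serialises to JSON
bit-identically. What the generator does *not* emulate: read-level noise
(mapping, positional bias within degraded transcripts), splice isoforms,
multi-mapping between homologous family members, and compositional
normalisation artifacts beyond the recorded library sizes — so passing
recovery tests demonstrate correctness of the screening logic, not
robustness to those real-data effects.

## Problem sizes and numerics

The default synthetic study (284 transcripts, ~1.5 Mb of transcript
sequence, ~1800 tags) runs the full pipeline in well under a minute on one
core; the acceptance script and test suite use that size, plus a 50-transcript
degradome experiment and 100 short random duplex-oracle cases. Score
comparisons use exact dyadic arithmetic (all penalties are multiples of
0.25, so float sums are exact); the only tolerance anywhere is a 1e-9 guard
on vectorised-sum comparisons. Report rounding is half-away-from-zero,
matching how such tables are conventionally printed.

## Known limitations

- The expectation scheme's absolute values are package conventions; use the
  cutoff comparatively, not as a cross-tool score.
- Degradome validation treats any single tag as sufficient evidence
  (window 0); there is no abundance-relative (T-plot style) category call.
- The anti-correlation screen with n = 4 conditions is a filter, not a
  test; r carries no significance.
- Dataset-level headline counts of the original study (e.g., 113 detected
  pre-miRNAs) depend on its sequencing libraries and cannot be reproduced
  offline; the planted-truth recovery runs are the package's acceptance
  surface instead, with matching planted proportions.
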