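# Methods

## Problem and model

A CpG island is treated as a unit of prediction.  Its methylation state is
summarized two ways from bisulfite data: a continuous intensity in
[0, 100] (percent methylation averaged over samples per CpG, then over the
island's CpG dinucleotides) and a binary label — methylated when the
intensity is ≥ 50, unmethylated when ≤ 10, excluded otherwise.  Islands
with at most 10% of their CpGs annotated are dropped; the coverage filter
is applied per tissue, since annotation density differs between tissues.
Both cutoffs are inclusive.

The classifier is a soft-margin RBF-kernel SVM on a PCA-reduced feature
space.  One trained model produces both outputs: the binary call is the
SVM class decision, and the continuous intensity is 100 × the
Platt-calibrated probability of the methylated class.  The two outputs are
deliberately not forced to agree (the class decision uses the margin, the
intensity the calibrated posterior); near the boundary they can differ.

## Island detection

Islands are defined by the Gardiner–Garden criteria on non-repetitive
sequence: length ≥ 200 bp, GC ≥ 0.5, observed/expected CpG
ratio = (#CpG·L)/(#C·#G) ≥ 0.6, with N positions excluded from L and from
the base counts.  The criteria only constrain what an island is, not how
to scan for one, so the detector fixes one reproducible procedure: slide a
200-bp window at step 1, mark windows passing all three criteria, merge
windows whose intervals overlap or touch, then — if the merged region
itself fails a criterion — greedily trim 1 bp at a time from whichever end
leaves the region closer to passing (ties trim the left end), stopping as
soon as the region passes; regions that cannot reach the thresholds above
the minimum length, or that intersect the repeat mask, are discarded.
Every emitted island therefore re-passes all three criteria
(an invariant the tests check).  Externally supplied island tracks (e.g.
browser extracts) bypass detection; their attributes are recomputed from
sequence but the thresholds are not enforced on them.

## Feature space

Nine families, 841 columns under the default manifest:

| family | count | notes |
|---|---|---|
| general attributes | 3 | length, GC, O/E ratio, recomputed from sequence |
| tetramer frequencies | 256 | overlapping counts / valid 4-windows |
| tetramer z-scores | 256 | maximal-order Markov model, see below |
| conserved TFBS | 230 | 115 groups × (count, mean score) |
| conserved elements | 2 | count, mean score |
| DNA conformation | 6 | island mean of each dinucleotide step table |
| nucleosome | 4 | occupancy mean/sd, 147-bp fragment potential mean/sd |
| gene function | 2 | oncogene / tumor-suppressor promoter indicators |
| histone methylation | 46 | 23 tracks × (mean, sd of tag counts) |
| histone acetylation | 36 | 18 tracks × (mean, sd) |

Word statistics use *overlapping occurrence counts*, not normalized
frequencies; the z-score

    Z(w) = (O(w) − E(w)) / σ(w),
    E(w) = O(N₁N₂N₃)·O(N₂N₃N₄)/O(N₂N₃),
    σ²(w) = E(w)·[O(N₂N₃)−O(N₁N₂N₃)]·[O(N₂N₃)−O(N₂N₃N₄)]/O²(N₂N₃)

is scale-consistent under that reading (on long i.i.d. sequence the 256
z-scores are approximately standard normal, a property the tests check
against a brute-force reimplementation).  Degenerate cases are mapped to
defined numbers so the matrix never contains missing values: a zero
shared-dimer count gives E = σ = Z = 0; σ = 0 with O = E gives Z = 0;
σ = 0 with O ≠ E gives sign(O−E)·Z_cap with Z_cap = 10 by default
(bounded, deterministic, configurable).  Windows containing N are skipped
and excluded from the valid-window totals.

Interval features use half-open overlap on 0-based coordinates throughout.
The flanking length for TFBS/element features is a single configurable
value (default 500 bp), keeping the 841-column contract; sweeping flank
lengths produces one matrix per flank for model comparison rather than a
concatenated feature space.  Empty overlap yields (0, 0) — count zero and
average score zero.  All standard deviations are population (divide by n)
standard deviations: the features are descriptive summaries of a fixed
stretch, not estimators of a sampled quantity.  Per-nucleotide track
summaries treat uncovered positions as zero (tag absence = zero tags).
The fragment track stores at position s the positioning potential of
[s, s+147); fragments overlapping an island are those with
s ∈ [start−146, end), clipped at the contig origin.

The six dinucleotide conformational tables ship as representative B-DNA
helical step parameters in an editable TSV (regenerated into every
synthetic bundle); they are placeholders in the synthetic setting — any
published parameter set can be substituted — and the tests exercise the
averaging logic with custom tables, so the shipped values are not
load-bearing.

## Feature selection

Screening routes by feature type: Fisher's exact test for the two binary
gene-function indicators (their contingency tables have tiny expected
counts), Pearson χ² for the count-valued TFBS/element features, and the
two-sample Kolmogorov–Smirnov test (asymptotic two-sided p) for every
other numeric feature.  χ² categories are the distinct count values;
values with fewer than 5 total occurrences are pooled into an "other"
row, and rows are further pooled smallest-first until all expected cells
are ≥ 1; tables that degenerate to one row or column make the feature
non-selectable (p = 1), as do constant features.  The retention rule is a
raw p < 0.05 with no multiplicity correction — deliberately, to preserve
the original protocol; at α = 0.05 about 5% of pure-noise features come
along, which the planted-signal tests quantify.

Retained features are standardized to zero mean, unit sd (constant
features dropped with a warning — standardization is necessary because
feature scales span orders of magnitude, lengths vs. probabilities) and
rotated by full-SVD PCA.  The component count k is the smallest prefix
whose cumulative explained-variance ratio reaches the threshold (default
0.999), with a 1e-9 tolerance against floating-point round-down of the
cumulative sum.  The stored standardization and rotation transfer
unchanged to unseen data (held-out folds, other tissues).

Two protocols are provided: the default `strict` mode refits screening
and PCA inside every training split, so no held-out information leaks
into selection; `paper` mode fits them once on the full training tissue
before partitioning, mirroring the original two-step global procedure.
Both are reported where they matter; large planted-signal runs use
`paper` mode, whose single selection fit makes 200-fold ablation studies
cheap, and whose optimistic bias is immaterial when the planted signal is
strong.

## Training and evaluation

Hyperparameters (cost, kernel width) are chosen by an inner stratified
3-fold grid search on the training split only.  The `train()` defaults
are the wide grids C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (step 2²); the
repeated-CV driver uses the coarser C ∈ 2^{−1..9}, γ ∈ 2^{−9..1} so a
full 10-fold × 20-repeat × 2-variant study runs in minutes on one core —
the grids are arguments, so any study can widen them.

Metrics: SP = correct negatives / negatives, SE = correct positives /
positives, ACC = correct / all (per fold, ACC equals the class-weighted
average of SP and SE — an identity the tests assert), and CC = Pearson
correlation between predicted and true **intensities** (the continuous
reading; correlating against binarized status is a coarser alternative
and the intensity version is primary).  Folds lacking one class skip the
undefined SP or SE with a logged count.

Cross-validation stratifies folds by class by default ("approximately
equally sized" is preserved: 469 islands in 10 folds gives sizes 46/47);
plain random partitioning is available.  Each repeat draws a fresh seeded
partition; everything downstream of the seed is deterministic, so the
same seed reproduces a report bit for bit.

The 16 ablation variants: M1 excludes nothing; M2 excludes both histone
categories; M3–M9 exclude the 7 non-empty subsets of {acetylation, gene
function, nucleosome}; M10–M16 exclude the same subsets plus histone
methylation.  Excluded categories are removed *before* screening, so
selection cannot smuggle them back in.

Generalizability: every fold-trained pipeline (selection + SVM) from the
training tissue is applied unchanged to another tissue's islands and the
metrics are averaged over all those models.  For histone-bearing variants
the other tissue's features are extracted with the training tissue's
histone tracks (histone marks correlate well across cell types, and
per-tissue chromatin data is exactly what one wants to avoid needing).

## Synthetic data generator

The generator emulates the *structure* of a multi-tissue bisulfite study,
not its biology: CpG islands (300–800 bp, GC near 0.56, CpG-enriched,
rejection-sampled to pass the detection criteria with margin) embedded in
AT-rich background on one synthetic contig, plus GC-rich decoy segments
covered by the repeat mask.  The island GC band is kept deliberately
narrow and close to the 0.5 criterion: the further an island's GC exceeds
the threshold, the further a detected region can extend into background
before failing the criteria, and sharp boundaries are what make the
≥ 95% recovery / ≥ 0.8 reciprocal-overlap self-check meaningful.

Island intensities are bimodal Beta draws scaled to [0, 100] with means
3 and 92 and sd ≈ 6 — far from the 10/50 cutoffs, resampled when within
1.5 of a cutoff — so that island labels are exactly recoverable from
calls carrying bounded (±3) per-call noise; this makes the label-recovery
check exact rather than statistical, and boundary behaviour is tested
separately with explicit values.  Twelve default tissues share a latent
consensus class per island; the first tissue matches consensus exactly,
somatic tissues flip labels with probability 0.01, and one designated
divergent tissue (named for the germline sample that motivates it) flips
with probability 0.08, which qualitatively reproduces the observed
pattern: high inter-somatic intensity correlations and a differential
count matrix dominated by the divergent tissue.

Class-conditional signal is planted through the tracks: each histone mark
gets a per-mark baseline ~U(1, 4) and island-level values shifted by
(effect size) × (within-class sd = 1) for methylated islands, written as
two half-island steps (±20%) so the sd features are informative too.
Default effect sizes are 3.0 for both histone categories and 0 for
nucleosome and TFBS — one strong, maskable signal family (the M2 ablation
removes exactly the informative categories) against otherwise null
features.  Sequence composition does not differ by class, so the 512
composition features act as realistic correlated noise for the screening
step.  All randomness flows from one integer seed; outputs are
fixed-precision text, so a seed reproduces a bundle byte for byte.

What passing tests on this generator do **not** show: performance on real
bisulfite data (real chromatin tracks are spatially autocorrelated, real
island intensities are not cleanly bimodal, and real feature families are
inter-correlated in ways the generator does not model).  The published
absolute performance of this model family on the human CD4 data is not
reproducible here, since it requires the original bisulfite, ChIP-seq and
annotation tracks; the test suite therefore checks structural claims,
formula-level oracle agreement, and qualitative signal-recovery and
ablation behaviour at stated tolerances.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; a CpG position is the C
  of the dinucleotide on the forward strand.
* Readers reject rather than repair: inverted BED coordinates,
  overlapping bedGraph steps, out-of-range or duplicate methylation calls
  are errors.
* Non-ACGTN FASTA characters map to N with a logged warning; N windows
  are skipped in word counts, N positions excluded from GC/O-E.
* All-N sequences, islands without CpGs, single-class training data and
  empty retained-feature sets raise explicit errors.
* Feature matrices round-trip through TSV at 12 significant digits.
* Run sizes used by the shipped acceptance run — 400 islands, 10 × 20
  folds, two variants, paper-mode selection, the coarse CV grid — were
  chosen as the smallest study at which the planted-signal contrasts are
  unambiguous.

## Known limitations

* The detector's trim rule is one admissible reading of window-based
  scanning; other merge/trim conventions shift boundaries by up to about
  one window.
* The χ² pooling rule is likewise one fixed convention.
* Interval-overlap queries are linear scans per group; adequate at
  synthetic scale, an interval index would be the first optimization for
  genome-scale track sets.
* `SVC(probability=True)` couples the class decision and the calibrated
  intensity to one estimator by design; sklearn deprecates this coupling,
  and a future version will need an explicit calibration wrapper.
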