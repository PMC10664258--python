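# Methods

`atacsim` studies how correlation and association statistics behave when
comparing binned chromatin-accessibility signal between replicates whose
true degree of agreement is known by construction. This note documents the
model, the defaults and why they are what they are, and what the synthetic
data does and does not capture.

## Signal representation: integer WFpkm tracks

Each sample is a set of *fragments* — the template span of one properly
paired read, counted once. The genome is partitioned per chromosome into
contiguous half-open bins of 10 kb laid from coordinate 0; the terminal
bin of each chromosome is truncated at the chromosome end and normalized
by its actual length. A fragment increments every bin it overlaps (the
default assignment policy; full-containment and midpoint assignment are
available for sensitivity analysis — midpoint assignment is the one
policy under which bin counts sum exactly to the library size). Counts
are standardized to fragments per kilobase of bin per million library
fragments (FPKM) and **rounded up** to the nearest whole integer, giving
whole fragments per kilobase per million (WFpkm). Two consequences of the
ceiling matter throughout:

* a bin's WFpkm is zero exactly when its raw count is zero, so the
  *co-zero* definition (both samples zero in a bin) is identical on the
  raw and standardized scales;
* every bin whose FPKM falls in (0, 1] collapses to WFpkm 1. In real
  libraries the genome-wide background falls in this interval, so the
  bulk of bins form a constant block at 1 and the informative structure
  lives in the co-zero bins and the strong peak bins. This quantization
  regime is load-bearing for everything below.

WFpkm conversion is computed in exact integer arithmetic
(`ceil(c * 1e9 / (len_bp * lib))` as an integer division) so
integer-valued FPKM is never perturbed by floating-point rounding.

## The seven statistics

On the paired WFpkm vectors of two samples, with co-zero bins either
retained or removed:

* **Pearson's R**, **Spearman's rho** (Pearson on mid-ranks) and
  **Kendall's tau-b** (tie-adjusted) via `scipy.stats`. Tau-b is used
  because integer WFpkm data are tie-heavy.
* **Top-Down correlation**: Savage scores `S_i = sum_{j>=i}^{n} 1/j` are
  assigned with rank 1 = largest value and tie groups receiving the mean
  score of their rank span (scores always sum to n); the statistic is the
  classical raw-product form `r_T = (sum S(x_i) S(y_i) - n)/(n - S_1)`
  with `S_1` the n-th harmonic number. For untied data this equals the
  Pearson correlation of the two Savage-score vectors; under heavy ties
  the tie-averaged scores shrink it toward zero, so the self-correlation
  of a tie-heavy vector is below 1. The raw-product form was chosen over
  a centered (Pearson-of-scores) form deliberately: bottom-ranked
  observations have scores near zero and contribute almost nothing to the
  product, which is what "down-weighting the smallest values" means
  operationally, whereas centering hands the co-zero block large
  leverage. A first-order identity worth knowing: removing a bottom tie
  block of mass z shifts every remaining Savage score by the harmonic
  tail `-ln(1-z)`, giving `r_retained ≈ r_removed + z(1 - r_removed)`.
  The statistic is therefore *nearly*, but not exactly, co-zero
  insensitive: the shift is z times the distance to 1.
* **R²** is the square of Pearson's R.
* **Kendall's W** (coefficient of concordance, custom implementation with
  the standard tie correction `T_j = sum(t³ - t)`), which accepts m ≥ 2
  rankings; for two untied rankings `W = (rho + 1)/2` exactly, an
  identity the tests exploit.
* **Normalized mutual information** treating integer WFpkm values as
  categorical labels, normalized by the arithmetic mean of the two
  Shannon entropies (natural log), via scikit-learn. Degenerate inputs
  follow the convention that two constant vectors are perfectly
  associated (1.0) and a constant vector is uninformative about a varying
  one (0.0). Min/max/geometric normalizations are exposed as options.

Statistics that are undefined on an input (constant vector for the
correlation measures) raise a typed error instead of returning NaN — a
silent NaN would corrupt the area-under-curve integration downstream.

## Synthetic replicate pairs with a designed shared-peak fraction

A parent fragment set is duplicated into two sister replicates. Given the
parent's reproducible peaks, a designed fraction p of peaks is left
untouched in both copies; each remaining *varied* peak is assigned to one
replicate by fair coin and depleted there by removing
`round(rate * n)` of its n overlapping fragments (rate 0.85 by default;
0.50 and 0.95 are the standard alternatives). The sweep runs p over
{0.99, 0.95, 0.90, ..., 0.05} (twenty points).

Randomness is structured so the sweep axis stays autocorrelated rather
than resampled per fraction: one permutation of the peaks is drawn per
simulation and the varied set at fraction p is its first
`round((1-p) N)` entries (so varied sets are nested along the grid, with
a floor of one varied peak when `(1-p) N` rounds to zero); and each
fragment carries one uniform removal key per simulation, a varied peak
dropping its lowest-keyed fragments. A peak varied at two fractions
therefore loses exactly the same fragments at both, and fragments outside
the varied peaks are bit-identical across parent and both replicates.
Fragment-to-peak assignment uses the fact that reproducible peaks are
disjoint; a fragment can be removed at most once.

Per repeat and fraction, both replicates are binned and the full 7 × 2
statistic suite computed. Everything is reproducible bit-for-bit from the
design seed.

## Curves, normalized AUC, and resampling inference

Each simulation yields one curve of statistic value versus shared
fraction per statistic and policy. Its summary is the trapezoidal area
under the curve divided by the span of the fraction grid (*normalized*
AUC): a constant curve at c scores exactly c and the identity curve
scores the grid midpoint 0.52, which makes AUCs comparable to the
identity benchmark. Mean AUCs across simulations carry 95% percentile
bootstrap confidence intervals (1000 resamples). Differences of mean AUC
— between statistics, or within a statistic across co-zero policies — are
tested by pooled label permutation (1000 permutations, two-sided via
absolute differences), with p reported as an exact proportion (0 is
possible; a (k+1)/(n+1) correction is available behind a flag). The
permutation draw is canonicalized (sorted pool, smaller group first) so
the p-value is exactly invariant to swapping the group labels.

## Synthetic parent samples

The generator emulates the statistical structure of real bulk ATAC-seq
libraries with three controlled features: a FrIP (fraction of fragments
in peaks) targeted at 0.50, the middle of the 0.34–0.72 range typical of
acceptable libraries; inaccessible blocks covering 5% of the genome that
receive no fragments at all (fragments are truncated at block
boundaries), which is the mechanism producing the few-percent co-zero
bins seen between real replicate pairs; and fragment lengths drawn from a
nucleosome-free / mono- / di-nucleosome Gaussian mixture
(80/200/400 bp at weights 0.50/0.35/0.15). Per-peak intensities are
negative-binomial with shape 0.15 — strongly over-dispersed, because real
peak heights span orders of magnitude — and allocated by a multinomial
draw so the peak total is exact; the peak/background split is corrected
for background fragments that land inside peaks so the realized FrIP
tracks the target.

Default scale: two chromosomes of 1.25 Gb (250k bins at 10 kb), 100k
peaks of 500–2000 bp, 2.5 million fragments. The genome is
gigabase-scale on purpose. The ratio of the WFpkm-1 count threshold to
the mean background count per bin equals `genome_bp / (bg_fraction × 1e9)`
— independent of bin size and library size — so only a genome of roughly
a gigabase or more puts the background below the ceiling threshold where
it quantizes to a constant 1, the regime real data occupy. On a toy
10 Mb genome the background instead lands at WFpkm ≈ 25 with visible
sampling variance that is identical in both sisters, which props every
statistic up and suppresses all co-zero effects; such configs remain
available (and are used) for structural and plumbing tests, but no
statistical conclusion should be drawn from them. At the default scale a
single sweep repeat (20 fractions, both policies, all seven statistics)
takes ~10 s on one CPU; the full study design used by the tests and the
acceptance script (3 parents × 5 repeats) runs in about three minutes.

What the generator does not model: sequencing error, duplicate reads,
Tn5 insertion bias, GC/mappability structure, inter-replicate background
variation (sisters share the parent's background exactly, as in the
down-sampling design itself), and negative correlation between samples.
Passing tests therefore demonstrate the statistics' behaviour under the
designed perturbation, not performance on any particular real library.

## Observed behaviour at the default scale

With 15 simulations (3 parents × 5 repeats) at depletion rate 0.85, all
statistic curves increase monotonically in the shared fraction on
average. Removing co-zeros significantly lowers the mean AUC of Pearson,
Spearman, tau, W, R² and NMI (permutation p = 0 at 1000 permutations),
leaving NMI's removed-policy mean AUC closest of the association
statistics to the identity value 0.52. With co-zeros retained, Kendall's
W has the largest mean AUC and Top-Down the smallest. Top-Down's mean
AUC shifts by ≈ 0.03 under co-zero removal — the structural
`z(1 - AUC)` harmonic shift noted above with z ≈ 0.05 — so it is the
least co-zero-sensitive statistic here but not strictly unchanged; with
a tie treatment that assigned the co-zero block zero weight outright the
shift would vanish, but that is not the classical statistic.

## Cohort analysis and replicate classifier

For a cohort on a common grid, the panel (Spearman, Pearson, R², NMI by
default) is computed between every unordered pair under both policies;
pairs sharing an experiment identifier are replicates. The effect of
co-zero removal on paired values is tested per statistic with a
two-sided Wilcoxon signed-rank test against a Bonferroni-adjusted alpha
`0.05/(n_statistic_tests × n_assays)` (default 12 × 3 → ≈ 0.00139); a
degenerate all-zero-difference comparison reports p = 1 by convention.
The replicate/non-replicate separation is summarized as the difference
of group means per statistic and policy, before and after removal.

The classifier assigns each pair one of three classes from the sample
sheet (same experiment → true replicate; same cell line, different
experiment → independent same-cell-line; otherwise different cell line),
takes the co-zeros-removed (R², NMI) as its two features, down-samples
the majority class (default target 39) and trains a 100-tree
entropy-criterion random forest. "Ten-fold stratified cross validation"
with a "stratified 40:60 split" is realized as ten stratified random
60:40 train:test splits (a classical stratified K-fold is available by
flag; the two phrasings cannot both describe one K-fold). Per-split
impurity importances (which sum to 1) are compared across folds with a
paired Wilcoxon signed-rank test on (NMI − R²).

## Numerical and edge-case conventions

* Coordinates are 0-based half-open everywhere; 1-based only in logs.
* round() is round-half-even for varied-peak counts and removal counts.
* Mitochondrial exclusion matches a configurable name set {chrM, MT, ...};
  alignment filtering uses mapq ≥ 30 and excludes unmapped, secondary,
  QC-fail, duplicate and supplementary records, attributing every
  excluded record to exactly one reason.
* An empty pair, an all-co-zero pair after removal, a zero library, and
  a fraction grid that is not strictly decreasing are all hard errors.
* Pipeline runs write a manifest with the package version, all
  parameters, the seeds used and a SHA-256 checksum of every artifact.
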