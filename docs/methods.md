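# Methods

## Model

A reference database is a labelled matrix of non-negative expression values:
genes × samples, each sample carrying one tissue class, with missing entries
allowed (real compendia mix array generations, so most samples cover only a
subset of genes). `agep` assumes the values are already normalized to a
common scale; it performs no preprocessing of its own.

For every gene *g* the package builds one evaluation grid of `grid_size`
(default 512) equally spaced points from 0 to the gene's maximum observed
value plus two times the largest of its per-tissue bandwidths, and for every
tissue *t* with at least two non-missing, non-constant observations a
Gaussian kernel density estimate f<sub>g,t</sub> on that shared grid. The
bandwidth is the normal-reference rule

    h = 1.06 · min(sd, IQR/1.34) · n^(-1/5)

with the sd used alone when the IQR is zero (heavily tied data), and an
error when the values are constant — such (gene, tissue) densities are
recorded as missing rather than represented by a pseudo-bandwidth spike.
Tissues with fewer than `min_tissue_size` (default 6) samples are dropped
from the model entirely: a density estimated from a handful of samples
misrepresents the tissue more than its absence does.

### Density evaluation

Densities are computed by binned FFT convolution. The observations are
linearly binned onto an internally refined copy of the grid whose bin width
never exceeds h/512, convolved with a Gaussian kernel truncated at 8h, and
the result is subsampled back to the 512 output points, clamped at zero and
renormalized to unit trapezoidal area. The refinement factor makes the
binning error smaller than 1e-6 of the curve's peak, so the FFT path is
numerically interchangeable with a direct kernel sum (this is asserted in
the test suite); the cost stays a few hundred microseconds per curve.

### Support truncation

A kernel estimate assigns (astronomically small) positive density
arbitrarily far from the data, but the tm-score semantics require a query
outside a tissue's observed expression range to score exactly 0. Each curve
is therefore zeroed outside its *effective support* — the observed
[min, max] extended by two bandwidths on each side (floored at 0) — and
renormalized. The two-bandwidth margin mirrors the grid's own headroom above
the gene maximum and keeps the probability that a fresh draw from the tissue
falls outside its own support negligible; truncating exactly at the sample
extremes would instead score ~2/(n+1) of the tissue's own samples as
complete non-matches, which at n = 20 corrupts one sample in ten. If the
effective support is narrower than the grid resolution the (gene, tissue)
density is treated as missing, like the constant case.

Off-grid evaluation interpolates linearly between grid points and is zero
outside the grid; negative query values (possible after upstream
normalization) are clamped to 0 with a warning.

## Scores

**tm-score.** For query value x, let d = f<sub>g,t</sub>(x) by
interpolation. tm(g,t) = (number of grid points with density ≤ d)/512 when
d > 0, and 0 when d = 0. Counting *≤ d* rather than *< d* makes a query at a
unique global mode score exactly 1 (a strict count would top out at
511/512); both scores are exact multiples of 1/512, so downstream
comparisons are free of floating-point ties.

**Typicality.** The null distribution of tm-scores under "the query really
comes from this tissue" is obtained analytically: every grid point's
tm-score is weighted by the probability mass the density assigns to it
(trapezoidal weights, normalized). A query gene is *atypical* when
P(TM ≤ tm) < α (default 0.05), which is equivalent to its value lying
outside the (1−α) highest-density region of the tissue's curve — the HDR
equivalence is asserted as a test. Grid points with zero density carry zero
weight, so tm = 0 is atypical at any α > 0. Because the null lives on the
512-point discretization, Monte-Carlo checks of the null CDF sample grid
points with the same mass weighting; continuous within-cell draws agree
with the atom null only to about the mass of the heaviest cells (~0.015 in
sup-distance on typical curves), which is a discretization statement, not an
error in either side. Calibration (atypical rate ≈ α for draws from the
tissue's own density) is checked with genuinely continuous draws via an
exact inverse-CDF sampler on the piecewise-linear curve.

**ts-score.** ts(g,t) is the mean of rwd(tm(g,t), tm(g,o)) over the other
tissues o with non-missing tm, where

    rwd(a, b) = (a − b)(1 + φ) / (max(a, b) + φ),   φ = 0.25.

This form is antisymmetric, bounded in [−1, 1], and weights a difference
more strongly when both scores are low: rwd(0.5, 0) = 5/6 while
rwd(1, 0.5) = 1/2. Those two anchor values, together with boundedness and
the monotonicity requirement, pin the functional form; φ → 0 approaches a
pure ratio criterion, larger φ approaches the plain difference.

**Similarity and ranking.** A tissue's similarity to the query is the mean
of its non-missing ts-scores; tissues are ranked by descending similarity
with lexicographic tie-break. A per-tissue coverage count reports how many
genes informed each mean, and genes with ts above `ts_threshold` (default
0.75) are counted as tissue-specific matches. Means over non-missing entries
are the package's missing-data contract throughout.

## Modality

Peaks of a density are found as local maxima, segments are delimited
valley-to-valley, and each segment's area is integrated; segments holding at
least `peak_area_threshold` (default 0.1) of the total area count as modes.
Local maxima with prominence below 10% of the curve maximum are not treated
as separate modes — kernel estimates of a few dozen samples routinely carry
shallow wiggles, and without the guard roughly a tenth of genuinely unimodal
(gene, tissue) curves at n = 20 split spuriously, while designed bimodal
mixtures in the generator show prominences above 20% throughout. An optional
filter (off by default) excludes genes having any peak with area in
[threshold/2, threshold): such near-threshold peaks make the gene's modality
call ambiguous, and the exclusion is recorded in the model's provenance.

## Cross-validation

LOOCV removes each sample in turn, recalculates its own tissue's densities
without it, aligns the sample, and scores the top-ranked tissue against the
truth. Because the per-gene grid depends on the gene-wide maximum and the
maximal bandwidth, the grid — and then all of that gene's curves — is
rebuilt whenever the removed sample determined either quantity; otherwise
only the left-out tissue's curve is refit, so other tissues' curves are
bit-identical to the full model's (tested). Sensitivity is tp/(tp+fn) and
specificity tn/(tn+fp) per tissue, with tp the tissue's samples matched to
it, fp other samples matched to it. Samples whose removal would push their
tissue below `min_tissue_size − 1` are skipped and excluded from the
accuracy denominator.

## Enrichment

For one tissue, genes with defined typicality form the background N, the
atypical ones the draw m; a gene set contributes M background members of
which k are atypical. Fold enrichment is (k/m)/(M/N) and the p-value is the
one-sided hypergeometric tail P[X ≥ k] — the exact test for the 2×2
membership/atypicality table. No multiple-testing correction is applied to
the reported p-values, but a Benjamini–Hochberg q column is emitted
alongside. Sets disjoint from the background are skipped with a warning.

## Tissue tree

For each gene present in both tissues of a pair, the non-overlap
1 − ∫min(f₁, f₂) of the two unit-area curves is computed on the shared grid;
the tissue distance is the median over those genes. (The summed variant
2 − 2∫min would double all heights but is a monotone transform, so the
clustering topology is unchanged; the bounded [0, 1] form is used.)
Complete-linkage agglomerative clustering of the distance matrix, with
labels sorted lexicographically beforehand so equal-distance merges resolve
deterministically, yields the dendrogram, exported as Newick with branch
lengths taken from merge-height differences.

## Synthetic data

The generator emulates the statistical structure of a curated reference:
per (gene, tissue) a zero-truncated Gaussian (negatives redrawn, avoiding a
spurious atom at 0), base means uniform on [100, 1000] with within-tissue
coefficients of variation on [0.08, 0.2], missing values at random
(default rate 0.10), and two designed signal types:

- **markers** — each tissue receives a block of genes whose mean is shifted
  upward by `marker_effect_sd` (default 6) within-tissue SDs in that tissue
  only; these are the ground truth for ts-score recovery.
- **bimodal genes** — a fraction (default 0.16) of genes is, in one tissue,
  an equal mixture of two components half an SD wide and 3.5 SDs apart. A
  marker gene is made bimodal in its own marker tissue, so second modes
  never coincide with another tissue's marker level.

The shipped benchmark (`benchmark_spec`) is 5 tissues × 20 samples ×
100 genes with 20 markers per tissue at 6 SDs. Everything is a deterministic
function of the spec's seed.

What the generator does **not** emulate: probe-level noise, cross-platform
batch effects, correlated gene modules, heavy-tailed or zero-inflated
single-cell counts, and class imbalance. Passing recovery tests therefore
demonstrates that the scoring machinery recovers the signals it defines —
markers, perturbations, modality — not that real tissue classification will
reach the same rates.

## Numerical choices and limitations

- Grid size 512, min tissue size 6, φ = 0.25, α = 0.05, ts threshold 0.75,
  peak-area threshold 0.1 are the method's defaults and live in one `Config`
  whose hash stamps every output file.
- Densities integrate to 1 within 1e-6 (asserted); tm/ts bounds are asserted
  property-style over random fixtures.
- The model archive and all writers are deterministic: fixed zip timestamps,
  6-significant-digit text output, gzip without mtime — repeated runs are
  byte-identical.
- tm-scores are resolution-limited to steps of 1/512; two queries closer
  than the grid spacing can tie.
- With only a handful of samples per tissue the support margin (2h) and the
  HDR calibration both become coarse; the minimum tissue size guards the
  worst of this but per-tissue accuracy at n = 6 should be read with care.
- The benchmark problem sizes (100 samples for LOOCV, 10^4 calibration
  draws, 10^5 null-CDF draws) were chosen to keep the full validation run
  around a minute while leaving Monte-Carlo noise an order of magnitude
  below every tolerance asserted against it.
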