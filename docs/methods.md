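# Methods

## Model

The centered compendium **X** (genes x samples, log₂ fold-change relative
to a reference condition) is modeled as a linear mixture **X = S A** of
statistically independent gene-coefficient signatures (columns of **S**)
with condition-specific activities (rows of **A**). The modeling
assumptions are: (i) regulatory effects combine additively in log
expression space; (ii) each underlying signal touches a small fraction
of genes, so components are sparse with a near-Gaussian background;
(iii) activities across a diverse condition set are non-Gaussian —
a signal is off in many conditions and strongly on in a few — which is
what makes the sources identifiable by ICA at all (a rotation of jointly
Gaussian sources is observationally equivalent).

An i-modulon is the set of genes whose coefficients stand outside a
component's background, with their signed weights; its activity row
quantifies condition-specific up/down-regulation relative to the
reference condition, where activities are ≈ 0 by construction.

## Robust decomposition

A single FastICA run converges to a local optimum that depends on its
seed, so the decomposition is stabilized at two levels:

1. *Within a repetition* — FastICA (scikit-learn; logcosh contrast,
   parallel updates, tolerance 1e-8, iteration cap 1000) is restarted
   `n_restarts` times. Pooled components are clustered with DBSCAN under
   the sign-invariant correlation distance d = 1 − |ρ| with ε = 0.1 and
   minimum cluster size ⌈0.5 · n_restarts⌉ (the neighborhood count
   includes the point itself, the standard DBSCAN convention). Each
   cluster member is flipped so its largest-|coefficient| gene is
   positive (ties break to the lowest gene index); the cluster collapses
   to the mean of the aligned members. Because a mean of unit vectors is
   not unit-norm, the S centroid is renormalized and the A centroid
   scaled inversely, preserving the product S·A. The number of DBSCAN
   clusters is the estimated dimensionality.
2. *Across repetitions* — the restart-and-cluster pass runs
   `n_repetitions` times with disjoint seed streams (all derived from one
   master seed via `numpy.random.SeedSequence`, so runs are exactly
   reproducible). A first-repetition centroid is retained only if every
   other repetition contains a match at d < d_max = 0.1, matched by
   nearest neighbor. The first repetition's centroids are the reported
   S/A; which repetition supplies the representative is a convention,
   not a statistically privileged choice.

The number of components per run defaults to the smallest K whose top-K
principal components reach 99% of the variance. Restarts that hit the
iteration cap are logged and excluded from clustering; if none converge
(typical when the component count sits at the noise floor), all runs are
clustered anyway — the strong components have stabilized long before the
residual rotation among noise directions settles, and the robustness
filter removes the rest.

Components are ordered by the L2 norm of their activity rows.
Reconstruction quality is the cumulative explained variance
CEV(K) = 1 − TSS(X − Σ_{k≤K} s_k a_k)/TSS(X), TSS being the sum of
squared entries.

## Thresholding

Gene significance in a component is decided by iterative peeling: remove
the gene(s) of largest absolute coefficient, recompute the D'Agostino–
Pearson K² omnibus statistic (z(skew)² + z(kurtosis)²; scipy's
`normaltest`) on the remainder, and stop the first time the statistic
drops below the cutoff — the removed prefix is the i-modulon. Genes tied
in |coefficient| are removed as a block so the result is independent of
their ordering; if the initial statistic is already below the cutoff the
set is empty; the loop never leaves fewer than 20 genes (the kurtosis
z-transform needs ≥ 20 observations) and returns the removed set with a
warning if it reaches that floor.

The default cutoff is 550. It can be recalibrated against a regulon
table: each component is first linked to the regulator whose regulon
best overlaps its top-20 |coefficient| genes (Fisher exact, BH-FDR
< 1e-5 across all component x regulator pairs, lowest p wins), then the
grid 200..1000 in steps of 50 is scanned for the cutoff maximizing the
mean F1 between thresholded gene sets and linked regulons (ties to the
smaller cutoff). Links are fixed before the scan and reused at every
grid value. A three-fold cross-validated variant trains the cutoff on
two thirds of the linked components and reports the held-out enriched
fraction and precision. Note the K² statistic grows roughly linearly
with the number of genes at fixed distribution shape, so the 550 scale
is tied to compendium-sized components (~4000 genes); small test
fixtures use proportionally lower cutoffs.

Orientation: if an i-modulon has more negative- than positive-weight
genes, the component, weights, and activity row are all negated (the
product is unchanged). An exact tie changes nothing.

## Regulon enrichment

An i-modulon/regulon association is tested on the 2x2 table (in-module x
in-regulon) over the gene universe (all genes surviving QC) with the
two-sided Fisher's exact test. Candidates are all single regulons plus
intersections ("+") and unions ("/") of up to three regulons, restricted
to regulators that individually share at least one gene with the module
(non-overlapping members cannot improve the overlap); mixed modes
compose left-to-right. BH-FDR is applied across the candidate family of
one i-modulon (a global family across all i-modulons is available in the
cutoff-calibration path); records below FDR 1e-5 are reported sorted by
p-value with precision k/n, recall k/K, and F1. Categories: regulatory
(passing enrichment), genomic (explicit rule, e.g. one gene holding
> 50% of squared weight and knocked out in some strain), biological
(explicit annotation only), else uncharacterized.

## Activity statistics

Replicate noise: for each i-modulon, absolute pairwise activity
differences within replicate groups are pooled; zeros are dropped and a
log-normal is fit by maximum likelihood on the logs (no location shift).
Fewer than 5 positive differences flags the i-modulon degenerate and
excludes it from testing. A Kolmogorov–Smirnov statistic of the fit is
recorded. Differential activity between two conditions uses
replicate-averaged activities; the p-value is the upper tail of the
fitted log-normal at |ΔA|, BH-adjusted across i-modulons, and a change
is significant only when |ΔA| > 5 *and* FDR < 0.01. The |ΔA| > 5 floor
guards against statistically crisp but biologically negligible shifts.

Profile correction removes selected i-modulon effects exactly:
x₂′ = x₂ − Σ s̃ᵢ (a_{i,2} − a_{i,1}), with s̃ᵢ the component zeroed
outside the i-modulon's significant genes; genes outside all selected
i-modulons are untouched and the operation is linear and invertible in
the activity differences. Projection of new centered profiles onto a
frozen basis is the Moore–Penrose least-squares solution
A′ = pinv(S) X′ after restricting to the genes shared between basis and
profiles (the cross-strain "core gene" restriction); the shared-gene
list is recorded in the output, and a rank-deficient restricted basis
yields the minimum-norm solution with a warning.

Activity-versus-regulator-expression association reports both an
ordinary least-squares line (R², adjusted R²) and a single-breakpoint
hinge fit (flat below a scanned breakpoint, linear above, 3 parameters),
because some regulators require a minimum expression level before their
targets respond; neither form is privileged.

## Synthetic data

The generator emulates the generative model the decomposition assumes:
X = S_true·A_true + ε. Defaults, which are the package's standard study
conditions: 4000 genes x 60 samples (30 conditions in biological
duplicate), 10 disjoint planted modules of 10–30 genes, ε i.i.d.
Gaussian with σ = 0.05.

Design choices where a value had to be fixed, with rationale:

- Member |weights| Uniform(0.5, 1.0) before column normalization with an
  80/20 positive/negative sign mix, over a Gaussian background of SD
  0.02 — a ≥ 5x member/background separation, matching the sparse
  heavy-tailed shape of real components.
- Activities are signed blocks: each module is active in ~50% of
  non-reference conditions (at least 3) at levels Uniform(10, 30) with
  random sign, plus replicate jitter of SD 0.5. Active levels of 10–30
  on components whose member weights are ~0.15–0.3 produce member-gene
  log₂ fold changes of roughly 2–6, i.e. strong but realistic regulon
  activation, and keep the sources far from Gaussian. Under these
  conditions the PCA-99% dimension coincides with the planted dimension,
  so dimensionality estimation is itself exercised.
- Condition 0 is the reference: true activities are exactly zero there
  (jitter only), and the emitted compendium is *uncentered* so the
  pipeline's own reference-centering step runs on it.
- The regulon table covers 80% of each module's members (what a curated
  database "knows") plus 20 decoy regulons size-matched to the true ones,
  so enrichment specificity is genuinely tested.
- Knockout fixtures copy the reference condition, shift the targeted
  module's activity by the stated effect size, and set the regulator
  gene's centered value to −10 log₂ units — the generator works in
  centered space, so "zero expression" is represented as a large
  negative deviation rather than a literal zero.

What the generator does not emulate: operon/genomic ordering of genes,
batch effects, count-level noise (values are Gaussian-noised linear
mixtures, not resampled reads), overlapping module membership, and
regulator genes whose own expression drives activities. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on any particular real compendium.

## Validation problem sizes

The test suite and the acceptance script validate the decomposition at
8 restarts x 3 repetitions per master seed (5 master seeds) on the
default 4000 x 60 compendium — enough Monte-Carlo depth for clean
planted-signal recovery, while the API defaults remain 256 restarts x
100 repetitions for production use on real compendia. The Fisher /
hypergeometric cross-check runs exhaustively over all 2x2 tables with
N ≤ 60 after de-duplicating by the row/column-swap symmetries of the
two-sided test (n ≤ K ≤ N/2), with the symmetries asserted separately.
Unit tests use a 600-gene fixture with a K² cutoff rescaled to its size
(see the thresholding note above).

## Numerical conventions and degenerate inputs

- Distances are clipped to [0, 1]; zero-variance vectors are rejected
  rather than silently given NaN correlations.
- Ties in the max-|coefficient| gene break to the lowest index; tied
  |coefficients| in thresholding are removed as a block; cutoff-scan
  ties go to the smaller cutoff; BH-FDR is order-invariant.
- Empty module or regulon in an enrichment test returns p = 1 with
  k = 0 instead of raising.
- All randomness flows from one master seed through `SeedSequence`
  streams; TSV matrices are serialized at 10 significant digits so a
  fixed-seed run reproduces byte-identical artifacts.
- A compendium flagged `centered` must have per-gene reference means
  within 1e-9 of zero; missing values are rejected, never imputed.

## Known limitations

- Robustness across repetitions filters ICA seed instability on fixed
  data; it cannot distinguish planted structure from stable
  high-kurtosis directions of a particular noise realization. On pure
  noise the retained set is near-empty only when the component count
  sits at the PCA-99% dimension (where FastICA has no reproducible
  optimum); with a generously small component count, noise directions
  can appear robust.
- The log-normal replicate-noise model is an empirical convenience; on
  half-normal-like difference distributions the fitted tail is
  conservative, and with few replicate pairs (< ~40) the tail estimate
  is noisy enough to cost power near the significance boundary.
- The cutoff grid 200..1000 presumes compendium-scale components; no
  per-component adaptive cutoff is attempted.
- Combined-regulon enumeration is exhaustive over overlapping
  regulators; with hundreds of overlapping regulators the triple
  candidates grow cubically, so `max_regs` may need lowering on dense
  networks.
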