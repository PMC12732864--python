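# Methods

## Cleavage windows and subsite indexing

A cleavage event is stored as a residue window of fixed length 2·W (default
W = 15) centered on the scissile bond: window indices 0…W−1 hold P_W…P1 and
indices W…2W−1 hold P1′…P_W′. Subsite label Pk therefore maps to index
W−k and Pk′ to index W+k−1. Positions that fall outside the parent protein
are padded with `X`; `X` is a first-class alphabet symbol (it encodes as the
substitution matrix's X row and is excluded from heterogeneity testing), and
records whose analysis span contains `X` are retained by default with a CLI
flag (`--drop-placeholder`) for sensitivity checks.

Spans such as P3–P4′ (7 positions), P4–P4′ (8) and P15–P15′ (30) are
resolved to contiguous window slices; P3–P4′ is the default analysis span
throughout, as it is the most informative region for distinguishing
cathepsin-family specificities.

## Subsite heterogeneity (Anderson–Darling)

The quantity tested at each subsite position is the vector of the 20
per-residue relative frequencies (placeholder counts excluded from both
numerator and denominator). A position used indifferently produces 20
comparable frequencies — an approximately normal sample of 20 values —
while a specific position with one or two predominant residues produces a
strongly right-skewed vector and a small p-value. This choice of test
sample is a genuine design decision (a per-position p-value over a
categorical distribution requires *some* reduction to a univariate sample);
it is isolated in `ad_normality`/`anderson_darling_heterogeneity` so an
alternative convention can be swapped at a single point.

The A² statistic uses the composite-null form (mean and variance estimated
from the sample). P-values use the Stephens small-sample correction
A²* = A²(1 + 0.75/n + 2.25/n²) with the standard piecewise-exponential
approximation — the same formulas as R's `nortest::ad.test`, against which
the implementation is cross-checked in the test suite. Classification:
heterogeneous p ≤ 0.05, borderline 0.05 < p ≤ 0.08, normal p > 0.08.
Degenerate positions (all counts on one residue, or an exactly uniform
vector with zero variance) are flagged rather than silently propagated; the
zero-variance case reports p = 1 since the test is undefined there.

The classification is invariant to record order and to k-fold duplication
of the dataset (it depends only on relative frequencies); fewer than ~20
records triggers a warning because a frequency vector estimated from a
handful of counts is mostly sampling noise.

## BLOSUM62 encoding

Each residue is featurized as its full 20-score BLOSUM62 row against the
standard amino acids in fixed NCBI order, giving 20·L features for a span
of length L (140 for P3–P4′). The substitution score of any residue pair is
then one coordinate of the feature vector. An alternative (scoring against
a per-position consensus residue) would need a consensus-estimation step
and is not implemented; restricting the encoding to a subset of span
positions (e.g. only AD-selected ones) is exposed via `position_mask` and
off by default. No feature scaling is applied — all coordinates are already
on the common half-bit score scale. Matrices are parsed from the NCBI text
format with symmetry and completeness validated; the bundled canonical
BLOSUM62 is the default.

## SVM-AUC discriminability

Two cleavage datasets are compared by training an SVM to separate them and
reading the ROC-AUC of held-out decision scores as a similarity statistic.
Cross-validation is repeated stratified hold-out ("jackknife"): per
repetition, a stratified random 25% of each class is reserved for testing.
The configured default of 25 repetitions reconciles the two natural
readings of a "25-fold jackknife with 25% held out" — it satisfies both the
repetition count and the fraction; both are configurable. Stratification
preserves class imbalance so neither class can empty out of a split.

The reported AUC is the **maximum** over repetitions. This is an
optimistically biased summary — under the null it lands near the upper tail
of the repetition distribution (≈ 0.55–0.60 at n = 500/side rather than
0.50) — so the mean and standard deviation over repetitions are always
carried alongside. ROC curves are computed from decision-function scores
(signed distance to the separating surface), never from hard labels.

Defaults reproduce the reference optimum: RBF kernel, gamma = 'scale',
C = 0.001, balanced class weights, tolerance 1e-4, at most 200 000 training
iterations, one-vs-one decision shape. The grid search covers
C ∈ {0.001, 0.01, 0.1, 1}, the four standard kernels, gamma ∈ {scale,
auto}, class weight ∈ {balanced, none} and hold-out fraction ∈ {0.10,
0.25}; ties are broken toward smaller C, then kernel order as listed.
Reproducibility is exact: repetition r derives its split seed from the
master seed as (seed·1000003 + r) mod (2³¹−1), so identical seed and config
give bit-identical per-repetition AUCs. Whether a grid search should be
re-run per enzyme pair or fixed globally is left to the caller; the
similarity-matrix builder applies one configuration to every pair.

## Ward clustering and enzyme-specific substrates

The combined two-enzyme dataset is clustered agglomeratively with Ward
linkage on Euclidean distance over the BLOSUM62 features. Ward requires
Euclidean geometry, so the substitution matrix enters through the encoding
rather than as a custom metric. The tree is cut at up to 400 clusters, with
one refinement: the cut never splits a zero-height merge, so duplicate
windows always co-cluster (requesting 400 clusters from 10 identical
windows yields one cluster, not 10 singletons). With continuous real-data
features zero ties are rare and the cut behaves like a plain
maximum-cluster-count criterion.

Enzyme-specific clusters are those with purity exactly 1.0 (all members
from one enzyme) and size ≥ 2; the size floor is the weakest rule that
excludes singletons, consistent with reported specific-cluster sizes
averaging ~2.25, and is exposed as a flag. A window present under both
enzyme labels blocks purity by construction, which matches the intent of
species specificity.

## General modifier kinetics

The scheme is treated under rapid equilibrium (K_s ≈ K_m) with un-depleted
substrate (S in µM, enzyme in nM). Units are fixed: substrate and K_m in
µM; inhibitor, enzyme and K_i in nM; σ = S/K_m is the standard
dimensionless substrate load.

Three velocity evaluations exist, in increasing generality:

1. `velocity_no_depletion` — the classical closed form in *free* inhibitor,
   valid when [I]_t ≫ [E]_t.
2. `velocity_with_depletion` — tight-binding form. Writing
   c = (α+σ)/(αK_i), the inhibitor mass balance reduces to
   x² + x[(1+σ) + c(E_t − I_t)] − I_t·c(1+σ) = 0 with x = I·c; the positive
   root gives free I and the velocity is the non-depleted law at that I.
3. `equilibrium_oracle` — direct numeric solution of both mass balances by
   200-step bisection on free I ∈ [0, I_t]; the residual closes to
   ~machine precision relative to the largest concentration involved.

The oracle is the module's source of truth: both closed forms are required
to agree with it to relative 1e-6 over a 1000-draw random parameter sweep
(the module's master test). The depletion correction is first order in the
bound fraction ~E_t/I_t, so the non-depleted law converges to the full
balance at that rate — e.g. agreement to 1e-6 requires E_t/I_t ≲ 1e-7 for
typical parameter values.

**Specific velocity plot.** For each inhibitor concentration, v_0/v_i is
exactly linear in x = σ/(1+σ) under the non-depleted law:
v_0/v_i = [(1+I/K_i) + x·(I/(αK_i) − I/K_i)] / (1+βI/(αK_i)), so the
fitted values at x = 0 and x = 1 are a₀ = (1+I/K_i)/(1+βI/(αK_i)) and
a₁ = (1+I/(αK_i))/(1+βI/(αK_i)). The secondary lines are then exactly
linear in 1/[I]_t with

    1/(a₁−1) = [αK_i/(1−β)]·(1/I_t) + β/(1−β)
    1/(a₀−1) = [αK_i/(α−β)]·(1/I_t) + β/(α−β)

so β = c₁/(1+c₁), αK_i = s₁(1−β), α = β + β/c₂, K_i = αK_i/α. These
relations are re-derived from the rate law and verified by exact recovery
on noise-free synthetic data (relative error ≤ 1e-6) before any use on
noisy data. v_0 per substrate concentration comes from the mandatory
uninhibited series; inhibitor concentrations showing no inhibition
(fitted a₀ ≤ 1 or a₁ ≤ 1) are excluded with a warning, and at least three
usable concentrations are required. Primary lines assume free ≈ total
inhibitor, so I_t/E_t < 20 triggers a warning when E_t is supplied.
Standard errors are first-order propagations from the secondary-line fit
uncertainties, neglecting the covariance between the two secondary fits
(they share the primary-stage data); they are indicative, not exact.

**K_i fit.** Nonlinear least squares of the tight-binding velocity against
measured rates at one substrate concentration, by default floating only K_i
and v_0 with α and β fixed at the specific-velocity estimates (a flag
floats all four). Bounds: K_i, v_0, α > 0 and β ∈ [0,1]; unweighted loss by
default with optional 1/v weighting; Levenberg–Marquardt with x/f
tolerances of 1e-10; asymptotic standard errors from the Jacobian. Designs
whose inhibitor range does not bracket E_t·5 or sit near K_i draw
identifiability warnings.

Derived constants are pure arithmetic: noncompetitive K_i = α·K_i; SPR
K_D = k_d/k_a with k_a in 1/(M·s) and k_d in 1/s, reported in nM.

## Synthetic data

The cleavage generator draws windows i.i.d. across records and
independently per position from a position-specific probability model over
the 20 standard residues. The default base model is uniform residue usage —
deliberately, so that null comparisons give AUC ≈ 0.5 cleanly — and a
cathepsin-like preset (hydrophobic P2, basic P1, small P1′) is available
for more realistic marginals. Divergence between two pseudo-enzymes mixes
the affected positions' probability vectors toward a randomly chosen
(seeded) target residue: B = (1−δ)·base + δ·one-hot(target), so δ = 0 gives
identical enzymes and δ = 1 a deterministic position. Default study
conditions for discrimination experiments are n = 500 windows per enzyme
with divergence applied at the P2/P1/P1′ positions.

What the generator does *not* emulate: positional dependence within a
window, protein-level effects (the same protein contributing correlated
sites), mass-spectrometric detection bias, and dataset-size imbalance
between enzymes. Passing tests on synthetic data therefore demonstrate the
statistical machinery (null behavior, power, monotonicity in divergence,
recovery of planted structure), not the biological numbers obtainable only
from the deposited substrate datasets.

The kinetic generator evaluates the depletion-aware law on the reference
assay grid (S ∈ {135, 270, 540, 1080} µM; I_t ∈ {53.7, 181, 483, 1448.9}
nM; E_t = 1 nM; K_m = 547.7 µM) and applies multiplicative Gaussian noise
v·(1+ε), ε ~ N(0, CV), clipped at zero — the simplest model of a constant
assay CV. For noise-free non-depleted data (specific-velocity validation),
a trace enzyme concentration (E_t = 1e-6 nM) makes the generator coincide
with the free-inhibitor law.

## Problem sizes and numerical choices

Test-suite simulations use n = 300–500 windows per enzyme for
discrimination checks, 50-record planted motifs for clustering recovery,
200–500 replicates for Monte-Carlo calibration of the heterogeneity test
and noisy kinetic recovery, and 1000 random draws for the oracle
equivalence sweep — sizes at which every statistical assertion is stable
across seeds while the full suite runs in well under a minute of compute
per module. Planted-motif clustering fixtures pin the span residues of each
motif (background positions outside the span stay random) because Ward
recovery of a motif requires between-motif separation to dominate
within-motif spread; a single divergent position under an otherwise uniform
span does not satisfy that and is not a meaningful recovery target.

## Known limitations

* The heterogeneity test's sample definition (frequencies, not counts) is a
  convention; with counts or with placeholder-inclusive denominators the
  p-values shift, though strongly specific positions stay significant.
* The max-over-repetitions AUC is upward biased; comparisons across
  datasets of very different sizes should use the mean AUC as well.
* The specific-velocity standard errors ignore cross-fit covariance.
* Steady-state (non-rapid-equilibrium) modifier kinetics and substrate
  depletion are out of scope; progress-curve fitting is not implemented.
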