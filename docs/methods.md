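# Methods

This note documents the models implemented in `spectroclust`, the
parameter defaults and why they were chosen, the numerical decisions that
affect results, and what the synthetic test scenes can and cannot show.

## Preprocessing

Reflectance spectra R(λ) on a fine regular grid (e.g. 400–2500 nm at
0.5 nm) are reduced to a coarser grid by **window means**: band center c
averages the native channels in [c − Δ/2, c + Δ/2) with Δ the resampling
interval (default 10 nm, giving 211 bands over 400–2500 nm). Window means
were preferred over interpolation because downsampling by a factor of 20
should aggregate, not subsample, the native channels; linear interpolation
is available as an option. Resampling at the native interval is the
identity, and resampling twice at the same interval is idempotent.

Absorbance is A = log₁₀(1/R) (base 10, the spectroscopy convention).
Smoothing is Savitzky–Golay with polynomial order 2 and a 15-channel
window, delegated to `scipy.signal.savgol_filter` with polynomial-fit
extrapolation at the edges (`mode="interp"`), so the band count is
preserved and any spectrum that is a polynomial of degree ≤ 2 passes
through unchanged.

The calibration target (SOC, g kg⁻¹) is modeled as **ln SOC** (base e —
distinct from the base-10 absorbance transform). Samples below a
positivity floor of 0.1 g kg⁻¹ cannot be log-transformed meaningfully;
they are dropped with a logged report rather than shifted by an offset,
because an additive offset would silently change the model space. Target
summaries report population-moment skewness g₁ = m₃/m₂^1.5 and both the
raw (m₄/m₂²) and excess (−3) kurtosis, since software conventions differ.

## Geographically weighted PCA

Spectra are globally z-scored per band (population sd). At each sample
location the local covariance is

Σ(u,v) = (X − μ_w)ᵀ diag(w/Σw) (X − μ_w),

with bisquare weights w(d) = (1 − (d/b)²)² for d < b and the weighted
column mean μ_w. Normalizing weights to sum 1 fixes the otherwise
arbitrary eigenvalue scale: with uniform weights Σ(u,v) is exactly the
population covariance, so in the infinite-bandwidth limit the local
eigenvalues and scores converge to global PCA (verified to 1e-6 relative
error in the tests).

Each sample is scored on its own local loadings, **Z_i = x_i,std · L_i**,
i.e. the globally standardized row is projected without local
re-centering. This matters: subtracting the local weighted mean before
projecting removes precisely the between-region mean structure that the
subsequent clustering is meant to find (empirically, cluster recovery
drops from ARI ≈ 1 to ≈ 0 at sub-cluster bandwidths when scores are
locally re-centered).

Local eigenvectors are defined only up to sign, and independent
eigendecompositions at neighboring locations can flip arbitrarily. Every
local loading column is therefore sign-aligned to the corresponding
global PCA loading (flip when the dot product is negative), which makes
scores continuous across space and comparable between samples — a
precondition for clustering them.

The retained component count k uses the eigenvalue > 1 rule on the
*global* covariance of the standardized data (k ≥ 1 enforced), so all
locations share one k. Distances are great-circle km (haversine,
R = 6371.0088 km) for lon/lat data, with a Euclidean option for projected
or synthetic coordinates. Bandwidths may be fixed (km) or adaptive
(distance to the N-th nearest neighbor, inflated by 1e-9 so that neighbor
carries non-zero weight). When asked to select a bandwidth, the package
minimizes a leave-one-out reconstruction score: at each location the
local loadings are refitted without the held-out sample and the squared
residual of projecting that sample on them is accumulated; fixed
bandwidths are searched by golden-section over [median nearest-neighbor
distance, max pairwise distance], adaptive ones by integer golden-section.
For spatially homogeneous data this score saturates at large bandwidths
(flat within 1% beyond twice the data diameter), so any large bandwidth
is equivalent there.

## Fuzzy c-means and validity indices

FCM minimizes J = Σᵢ Σⱼ μᵢⱼᵐ d²ᵢⱼ over column-stochastic memberships
(c × n) and centers, with squared Euclidean distances on the GWPCA
scores. The updates are the standard alternating (Bezdek) optimization;
each half-step is the exact minimizer given the other block, so J is
non-increasing at every iteration — asserted in the tests for every
seeded run.

Defaults follow common chemometric practice: fuzziness m = 1.5, at most
300 iterations, convergence when max |ΔU| < 0.001 (the membership change
is used because "convergence threshold" is ambiguous between objective
and memberships; memberships are scale-free). Initialization draws a
random column-stochastic U per restart (5 restarts, best final J kept)
with a twist: each sample's column is seeded from a hash of its own
coordinate vector, so permuting sample order permutes the memberships
identically instead of changing the answer. A sample coinciding with one
or more centers splits its membership equally among the coincident
centers.

Cluster-count selection sweeps c = 2…10 and records

* FPI = c(1 − PC)/(c − 1), PC = (1/n) ΣΣ μ², which is 0 for a crisp
  partition and 1 for a uniform one;
* NCE = n/(n − c) · H, H = −(1/n) ΣΣ μ ln μ (natural log; the base is
  configurable since conventions vary).

The automatic choice minimizes the rank-sum of (FPI, NCE), ties to the
smaller c; a manual override is provided because in practice the choice
may also weigh agreement with auxiliary strata such as land cover. Note
the FPI convention: some printed forms of the index evaluate to 1 for
crisp partitions, contradicting the accompanying interpretation that
values near 0 mean well-separated clusters; this package uses the
convention consistent with that interpretation (crisp → 0).

## Kennard–Stone splitting

The calibration set is grown greedily: seed with the two most distant
samples, then repeatedly add the sample with the largest minimum distance
to the selected set (ties to the lowest row index), until
|cal| = ⌈2n/3⌉ for the default 2:1 ratio. Distances are Euclidean on the
preprocessed absorbance spectra — the actual model inputs — not raw
reflectance. The procedure is deterministic and id-stable under row
permutation, and the implementation (incremental O(n²)) is tested
exactly against a literal O(n³) transcription of the procedure. Splits
are performed within each group, so grouped and global reports share one
validation protocol.

## Calibration models

**PLSR** is PLS1 NIPALS with mean centering (no variance scaling — bands
are already on one absorbance scale). The NIPALS recursion yields the
coefficient vector for every truncation 1…A in a single decomposition,
so the automatic latent-variable choice (10-fold CV RMSE over
1…min(30, n−2, m), ties to fewer components) costs one decomposition per
fold. With as many components as the predictor rank, PLS1 predictions
equal ordinary least squares; with one component on univariate input it
is simple linear regression — both are test oracles, and coefficients are
additionally checked against an independent NIPALS implementation.

**Model tree** is a single M5-style tree:

* splits maximize the standard-deviation reduction
  SDR = sd(S) − Σ |Sᵢ|/|S| · sd(Sᵢ), requiring ≥ 20 samples per leaf
  (`min_leaf`), and stop once a node's sd falls below 5% of the root sd;
* every node carries a multivariate linear model: exact least squares
  when the band matrix has full column rank, otherwise ridge with
  λ = 1e-6 · trace(XᵀX) — for spectra (n < m in any leaf) the ridge path
  is the norm; a tiny λ keeps well-posed cases unchanged to ~1e-8;
* predictions are smoothed along the path to the root,
  p ← (n_child·p + k·p_node)/(n_child + k) with k = 15, which tempers
  overparameterized leaf models; smoothing can be disabled;
* subtrees are pruned bottom-up when the node's own linear model
  cross-validates (3-fold RMSE) at least as well as the weighted CV error
  of its children, with ties favoring the simpler node — so a noiseless
  linear target collapses to a single exact leaf.

Committees and nearest-neighbor composite corrections of the full Cubist
algorithm are out of scope; the single-tree core captures the mechanism
that matters for the grouped-vs-global comparison (piecewise-linear
response).

All modeling and evaluation happens in ln-SOC space; reported RMSE values
are therefore in log units. Predictions can be back-transformed on
request, but metrics are not, to keep rows comparable.

## Evaluation

R² = 1 − SSE/SST (SST about the observed mean), RMSE, and
RPIQ = (Q3 − Q1 of observed)/RMSE with linearly interpolated (type-7)
quantiles — the quantile convention is documented because RPIQ depends on
it. Quality categories: RPIQ < 1.5 very bad, [1.5, 2.0) poor, [2.0, 2.5]
good, > 2.5 very good. Degenerate cases use sentinels: RMSE = 0 gives
RPIQ = +inf, constant observations give R² = NaN.

Grouped reports contain one row per group, a pooled *All* row from the
global model, and a *Mean* row. The Mean row is the **unweighted
arithmetic mean of the group rows computed in 2-dp decimal arithmetic
(half-up) from the displayed cells**, so a printed table can be recomputed
exactly from its own rows; the sample-count mean rounds half-up to an
integer. Groups with fewer than 2 validation samples are skipped with a
warning.

Band importance uses a bagged ensemble of CART trees (mtry = ⌊m/3⌋
features per split, 500 trees by default) with Breiman's out-of-bag
permutation importance: per tree, the OOB MSE increase after permuting
one band, averaged over trees. Permutation/OOB importance was chosen over
impurity importance because the latter is biased for the strongly
correlated bands of spectra.

## Synthetic scenes

The generator plants, per cluster: a spatial blob (Gaussian around a
center in a 10°×10° region, or uniform for homogeneous scenes); an
absorbance endmember (baseline offset + slope plus Gaussian absorption
features at 1400/1900/2200 nm, mimicking water, clay and organo-mineral
bands); lognormal SOC (cluster log-medians around 3.0–3.5, σ = 0.8, i.e.
median SOC ≈ 20–33 g kg⁻¹ with a long right tail); and a coupling term
`coupling · (ln SOC − 3.2) · g(λ)` that raises absorbance with SOC, so
SOC and mean reflectance are negatively correlated by construction.
Noise is a Gaussian process along wavelength (length scale 50 nm) rather
than white noise, so Savitzky–Golay smoothing is exercised against
realistic correlated perturbations. Reflectance is R = 10^(−A), clipped
into (0, 1].

Presets:

* `four-cluster-separated` (4 × 250): endmembers differ in offset
  (0.4…1.6), slope and feature-depth pattern — each cluster has a
  distinct dominant absorption band — with a weak common coupling (0.06),
  so the four classes are recoverable from the spectra alone. Used for
  cluster-count selection and partition-recovery checks.
* `heterogeneous-slopes` (4 × 200): the same separable endmembers but
  strongly different coupling strengths (0.05…0.24) and bent coupling
  shapes per cluster; one global linear model is structurally
  mis-specified while per-cluster models are not. Carries noisy
  land-cover strata (70% agreement with the spectral clusters) for the
  three-way grouped/stratified/global comparison.
* `planted-band` (300): SOC coupled to a single narrow band at 1400 nm,
  for importance profiling.
* `homogeneous` (200): one spatially uniform population, for
  bandwidth-score flatness checks.

What passing these tests does **not** show: the scenes have exactly
Gaussian blobs, noiseless labels and a linear (per cluster) spectra–SOC
link, so recovery there does not imply comparable accuracy on real
libraries with gradual spatial transitions, label noise, nonlinear
responses and instrument artifacts. The scenes establish correctness of
the machinery and the *direction* of the grouped-vs-global effect, not
field performance.

## Problem sizes and determinism

The shipped checks run at desk scale: scenes of 500–1000 samples × 211
bands, bandwidth selection exercised at n ≤ 100 with thinned bands, and
the grouped-vs-global comparison over 10 scene seeds. One run seed fans
out to per-stage seeds via a stable hash of the stage name (all < 2³¹),
so stages are individually re-runnable and full pipelines are
bit-reproducible given the same numerical libraries.

## Known limitations

* GWPCA is O(n · m³ + n²) per fit and the LOO bandwidth score multiplies
  that by the number of candidate bandwidths; for libraries of 10⁴+
  samples the bandwidth should be set from domain knowledge or selected
  on a subsample.
* The eigenvalue > 1 rule is coarse for highly collinear spectra (the
  first component dominates); k can always be set explicitly.
* FPI/NCE both reward crisper partitions and often decrease toward small
  c on weakly structured data; the rank-sum choice should be reviewed
  against the validity curve, which is why the sweep returns it in full.
* Model-tree leaf models on n < m spectra rely on the ridge fallback and
  path smoothing for stability; they interpolate their training data and
  their individual coefficients are not interpretable.
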