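# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `dabold`. Everything quantitative stated
here is computed by the test suite or the acceptance script; nothing is
quoted from external data.

## PET simulation and quantification

Time–activity curves are simulated forward from the simplified reference
tissue model (SRTM). The plasma input is a bi-exponential surrogate
C_p(t) = a₁e^(−b₁t) + a₂e^(−b₂t) (defaults a₁=800, b₁=0.8 min⁻¹, a₂=90,
b₂=0.04 min⁻¹, arbitrary kBq/mL scale — the Logan estimator is scale
invariant, so only the shape matters). The reference region follows a
one-tissue model (K₁′=0.10 mL·min⁻¹·g⁻¹ equivalent, k₂′=0.16 min⁻¹,
raclopride-like cerebellum); the target follows
dC_T/dt = R₁·dC_ref/dt + k₂C_ref − k₂ₐC_T with k₂ = R₁k₂′ and
k₂ₐ = k₂/(1+BP_ND). Integration uses an exact exponential-integrator step
for piecewise-linear input on a 0.5-s grid; frame values are interval
averages, matching what a scanner reports. At BP=0, R₁=1 the target and
reference coincide identically — the key self-test of the simulator.

Quantification is the classic Logan reference plot *without* the k₂′
correction term, the conventional choice for raclopride at late fit windows;
t\* defaults to 18 min and is configurable. Cumulative integrals are
trapezoid sums anchored at zero activity at t=0; negative frame activities
(noise) are clamped to zero and logged before integration. On the 55-min
18-frame schedule the noise-free estimator is accurate to ~1% at BP ≤ 1,
−3 to −4% at BP = 2 and about −7% at BP = 3.5 (slow equilibration at high
binding), and is strictly monotone in true BP over [0.2, 3.5]. SRTM is
simulation-side only; it is never used as an estimator.

## Latent profile analysis

LPA is Gaussian-mixture EM (scikit-learn backend) over the three sum-correct
scores, K = 1..5, full per-class covariance by default, 10 restarts.
Model selection minimizes BIC = −2 log L + p log n; the mixture literature's
"maximize negated BIC" convention maps onto this with a sign flip, and the
test suite pins the minimized form against a hand computation. The
parametric bootstrap LRT resamples from the fitted K-class model and uses
p = (1 + #{boot ≥ observed}) / (B + 1). The below-chance screen is an exact
one-sided binomial rule: the threshold is the smallest score c with
P(Bin(90, ½) ≥ c) < α (α = 0.05 ⇒ c = 54), and a subject is excluded only
when below c on all three loads. Class naming is semantic: the class with
the highest 3-back mean is "normal-performing", the rest "low-performing";
when BIC selects more than two classes the pipeline folds all non-top
classes into "low", because the PLS design declares exactly two subgroups.

## Hierarchical factor model

Σ(θ) = Λ₁(Λ₂ΦΛ₂ᵀ + Ψ)Λ₁ᵀ + Θ with one loading per factor fixed to 1,
indicator-specific uncorrelated errors, correlated second-order factors
(Φ full, parameterized by its Cholesky factor), and log-parameterized
variances — so Heywood cases are bounded at zero by construction and
flagged when a variance collapses below 10⁻⁸. The free-parameter census is
8 + 5 loadings + 16 + 8 variances + 6 Φ entries = 43, giving df = 136 − 43
= 93. F_ML is minimized by L-BFGS-B (ftol 10⁻⁸) from multiple jittered
starts after standardizing indicators internally; the model family is
closed under diagonal rescaling, so the optimum is unchanged and the
solution is mapped back to the raw metric exactly. Fit indices:
χ² = (n−1)F_ML, RMSEA = √(max(χ²−df,0)/(df(n−1))), CFI against the
independence baseline; a noncentral-χ² RMSEA interval is available but off
by default. Note that published AMOS analyses of comparable models report
different df (e.g. 77 for 16 indicators), implying extra constraints or
freed parameters that are not documented; we report our own census and do
not tune toward any published value. Cross-hemisphere error covariances are
not modeled.

Factor scores are regression (Thurstone) estimates
(X − X̄)Σ̂⁻¹Λ̂₁Λ̂₂Φ̂, rescaled to unit variance per factor. The composite
DA measure is the first principal component of the standardized three
scores (eigendecomposition of the 3×3 correlation matrix); loadings are
reported as score–component correlations and the sign is oriented
positively with the mean score.

## Behavioral PLS

Rows of the cross-block matrix are stacked per DA variable (outer), then
block; entries are Pearson correlations; constant voxel columns get r = 0
with a warning (out-of-brain voxels). The SVD is full; each LV is oriented
so its DA-weight vector sums positive. Permutation inference reassigns DA
values across subjects *within group* (preserving the group structure;
cross-group permutation is available), recomputing the matrix and SVD per
draw; p is the raw exceedance count over n_perm (the add-one convention is
optional). The bootstrap resamples subjects with replacement within group,
redraws replicates whose blocks retain fewer than 3 unique subjects, and
aligns each replicate's singular vectors to the original solution by greedy
maximal-|inner product| matching with sign flips before accumulating
(unaligned bootstraps inflate SEs through sign and order indeterminacy).
BSR = original salience / bootstrap SE, with a ±∞ sentinel and a flag when
an SE is exactly zero; correlation-score CIs are 2.5/97.5 percentiles of
the replicate distribution. The outlier rule standardizes LV1 brain scores
within block, removes subjects beyond 3 SD in any block, and triggers
exactly one recomputation. Correlation scores are in-sample quantities and
are optimistically biased when voxels ≫ subjects — the same property the
field's PLS toolboxes exhibit — which is why decisions rest on CI overlap
rather than on the point values. The spatiotemporal lag dimension is a
configurable window (default 1, purely spatial), with per-lag signal
attenuation in the generator.

## Cluster report

Suprathreshold voxels (|BSR| ≥ 3.29 ≈ two-tailed p = 0.001) are grouped by
26-neighbor connectivity (6/18 selectable), positive and negative maps
separately; clusters under 50 voxels are dropped. Within a cluster the
global maximum is the peak; other local maxima at least 10 mm (affine
distance) from every stronger reported maximum become subcluster rows;
separate components with peaks closer than 10 mm are merged and the weaker
peak demoted. Peaks are reported in mm through the volume affine.

## Dependent correlations and CI rules

Steiger's Z̄\*ₕ with the pooled back-transformed correlation: Fisher
transforms z₁₂, z₁₃; covariance term
ψ = r₂₃(1−2r̄²) − ½r̄²(1−2r̄²−r₂₃²), s = ψ/(1−r̄²)²,
Z = (z₁₂−z₁₃)√((n−3)/(2(1−s))), two-tailed normal p. Williams' t is
available as an option. CI rules treat intervals as closed: two scores
"differ" only when their CIs are disjoint, and a score is "unreliable"
when its CI contains zero — ties count as overlap (conservative).

## Synthetic cohort: what it emulates and what it does not

Defaults define the study conditions: 168 included subjects in two latent
classes with proportions 113/168 and 55/168; per-load accuracy means
(87, 79, 68) vs (75, 59, 41) with SDs (3–8) and within-class correlation
0.35 — about three within-class SDs of separation per indicator, the regime
in which BIC reliably selects K = 2 (30/30 seeds in the suite) and hard
assignment accuracy is ≈98%. Out-of-range draws are resampled, not clipped,
preserving the mixture shape; scores are rounded to integers.

Regional BPs come from the same hierarchical factor structure the CFA
estimates, at raclopride-like scales (putamen ≈ 3.1 down to neocortex
≈ 0.25–0.45, CV 15%) with second-order correlations (striatal–limbic 0.45,
striatal–neocortical 0.40, limbic–neocortical 0.75) chosen so the
composite's loading ordering is limbic > neocortical > striatal — the
striatal system is the least coupled to the other two.

BOLD is condition-averaged directly (no HRF convolution — a stated
non-goal): a 12×12×12 grid at 3.4 mm with a contiguous central blob
(radius 2.6 voxels, 88 voxels — comfortably above the 50-voxel cluster
rule). Blob voxels follow y = r·z(DA) + √(1−r²)·(√ρ·η + √(1−ρ)·ε) with
ρ = 0.5: each voxel's expected correlation with the composite equals the
planted r, while the shared component η keeps block-level brain-score
correlations from saturating (independent voxel noise would average away
and every block would correlate ≈1 with DA, erasing the planted contrast —
real spatially smoothed BOLD has exactly this kind of shared noise).
Planted defaults encode the load-by-group interaction: normal group
r = 0.10/0.20/0.65 across 1/2/3-back, low group r = 0.10/0.50/0.05. No
published effect sizes exist for these cells; the values are the package's
design choice, set once so that the qualitative pattern — reliable 3-back
association only in the normal group, reliable 2-back association in the
low group, and a between-group 3-back difference — is recoverable by the
full pipeline's CI rules in ≥90% of seeds. Passing tests therefore show
that the machinery recovers structure *of this planted kind and strength*;
they do not certify sensitivity at weaker, unmodeled real-data effect
sizes, spatially extended signals, or physiological noise spectra.

## Problem sizes and determinism

The default pipeline (n = 168, 1728 voxels, n_perm = n_boot = 1000) runs in
a few minutes on one core; the test suite and acceptance script use reduced
replicate counts (40–300) and smaller grids where the quantity under test
does not depend on scale, with Monte-Carlo tolerances widened accordingly
(3 binomial/empirical SEs). All randomness flows from named seeds spawned
from one master seed; identical config + seed reproduces cohorts
bit-for-bit and the pipeline's summary JSON byte-for-byte (floats rounded
to 10 decimals on output to keep the contract platform-stable).

## Known limitations

- Logan without k₂′ correction is negatively biased at high BP on a 55-min
  window (≈−7% at BP 3.5); t\* is not adaptively chosen.
- The CFA reports a single fitted solution; no standard errors on loadings.
- In-sample PLS correlation scores are optimistic at voxels ≫ subjects (see
  above); between-group inference uses CI overlap only.
- The generator plants one signal blob per analysis, a single lag by
  default, and Gaussian noise; no motion, drift, or physiological artifacts.
- Voxelwise Logan is supported but the pipeline quantifies region-level
  TACs; map smoothing and partial-volume correction are out of scope.
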