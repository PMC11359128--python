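# Methods

This note documents the models implemented in `soilhazard`, the
calibration of the synthetic-survey generator, the numerical choices
that matter, and what the test suite does and does not demonstrate.

## Semivariogram models

All spatial analysis is isotropic. For lag distance h ≥ 0 the
semivariogram families are, with nugget C₀ ≥ 0, partial sill C ≥ 0 and
range a > 0 (γ(0) = 0 always):

| family      | γ(h), h > 0 |
|-------------|-------------|
| exponential | C₀ + C(1 − e^(−h/a)) |
| gaussian    | C₀ + C(1 − e^(−h²/a²)) |
| spherical   | C₀ + C(3h/2a − (h/a)³/2) for h ≤ a, else C₀ + C |
| circular    | C₀ + C(1 − (2/π)(cos⁻¹(h/a) − (h/a)√(1 − h²/a²))) for h ≤ a, else C₀ + C |
| stable      | C₀ + C(1 − e^(−(h/a)^ω)), ω ∈ (0, 2] |

Spherical and circular attain the sill at h = a; the others approach it
asymptotically, with effective (95 %) ranges 3a (exponential), √3·a
(gaussian) and 3^(1/ω)·a (stable). The stable family generalizes the
exponential (ω = 1) and gaussian (ω = 2); its shape is fitted jointly
with the other parameters. `range_` always denotes the distance
constant a; effective ranges are reported separately.

The empirical semivariogram is the method-of-moments estimator
γ̂(bin) = Σ(zᵢ−zⱼ)²/(2N) over unordered pairs binned by distance
(equal-width bins; default max lag = half the maximum pairwise distance,
12 bins). Bins without pairs are excluded. Fitting minimizes
Σ N(h)(γ̂ − γ)² with bounds C₀, C ≥ 0 and a ∈ (0, 2·max_lag], restarting
from five initial points. The starts are ordered from the pure-nugget
configuration upward and a new optimum must strictly improve the
objective, so a flat empirical variogram resolves deterministically to
C ≈ 0 rather than to an arbitrary nugget/structure trade-off.

## Ordinary kriging

Predictions solve the covariance-form OK system per target with a
Lagrange multiplier enforcing Σλ = 1; the covariance is
C(h) = sill − γ(h) with the nugget on the diagonal only. The
neighborhood is the k = 16 nearest samples (all, when n < 16); tests
verify the truncated solver equals a dense full-matrix solve whenever
k ≥ n. Duplicate sample locations are averaged (with a warning) since
they make the system singular. Negative kriging variances from
round-off are clipped at zero. With C₀ = 0 the predictor interpolates
the data exactly.

The pipeline fits variograms and kriges on z-scored concentrations and
maps predictions back through the affine transform (exact, since
kriging is linear); fitted variograms are therefore reported on z-score
scale, where survey semivariogram tables conventionally live, and
concentration rasters come out in mg kg⁻¹.

Leave-one-out cross-validation predicts each sample from the remaining
n − 1 and standardizes residuals by the kriging standard error:
MSE = mean(r), RMSSE = √mean(r²), ideals 0 and 1. The *standardized*
forms are implemented deliberately — without the standardization an
"RMSSE close to unity" criterion is meaningless — and the plain mean
error is kept as an extra diagnostic. Family selection ranks candidates
by |MSE| + |RMSSE − 1| with ties broken by fitting objective, then input
order. The nugget/sill ratio classifies spatial dependence (SPD):
< 0.25 strong, 0.25–0.75 moderate (boundaries inclusive), > 0.75 weak.

## Contamination indices

CF = C_metal / C_background with average upper-continental-crust
backgrounds (As 2, Cd 0.1, Co 11.6, Cr 35, Cu 14.3, Mn 527, Ni 62,
Pb 17, V 53, Fe 59100, Zn 52 mg kg⁻¹). PLI is the geometric mean of a
site's CFs, computed in log space; a zero CF forces PLI = 0 with a
warning. Class schemes are configurable; the defaults are CF cut points
1/3/6 (each threshold belonging to the class above, so CF = 1 is
already "moderate") and PLI cut points 1/2 (threshold belonging to the
class below, so PLI = 1 is still "unpolluted"). The PLI defaults were
chosen because they reproduce the mapped moderate/strong levels of the
emulated survey from its printed zone-mean concentrations (the
moderate-zone means give PLI ≈ 1.65 ∈ (1, 2], the strong-zone means
PLI ≈ 2.07 > 2); both checks run in the test suite.

Hazard rasters are derived cell-wise from the kriged concentration
grids — CF per metal per cell, PLI as their geometric mean, then the
categorical map — not by interpolating sample-level PLI. Classified
areas are cell count × cell_size²; percentages default to shares of the
mapped cells, with an optional independent total area for surveys whose
mapped outline is known separately from the analysis grid.

## Multivariate zoning

Concentrations are z-scored (ddof = 1). Pearson correlations carry
two-sided t-test p-values, uncorrected for multiple testing (the usual
star-table convention; flagged as such). Sampling adequacy uses the
overall KMO measure computed from anti-image partial correlations, with
the conventional > 0.5 adequacy rule, and Bartlett's sphericity test
χ² = −(n − 1 − (2p+5)/6)·ln det R. Note that for data with *no* shared
variance KMO tends to 0.5, not 0: the partial correlations equal the raw
ones to first order.

PCA is an eigendecomposition of the correlation matrix; components with
eigenvalue > 1 are retained, loadings are eigenvectors scaled by √λ,
and each component's sign is fixed so its largest-magnitude loading is
positive (determinism). No rotation is applied by default.

Zoning uses agglomerative hierarchical clustering with Ward linkage on
Euclidean distance over the z-scored metal matrix (linkage and the
choice to cluster on PCA scores instead are configurable). Labels are
renumbered so cluster 1 has the larger mean of an anchor metal (Fe by
default), mirroring the convention that zone 1 is the high-concentration
zone. Cluster contrasts report per-metal descriptive statistics,
one-way ANOVA F and p, and two-group significance letters (different
letters ⇔ p < 0.05); letters are implemented for the two-group case
only — more groups would require a post-hoc procedure, which is out of
scope.

## Synthetic-survey generator

The generator emulates a 32-sample, 11-metal topsoil survey of a
36.5 × 72.3 km area (an equirectangular projection of the Al-Baha survey
window at 111.2 km/degree, longitude scaled by cos 20.275°). Its
defaults are the survey's published summaries: per-metal means, sds and
minima; per-metal z-score semivariograms (families and nugget/partial
sill per metal; ranges are not published and default to a = 10 km,
stable shape ω = 1.5); the 11 × 11 Pearson matrix; and a two-zone mean
shift equal to the difference of the published cluster means, with zone
1 holding 13/32 of the samples (a western slice split at the matching
x-quantile).

Construction per realization:

1. coordinates uniform in the bounding box; zone labels from the
   x-quantile split;
2. one zero-mean latent Gaussian field per metal with that metal's
   semivariogram, via Cholesky (eigenvalue fallback) factorization of
   the covariance sill − γ(h), the nugget entering the diagonal only;
3. cross-metal mixing through the Cholesky factor of the **within-zone**
   correlation matrix;
4. scaling to the within-zone sd, adding the zone mean, flooring at the
   published minimum.

Two calibration choices matter and are deliberate:

* **Pooled-moment decomposition.** The published sds and correlations
  are pooled over both zones, so the generator removes the between-zone
  component before simulating within-zone variation:
  Σ_within = D·R·D − p(1−p)·s·sᵀ (D pooled sds, s the shift vector,
  p the zone-1 fraction). The pooled moments of generated data then
  match the published tables in expectation, and the implied within-zone
  sds closely reproduce the survey's printed per-cluster sds. Treating
  the pooled sds as within-zone sds instead would make the two zones
  statistically inseparable (Mahalanobis separation 1.87, Bayes
  misclassification ≈ 18 %), contradicting the survey's own clean
  two-cluster solution; under the decomposition the separation is 5.9.
* **Moment-matched flooring.** Flooring Gaussian draws at the published
  minima inflates the mean — non-negligibly for high-CV metals (As:
  ≈ +7 %). Pre-floor zone means are therefore root-solved so the
  *censored* mean equals the target. Flooring still shrinks sds somewhat
  (As ≈ −15 %) and leaves a point mass at the floor; both are accepted
  as the price of hard non-negativity.

Correlation matrices transcribed at 3 decimals need not be positive
semi-definite; they are repaired by eigenvalue clipping at 10⁻⁶ and
diagonal renormalization. Matrices whose most negative eigenvalue
exceeds 0.1·p in magnitude are rejected as unrepairable.

What the generator does *not* emulate: non-Gaussian marginals and
outliers of real assay data, cross-metal spatial kernels (mixing the
per-metal kernels makes realized cross-variograms approximate),
anisotropy, the irregular survey outline (bounding box only, with an
optional mask grid), and any geodetic CRS handling beyond the fixed
equirectangular constant. Passing tests therefore demonstrate method
correctness and statistical calibration under a Gaussian, isotropic,
two-zone world — not robustness to real-data pathologies.

## Statistical behaviour under the study conditions

A sample mean over a spatially correlated field does not converge at
1/√n: with 10-km ranges in the 36.5 × 72.3 km domain its seed-to-seed
sd is ≈ 0.2 pooled-sd units regardless of n. Generator calibration is
therefore asserted on seed-averaged expectations (60 seeds), not on a
single realization. Likewise the stochastic recovery checks (LOO-CV
calibration MSE ≈ 0 / RMSSE ≈ 1 at n = 200; median fitted sill within
25 % at n = 500; the generating exponential family winning the CV
ranking plurality among the four classical families; two-zone recovery
averaging ≥ 90 % agreement at n = 200) run over 20 fixed seeds on the
survey's own bounding box with its Cr-row exponential model
(C₀ = 0.41, C = 0.64, a = 10 km) as the truth. Model-family selection is
intrinsically noisy at survey nugget levels — the per-family CV scores
differ in the third decimal — which is why the plurality, not every
seed, is the claim, and why the stable family (which contains the
exponential at ω = 1) is excluded from that particular contest.

## Numerical choices and degenerate inputs

* Covariance factorizations add a jitter of 10⁻¹⁰·sill before Cholesky
  and fall back to an eigenvalue factorization (clipping eigenvalues
  ≥ −10⁻⁶·sill) before declaring a model non-PSD.
* Kriging with a zero-sill model is rejected; zero kriging standard
  errors in LOO-CV raise an error naming the sample.
* PLI of any zero CF is 0 (log-space otherwise); empty CF vectors are
  rejected.
* Classification boundary conventions: CF thresholds belong upward,
  PLI thresholds downward, SPD boundaries (0.25, 0.75) to "moderate".
  Reported nugget/sill ratios and percentages are rounded to 2 decimals
  in output tables; classification always uses unrounded values.
* Pipeline determinism: a fixed seed reproduces every table, raster and
  report byte-for-byte (the elapsed-time provenance field aside);
  report provenance includes a SHA-256 hash of the canonical
  configuration.

## Known limitations

* Isotropy throughout; no co-kriging, universal kriging or empirical
  Bayesian kriging.
* ANOVA letters only for two groups; correlation p-values uncorrected.
* The study-area polygon is approximated by its bounding box unless a
  mask grid is supplied; classified-area percentages then refer to the
  box, not the irregular outline.
* Variogram ranges of the emulated survey are unpublished; the 10-km
  default is a plausible, not an inferred, value, and nothing in the
  tests asserts it.
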