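# Methods

This note records the statistical model, the numerical choices and the
known limitations of `mpcmr`, in the spirit of a model-documentation
page: enough detail to audit every default.

## Structural model and identification

The outcome model is Y = β₀ + ∫₀ᵀ β(t) X(t) dt + g(U, ε): β(t) is the
direct effect of the exposure at time t on the end-of-window outcome,
and the contrast of shifting the whole trajectory by a(t) is
∫ β(t) a(t) dt. Identification of a *time-varying* effect requires the
genetic effect curves αⱼ(t) on the exposure to vary in shape across
variants; if every αⱼ(t) is flat, only the cumulative effect
∫ β(t) dt is identified. The package assumes one-sample individual-level
data, valid instruments (relevance, exchangeability, exclusion), and a
linear, additive exposure-outcome model.

Expanding X(t) = μ(t) + Σₖ ξₖ φₖ(t) + e(t) (Karhunen–Loève) turns the
functional problem into a K-dimensional multivariable MR with
pseudo-exposures ξₖ and coefficients βₖ\* = ∫ β φₖ dt. The truncation
remainder ∫ β(t) e(t) dt acts as *structural pleiotropy* if it is
correlated with the instruments — the reason K is chosen to leave e(t)
small (default: smallest K explaining 95% of the positive spectrum).

## Sparse FPCA (PACE)

* **Mean.** Local-linear smoothing of all pooled (time, value) pairs
  with an Epanechnikov kernel; default bandwidth 10% of the domain
  width. Exact (non-binned); local-linear smoothing reproduces linear
  mean functions exactly.
* **Covariance.** Off-diagonal raw products (xᵢⱼ−μ̂)(xᵢₖ−μ̂), j≠k, from
  subjects with ≥2 observations, binned onto the output grid and
  smoothed with a separable-kernel weighted fit of the local model
  1 + ds + dt + ds·dt; default bandwidth 15% of the domain. The
  bilinear term matters: a pure local plane is biased upward in the
  grid corners on product-form surfaces (rank-one terms φ(s)φ(t)),
  which inflates the smaller eigenvalues; with the interaction term the
  smoother is exact for surfaces of the form a + bs + ct + dst.
  Binning makes the cost independent of the number of raw pairs (all
  moments are separable 1-D correlations), at a discretisation cost far
  below the smoothing bandwidth. The surface is symmetrised exactly.
* **Noise variance.** σ̂² = average over the central half of the domain
  of (smoothed diagonal of raw products − surface diagonal), floored at
  0. Note that under the simulator's design the exposure contains a
  Wiener component; its rough (non-smooth) part is partially absorbed
  into σ̂², which is precisely how a smoothing-based FPCA treats
  near-diagonal roughness.
* **Eigenproblem.** Symmetrised weighted eigenproblem under trapezoid
  quadrature: eig of W^{1/2} Ĝ W^{1/2}, eigenfunctions rescaled to unit
  quadrature norm. Non-positive eigenvalues are dropped; FVE is
  computed over the positive part. Sign convention: ∫ φₖ(t)·t dt ≥ 0,
  ties broken by ∫ φₖ dt ≥ 0, so orientations are reproducible across
  replicates.
* **Scores.** Best linear prediction
  ξ̂ᵢ = Λ Φᵢᵀ (Φᵢ Λ Φᵢᵀ + σ̂² I)⁻¹ (xᵢ − μᵢ) with eigenfunctions
  linearly interpolated to the subject's times; subjects are batched by
  observation count for vectorised solves. When σ̂² ≈ 0 a relative
  ridge of 10⁻¹⁰λ₁ stabilises duplicated-time designs (warned).
  Scores are shrunk: var(ξ̂ₖ) ≤ λₖ. Subjects with a single observation
  are scored but contribute no covariance pairs.
* **Output grid.** 101 equally spaced points on the observed domain by
  default; domain inferred as [min, max] of observed times unless
  stated.

## Estimation

With centered instruments Z (n×J), exposures E (n×L; scores or
basis-transformed scores) and outcome y, the CUE objective with the
homoskedastic weighting Ω̂(β) = Ê[ZZᵀ]·σ̂²(β) is a ratio of quadratic
forms; its minimiser is the k-class fixed point

    β ← [Eᵀ(P_Z − κI)E]⁻¹ Eᵀ(P_Z − κI)y,  κ = objective(β)/n,

iterated from the 2SLS start (κ=0) to relative change < 10⁻¹⁰
(max 200 iterations; non-convergence returns the best iterate with a
warning). Just-identified fits coincide with 2SLS/the Wald ratio;
over-identified fits are LIML-like. Reported covariance is
Σ̂ = (ĜᵀΩ̂(β̂)⁻¹Ĝ)⁻¹/n (estimate scale), Wald level fixed at 95%. The
intercept is absorbed by mean-centering and not reported. A numerically
exact fit (zero residual) reports objective 0 and zero covariance.
The CUE objective at the fit doubles as the Hansen-J over-identification
statistic against χ²(J−L).

Polynomial bases are evaluated in rescaled time u = (t−t₀)/T for
conditioning; fitted coefficients are therefore on the u-scale and all
reported curves/SEs are evaluated through b(t), which is scale-consistent.

## Identification-robust inference

Kleibergen's LM statistic at a candidate β₀ uses the three-step
construction: Δ̂ₖ = Ê[−Zξₖ(Y−ξᵀβ₀)Zᵀ], D̂ₖ = Ĝₖ − Δ̂ₖᵀΩ̂⁻¹ĝ, and
LM = n·ĝᵀΩ̂^(−1/2) P̂ Ω̂^(−1/2) ĝ with P̂ the projection onto
Ω̂^(−1/2)D̂. Degrees of freedom equal the number of fitted parameters L
(a rank-deficient D̂ reduces df with a warning). Ω̂^(−1/2) uses the
symmetric eigendecomposition root. Because ĝ, σ̂² and Δ̂ₖ are
affine/quadratic in β₀, all data moments are precomputed once and the
lattice scan is vectorised; a 41² lattice costs milliseconds.

Confidence regions invert the test over an m-per-parameter lattice
(default m = 41) spanning ±width·SE (default width 4) around the point
estimate; regions may be empty (warned) or disconnected (kept as-is,
the band uses the union). The pointwise band for β(t) is the min/max of
b(t)ᵀβ₀ over accepted candidates. The global no-effect test evaluates
the statistic at β₀ = 0.

The width default matches the search region of the full-scale
reference design (n = 10 000). The requirement behind it is that the lattice cover
the whole non-rejected region: in the reduced-n coverage study shipped
in the test suite (n = 3 000) a ±4·SE lattice is demonstrably clipped
(accepted points on the lattice boundary in most replicates), so that
study widens the search to ±8·SE. Users can check clipping by looking
for accepted points on the boundary of `lm_region.csv`.

## Instrument-strength diagnostics

Conditional F per pseudo-exposure k: partial the instrument-predicted
part of the other exposures out of Eₖ (equivalently, 2SLS of Eₖ on
E₋ₖ), regress the residual on Z, and form
F = (ESS/(J−L+1)) / (RSS/(n−J−L)). With L=1 this is the ordinary
first-stage F. The degrees-of-freedom convention is this package's
definition; it reproduces the reference instrument-strength values used in the
acceptance checks within ±15%.
Diagnostics report conditional F on the principal-component scores
(basis-transformed exposures under a polynomial basis are nearly
collinear by construction, so their conditional F is close to 0 and not
informative about the genetic instruments).

Genetic association curves are reconstructed as
α̂ⱼ(t) = Σₖ [côv(Zⱼ,ξₖ)/v̂ar(Zⱼ)] φₖ(t).

## Synthetic-data generator

The simulator reproduces the validation design: X(t) = Σⱼ αⱼ(t)Gⱼ +
U₀ + U(t) + ε_X(t) on [0, 50], Gⱼ ~ Binomial(2, 0.3) i.i.d. (J = 30),
U₀ ~ N(0,1), U and ε_X independent Wiener processes with variance 1 at
t = 50; Y = ∫ β(t)X(t)dt + 10[U₀+U(50)] + ε_Y with ε_Y ~ N(0,1) (an
independent Wiener process evaluated at the end of the window).
Scenario A: αⱼ(t) = 0.05 sin(aⱼt) + bⱼ, aⱼ,bⱼ ~ U(−0.1,0.1);
Scenarios B/C: αⱼ(t) = aⱼ + bⱼt with slopes U(−0.004,0.004) /
U(−0.01,0.01). Outcome shapes 1–6: null, constant 0.1, 0.02t,
0.5−0.02t, and the two threshold shapes.

Choices the design leaves open, fixed here once: dense simulation grid
of 501 points (0.1 spacing); Wiener increments N(0, Δt/50); the 10
observation times drawn uniformly without replacement from the dense
grid per subject; trapezoid quadrature for every time integral; one
master seed expanded into independent named substreams (genotypes,
coefficients, paths, sampling, outcome) so components can be redrawn
independently.

Two calibration facts about this generative law, as implemented: the
average per-timepoint genetic R² is ≈ 0.044 under Scenario B but
≈ 0.029 under Scenario A (closed-form and Monte-Carlo agree); the
package reports the A/B average. The first two eigenfunctions under
Scenario B are approximately — not exactly — linear (R² vs a linear fit
0.93–0.96 at n = 10 000).

What the simulator does *not* emulate: measurement error distinct from
the trajectory (observations are exact reads of the latent path),
missingness or informative observation times, selection/survival bias,
time-varying instruments, binary outcomes, and population structure in
the genotypes. Passing tests therefore demonstrate correctness of the
method under its own assumptions, not robustness to these features of
real cohort data.

## Problem sizes used in the shipped checks

The reproduction script uses the full design size (n = 10 000) with 30
replicates per scenario (the full-scale reference design uses 1000). The coverage
study uses n = 3 000 with 200 replicates per cell, sharing each
replicate's exposure side across the three outcome models; LM size
calibration uses 1000 replicates of a direct linear IV design at
n = 2 000. These sizes are the package's chosen trade-off between
Monte-Carlo error and a test run a laptop can complete.

## Known limitations

* One-sample, individual-level data only; no two-sample or
  summary-statistic mode.
* Coverage of β(t) at a timepoint is only as good as the basis: with a
  misspecified basis (e.g. threshold effects under a linear basis) the
  robust band covers the *projected* effect, not the true one, and
  undercovers where the approximation bias is largest — the strongest
  instruments expose this first.
* Fixed smoothing bandwidths (no GCV); very irregular designs may need
  manual bandwidth adjustment.
* The conditional-F degrees-of-freedom convention is one of several in
  circulation; comparisons across software should expect few-percent
  differences.
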