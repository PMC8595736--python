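# Methods

## The model

`glediff` models the lateral (two-dimensional) diffusion of a membrane
protein's center of mass as a generalized Langevin equation (GLE),

    M dU/dt = - ∫₀ᵗ ζ(t-u) U(u) du + Ξ(t),

with Gaussian colored noise Ξ tied to the friction kernel ζ by the
fluctuation-dissipation theorem.  The kernel superposes an instantaneous
viscous response and a retarded (elastic) response of the lipid matrix:

    ζ(t) = M [ ωs² δ(t/τs) + ω₀² e_{λ,ν}^δ(t/τ) ],
    e_{λ,ν}^δ(x) = x^{ν-1} E_{λ,ν}^δ(-x^λ),

where E_{λ,ν}^δ is the three-parameter Mittag-Leffler (Prabhakar) function.
For 0 < λ ≤ 1 and 0 < λδ ≤ ν ≤ 1 the elastic component is completely
monotone — a nonnegative superposition of exponential decays with rate
density p(f) (the relaxation-rate spectrum).  The Laplace transform of the
kernel is

    ζ̂(s) = ξs + ξp (τs)^{δλ-ν} / (1 + (τs)^λ)^δ,
    ξs = M ωs,  ξp = M ωp,  ωp = ω₀² τ,

and every observable follows from the resolvent ĝ = 1/(Ms + ζ̂) via

    Cv(t) = d kB T g(t),   D(t) = kB T ∫₀ᵗ g,   MSD(t) = 2 d kB T ∬ g,

(d = spatial dimension, default 2).  The Brownian constraint δλ = ν makes
the zero-frequency friction finite, giving a ballistic → subdiffusive →
Brownian crossover with exact long-time diffusion coefficient
D∞ = kB T/(ξs + ξp); the VACF then decays as a negative power law
∝ t^{-1-λ} (the Γ(-λ) < 0 prefactor; λ must be non-integer).  Both
algebraically equivalent prefactor forms (ξ-ratio and ω-ratio) are
evaluated and asserted equal at run time.

A useful subtlety: D(t) overshoots D∞ at the end of the ballistic regime
(it peaks near kB T/ξs ≈ (1+φ) D∞, φ = ξp/ξs) and approaches the plateau
*from above* through the subdiffusive window, because the VACF tail is
negative.  With the reference parameter set, |D(t)/D∞ - 1| remains above
5% out to ~100 ns and first comes within 3% at lags of order hundreds of
ns — the quantitative sense in which Brownian motion is "recovered at
~400 ns".

### Parameters and units

| parameter | meaning | unit | reference value |
|---|---|---|---|
| M | particle mass | g/mol | 41 697 |
| T | temperature | K | 310 |
| ωs | viscous-friction frequency; 1/ωs ends the ballistic regime | ps⁻¹ | 0.98 |
| ωp | retarded-friction frequency, ωp = ω₀²τ | ps⁻¹ | 447 |
| τ | elastic response timescale (spectrum peak at 1/τ) | ps | 13 400 |
| λ, ν, δ | Prabhakar exponents; δλ = ν for a Brownian long-time limit | — | 0.715, 0.715, 1 |

Internally everything is computed in MD-native units (g/mol ≡ amu, nm, ps,
K, kB = 0.00831446 kJ mol⁻¹ K⁻¹, so kJ/mol ≡ amu nm² ps⁻²).  Conversions to
laboratory units happen only at the API boundary: friction in Pa·s·μm
(× 10¹⁵/N_A from g mol⁻¹ ps⁻¹) and diffusion coefficients in μm²/s (× 10⁶
from nm²/ps).

## Numerical evaluation of the Prabhakar function

`ml3_negative` evaluates E_{λ,ν}^δ(-x) on x ∈ [0, 10⁶] to ~10⁻¹⁰ relative
accuracy with per-point adaptive method selection:

1. **float64 power series** Σ_k Γ(δ+k)/(Γ(δ)k!Γ(λk+ν)) (-x)^k, accepted
   only when its cancellation estimate max|term|/|sum| stays below 10³;
2. **algebraic large-x expansion** x^{-δ}/Γ(δ) Σ_j (-1)^j Γ(δ+j)/j!
   x^{-j}/Γ(ν-λ(δ+j)), evaluated fully in log space with reciprocal-gamma
   reflection; the optimal truncation point is chosen on the envelope
   Γ(1-z)/π rather than on individual terms, which vanish spuriously at the
   sine zeros; accepted when the envelope at truncation is below 10⁻¹¹ of
   the sum;
3. **adaptive-precision series** (mpmath) in the crossover band, with
   working precision sized from the series peak located via log-gamma on a
   float grid.  Parameters are promoted to arbitrary precision *before* the
   gamma-argument arithmetic: float64 rounding of λk+ν is amplified by the
   full cancellation of the series and was observed to corrupt the sum
   completely at 10¹³-fold cancellation.

Two independent routes check this evaluation in the tests: a plain
high-precision term-by-term oracle, and adaptive quadrature of the spectral
superposition ∫ p(f) e^{-ft} df (valid in the CM region), which agrees to
better than 10⁻⁸.

The spectrum p(f) uses the principal branch θ(f) = atan2(sin(πλ)(fτ)^λ,
cos(πλ)(fτ)^λ + 1).  Outside the CM region evaluation proceeds with a
warning (the density may change sign).  Note ∫p(f)df = e(0⁺) diverges for
ν < 1; only Laplace-weighted integrals are used.

## Numerical inverse Laplace transform

Two independent algorithms, each in a fast float64 form and a
multiprecision form (the latter delegated to `mpmath.invertlaplace`):

* **fixed Talbot** — cotangent contour with nodes s = δ_k/t, so the contour
  re-centres per time point automatically (per-decade behaviour for free);
* **de Hoog** — quotient-difference-accelerated Fourier expansion, grouped
  per decade of t with period 4·max(t) per group.

Error control is empirical and two-tiered.  The float64 estimate is the
*maximum* of the node-doubling difference and the cross-algorithm
difference: on Prabhakar-type branch-cut transforms the fixed-Talbot
contour sum can converge to a false plateau (observed errors up to ~17% on
values far below the curve scale) that node doubling alone does not detect,
while two independent algorithms disagree visibly.  Points that miss the
accuracy goal escalate to multiprecision rounds of increasing degree
((60,80), (120,160), (240,320)), each round again cross-checked against the
other algorithm; points that still fail raise an `AccuracyError` naming the
offending times.  The same false-plateau phenomenon affects multiprecision
fixed Talbot up to degree ~100 on rare parameter sets, which is why the
cross-algorithm check is kept inside the escalation.

Accuracy statements for sign-changing originals (the velocity relaxation
function g crosses zero) are necessarily relative to the curve scale near
the crossing; pointwise relative error is unbounded at a zero for any
method.  The known-pair battery (exponential, ramp, one-parameter
Mittag-Leffler, damped oscillation) passes at 10⁻⁸ relative; the
dual-method agreement on model transforms is ≤ 10⁻⁶ (pointwise for the
positive transforms, curve-scale for g) over 8 decades of lag.

## Trajectory estimators

Time-averaged MSD and VACF use the FFT correlation identity (O(N log N)),
averaging over all overlapping origins; ensemble averaging applies across
trajectories.  An O(N²) double-loop reference implementation is kept for
cross-checks (agreement ≤ 10⁻¹⁰).  Velocities default to central
differences when not stored.  The local exponent α(t) = dlogMSD/dlogt and
D(t) = MSD/(2dt)·α(t) are computed on a log-uniform resampling smoothed by
a 7-point local quadratic (Savitzky-Golay) filter; raw finite differences
of noisy MSDs are unusable.

The Gaussianity diagnostic builds the empirical cumulative distribution
Π(r², Δ) of squared displacements over overlapping origins (Hazen plotting
positions keep Π < 1) and regresses log(-log(1-Π)) on log r over the
central quantile window (default 10-90%).  Gaussian diffusion gives slope
2 at every lag; heavy-tailed displacement mixtures fall measurably below.
Overlapping origins are declared in the distribution's metadata (the
origin-spacing convention is a package choice; independent windows would
only enlarge the variance).

Shell selection ranks particles by residence fraction within a threshold
distance (default use case: 3 nm around the protein) with ties broken
toward lower particle index.

## Bayesian fitting

Both model flavours build in the Brownian constraint:
M1 fits θ = (ωs, ωp, τ, λ, δ) with ν = δλ; M2 fits θ = (ωs, ωp, τ, λ) with
δ = 1, ν = λ.  The likelihood is Gaussian and independent per lag with
σᵢ = σ_rel·MSDᵢ (default σ_rel = 0.02) unless per-point σ are supplied; the
error model behind any particular experimental curve is the user's to
declare.  Fit lags are resampled to log spacing (40/decade, capped at 300)
so no regime dominates χ².  The model MSD comes from Eq.-form
MSD̂(s) = (2d kB T/M)/(s²(s + ωs + ωp/(1+(τs)^λ)^δ)) inverted by a
vectorised fixed-Talbot rule whose (τ,λ,δ)-dependent complex power is
shared across the (ωs, ωp) grid block — the step that makes dense grids
affordable (validated at 5·10⁻¹⁰ against the error-controlled inverter).

The flat-prior posterior is evaluated on a rectangular grid (log axes for
ωs, ωp, τ; linear for λ, δ) with **adaptive refinement**: each stage
rebuilds the grid on the bounding box of all points within Δχ² ≤ 25 of the
stage optimum, padded by one cell (four cells where the box touches a grid
edge, since the optimum may lie outside), and refinement stops when the
posterior's effective sample size on the grid reaches `ess_target`
(default 50) or the box stops shrinking.  A single wide grid cannot resolve
posteriors orders of magnitude narrower than its spacing; the Δχ² box (as
opposed to a credible-interval box) keeps competing ridges of degenerate
posteriors — notably the λδ trade-off of M1 — inside the refined grid.
Even so, M1 at desk-scale grids needs the coarse-then-finer workflow (scan
wide, then refine the scale parameters while both exponents span their full
range); fitting M1 to δ = 1 synthetic data then concentrates the δ marginal
near 1, the indication that the four-parameter flavour suffices.

Summaries: posterior mean (point estimate), mode, equal-tailed 95%
intervals (the interval convention is flagged in the diagnostics), 1D/2D
marginals, reduced χ² at the posterior mean, and derived parameters
(ω₀ = √(ωp/τ), ξs, ξp, D∞) propagated through the posterior with weighted
quantile intervals.  An affine-invariant ensemble sampler (emcee) is the
alternative backend; convergence is reported via the split-chain statistic
(warning above 1.05) and chains are bitwise-reproducible for a fixed seed.

## Synthetic-data generator

The generator defines the package's study conditions:

* `noisy_msd` — the analytic model MSD at 300 log-spaced lags spanning
  0.1 ps - 5 μs with 2% relative multiplicative Gaussian noise: a stand-in
  for MD-derived MSD curves of a single protein at infinite dilution.  It
  does *not* emulate the correlated sampling noise of a real time-averaged
  MSD (adjacent lags of MD curves share origins and are strongly
  correlated), so recovery tests validate the inference machinery, not the
  statistics of any particular MD estimator.
* `simulate_gle` — trajectories of the GLE itself via Markovian embedding.
  The elastic kernel is discretised into K exponential modes: rates at the
  spectral mass centroids of log-spaced cells over the reciprocal of the
  target time window, nonnegative weights refined by bounded least squares
  against ω₀²e(t/τ) on a dense log grid (≤1% contract, typically ≪0.1%),
  plus one heavily weighted equality row pinning the zero-frequency
  friction Σc_k/f_k = ωp so the embedded system has exactly the model's D∞
  (without it the unrepresented kernel tail shifted D∞ by ~25%).  Each mode
  is an auxiliary variable coupled antisymmetrically to the velocity; the
  full linear SDE (x, u, ŝ₁..ŝ_K) per component is propagated by its exact
  discrete-time transition kernel (matrix exponential + van Loan noise
  covariance), so equipartition <u²> = kB T/M holds exactly at any dt and
  initial states are drawn from the exact stationary distribution.  The
  kernel below the window start is unrepresented; ensemble statistics are
  trustworthy for lags ≳ 100× the window's t_min (the bias decays as
  (t_min/lag)^λ) — comparisons in the tests respect that domain.
  dt must still resolve the fastest mode (dt·f_max ≤ 0.1) so that sampled
  VACF/MSD resolve the kernel dynamics.
* `brownian2d` — plain Gaussian steps, the null case for the Gaussianity
  diagnostic.

## Problem sizes used by the shipped checks

The acceptance script fits 300-lag synthetic curves on 13-point-per-axis
refined grids (a few tens of seconds), evaluates the VACF tail on 40 lags
in 10-200 ns, and runs one 10⁶-step Brownian walk; the simulator
consistency test uses 200 trajectories of 2·10⁵ steps.  These sizes were
chosen so each check is decisively more precise than the tolerance it
guards while remaining desk-scale.

## Known limitations

* The fitting machinery assumes independent Gaussian noise; real
  time-averaged MSDs have strongly correlated errors across lags, which
  narrows credible intervals artificially when ignored.
* Finite-size (periodic-box) corrections to D∞ from simulation data are
  out of scope; fitted D∞ reflects the input curve as given.
* The grid posterior assumes the refined box eventually contains and
  resolves the dominant mode; strongly multimodal posteriors outside the
  M1-ridge pattern should use the MCMC backend.
* Complex-argument Mittag-Leffler evaluation and non-CM parameter
  guarantees are out of scope; outside the CM region the spectrum may be
  signed and the simulator refuses to embed the kernel.
* Simulated trajectories represent the kernel only within the configured
  mode window (plus the pinned zero-frequency friction); observables at
  lags below ~100× the window start carry a documented systematic bias.
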