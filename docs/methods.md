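# Methods

## Model and assumptions

A pixel's fluorescence decay is modelled as a two-component exponential
mixture: a donor-alone species with lifetime τ_D and a FRET species with
lifetime τ_F ≤ τ_D, mixed with molecular fraction f_D (fraction of donors
engaged in FRET). Because each molecule emits in proportion to its
lifetime, the *intensity* fraction of the FRET species is
φ = f_D τ_F / (f_D τ_F + (1−f_D) τ_D) ≤ f_D; all histogram-level statistics
are φ-weighted. Assumptions: the donor-alone decay is mono-exponential; the
FRET population has a single (narrow) transfer rate; τ_D is known from a
donor-only reference and is spatially uniform; excitation is periodic at
the laser repetition rate (default 80 MHz, window T = 12.5 ns) and the
decay wraps across windows. Multi-exponential donors, acceptor-channel
quantities and FRET-efficiency/distance conversion are out of scope.

## The three non-fitting estimators

**Phasor (polar).** u and v are the cosine and sine transforms of the
normalized decay at the fundamental angular frequency ω = 2π/T. A
mono-exponential lies on the semicircle u² + v² = u; the mixture phasor is
the φ-weighted point on the chord joining the donor phasor P_D to the FRET
phasor P_F. Inversion intersects the line through P_D and the measured
point with the circle, discards the structural root at τ_D (Vieta), reads
τ_F from the second intersection and φ from the position along the chord,
then converts φ → f_D. Only the fundamental harmonic is used.

**Moments.** E{t} and E{t²} of the mixture are
m₁ = φτ_F + (1−φ)τ_D and m₂ = 2[φτ_F² + (1−φ)τ_D²]; with τ_D fixed the 2×2
system gives τ_F = (τ_D m₁ − m₂/2)/(τ_D − m₁) and φ = (τ_D − m₁)/(τ_D − τ_F).
A solution is accepted only when τ_F ∈ (ε, τ_D−ε) (ε = 10⁻⁶ ns) and
φ ∈ [0, 1]; otherwise the pixel is flagged invalid. This is the route's
documented failure mode near its validity limits (small f_D, few photons or
gates), where the defining residual can have several admissible roots — a
non-unique root set is likewise flagged, never silently resolved.

**Minimal fraction mf_D.** Given only the mean lifetime ⟨τ⟩ = m₁ and τ_D,
every τ_F yields a candidate f_D; the minimum over τ_F (attained at
τ_F = ⟨τ⟩/2) is mf_D = τ_D(τ_D−⟨τ⟩)/[τ_D(τ_D−⟨τ⟩)+⟨τ⟩²/4]. It equals f_D
exactly when τ_F = ⟨τ⟩/2 and underestimates it otherwise (at
τ_D = 2.5 ns, τ_F = 1.5 ns the asymptotic deficit is 0.016/0.046/0.099 for
f_D = 0.25/0.5/0.75).

Boundary convention: a measurement at (or beyond) the donor reference —
phasor at P_D, m₁ ≥ τ_D — returns f_D = 0 with τ_F undefined (NaN) and a
`no_fret` flag rather than an error, so per-pixel maps stay total.
Moment outputs are additionally blanked wherever the reference fraction
(polar estimate where valid, else mf_D) is not strictly greater than 0.2.

## Finite-gate and finite-window correction

Time-gated systems split the window into N_ch contiguous gates of width
w = T/N_ch (N_ch as low as 4). The integral transforms must then be
approximated from N_ch numbers, which biases the naive estimates severely
at low N_ch. The correction inverts the *discretized* forward operator:
for a wrapped, binned mono-exponential the channel profile is proportional
to r^k with r = e^(−w/τ), so every discrete statistic the raw estimator
reports — ũ(τ), ṽ(τ), m̃₁(τ), m̃₂(τ) and the per-photon normalizer l₀(τ) —
is a closed-form finite geometric sum. A binned two-component decay is an
l₀-weighted convex combination of two such profiles, so each inversion
reduces to a 1-D root-find on smooth curves:

- *mean lifetime*: m̃₁ is monotone in τ; vectorized bisection inverts it
  (corrected ⟨τ⟩, hence mf_D);
- *polar*: the collinearity residual cross(P̃(τ)−P̃_D, P−P̃_D) has a
  structural simple zero at τ = τ_D which is divided out; the remaining
  sign change on (0, 4τ_D] locates τ_F (a root beyond τ_D ⇒ no FRET);
- *moments*: eliminating the mixture weight between the two moment
  equations leaves one residual in τ_F, likewise deflated at τ_D and
  scanned on (0, τ_D).

Sign changes are bracketed on a fixed geometric grid (256 points for the
polar curve, 200 for the moments) and refined by 60 bisection steps, all
vectorized across pixels; no per-pixel iterative fitting is involved. By
construction, noiseless binned decays invert exactly (< 10⁻¹⁴ observed) at
every N_ch from 4 to 64 and the correction is convention-independent.

**Quadrature convention.** Counts are integrals of the intensity over
their gates, so the plain channel sum is the exact intensity integral over
the window; the default ("midpoint") therefore discretizes only the
transform kernel, evaluated at gate centres t_k = (k+½)w with uniform
weights — a second-order product rule. Two degree-1 alternatives are
selectable per acquisition config (`trapezoid`, integrating the linear
interpolant of the centre samples over the full window, and
`interior-trapezoid`, the textbook rule with half end-weights). The
interior rule halves the weight of the peak channel and biases the raw
phasor by ~0.025 even at 64 channels; it is retained only for comparison.
Corrected results are identical under all three because the reference
curves use the same weights.

**Residual biases accepted.** The detection jitter (IRF) is *not* modelled
in the reference curves — estimation runs directly on histograms — and the
mono-exponential mean-lifetime inversion applied to a mixture carries a
small model discrepancy (≲ 0.02 ns at N_ch = 4). Both are part of the
method's real-world error budget and are visible in the gate-sweep
experiments.

## Simulator

Per photon: a Bernoulli draw with probability φ selects the branch, an
exponential time with the branch lifetime is drawn and wrapped modulo T
(periodic re-excitation; this makes the simulated phasor agree with the
continuous model at the fundamental), then Gaussian detection jitter with
σ = FWHM/2.355 is added. Jittered times falling outside [0, T) are, by
default, recorded in the boundary channel (`edge="clip"`): physically, the
gate phase is set so the excitation instant lies just inside the first
gate, so the IRF spread moves photons between interior channels only.
Wrapping the jitter instead (`edge="wrap"`) would transfer ~2% of photons
(200 ps IRF) to the far end of the window and bias the raw first moment by
≈ +0.2 ns — a gate-phase artefact, not a property of the estimators —
while leaving the phasor essentially unchanged (e^{iωt} is continuous
across the wrap point); both `wrap` and `discard` remain selectable.

Acquisition presets: **TCSPC** — 64 channels, 32 ps FWHM IRF, no offset,
no smoothing; **time-gated** — N_ch ∈ {4…64} contiguous gates, 200 ps FWHM
IRF, a Poisson-distributed intensifier offset with per-pixel total mean
190 photons (realized as independent Poisson(190/N_ch) per gate; the
offset is interpreted as a per-pixel total, matching its grey-level
equivalent at the camera gain of 8.5 grey/photon), and a 3×3 average
filter applied to each gate plane (edge pixels use the clipped
neighbourhood so uniform stacks are preserved). Images default to 64×64
pixels (4096 decays). All randomness flows through one
`numpy.random.Generator`, so fixed seeds give bit-identical stacks.

Not emulated: detector dead-time, pile-up and afterpulsing; camera read
noise and gain fluctuations; optical point-spread blur beyond the 3×3
filter; spatial heterogeneity of τ_D; autofluorescence. Passing tests
therefore demonstrate estimator behaviour under ideal counting statistics
with the stated instrument effects, not performance on arbitrary real
data.

## Precision theory

Each fraction estimator is a smooth function of sample means of per-photon
statistics (t for mf_D; cos ωt, sin ωt for the polar route; t, t² for the
moments). With the per-photon covariance C (closed form: mixture raw
moments up to order four, and the mixture phasor at the first two
harmonics) and inversion map f, the delta method gives
E[f̂] ≈ f(µ) + tr(H C)/(2N) and SD[f̂] ≈ √(gᵀCg/N), with g and H the
gradient and Hessian at the population value (evaluated by central finite
differences on the closed-form maps). These formulas assume continuous,
untruncated sampling; binned finite-window acquisitions deviate, so
simulation comparisons use the 64-channel TCSPC geometry.

What the oracle shows. For mf_D the map is nearly linear and the
expansion tracks Monte Carlo closely (means within MC error; stds within
~13% at N = 120, ~2% at N = 1000), with the expected value within 0.05 of
its asymptote by N ≈ 120. For the polar and moment fractions the
first-order stds match the robust MC spread at moderate N and the
σ ordering mf_D < moments < polar holds throughout, but the *mean*
expansion has very large 1/N coefficients at small fractions
(B ≈ +270 at f_D = 0.25): the MC oracle confirms the estimator mean
genuinely converges this slowly — at f_D = 0.25 and N ≈ 140 the phasor
displacement from the donor point is comparable to its noise, the
inversion is effectively unidentifiable, and no consistent error
propagation yields fast mean convergence there. The same
non-identifiability shows up in simulation as a low-biased τ_F median at
low f_D and low N. Practical accuracy claims at small fractions should
therefore rest on medians of the simulated pipelines, not on the mean
expansion.

## Fitting baseline

Damped least squares (scipy `least_squares`, bounded reflective variant)
on the binned two-component model with τ_D fixed and the total amplitude
pinned to the observed counts; free parameters (f_D, τ_F) with bounds
f_D ∈ [0,1], τ_F ∈ (0, τ_D]. Routine-software settings are the default:
10 damped iterations (max_nfev = 3 per iteration for a 2-parameter
2-point Jacobian) and a relative chi-square tolerance of 10⁻³, stopping at
whichever comes first; the last iterate is returned (flagged) when the cap
binds. Residuals are unweighted by default; Poisson weighting is an
option. The "max ratio 1" constraint is read as the interacting-amplitude
fraction bounded by one, the only dimensionless ratio in the model. Under
these settings the fitted parameters depend visibly on the starting values
at N = 200 photons and stabilize by N = 10⁵ — the behaviour that motivates
the non-fitting estimators.

## Pipeline conventions

- Summaries are medians with interquartile ranges; per-pixel estimate
  distributions are skewed with occasional wild values near validity
  limits. Summary tables expose both `iqr` (q₃−q₁) and `qdev`
  ((q₃−q₁)/2, the half-length of a median-to-quartile error bar, the
  dispersion scale used for cross-study comparison).
- Background: `background_subtract` floors at zero and counts floor events
  (for sanitizing stored stacks); the estimation path in `analyze_stack`
  subtracts the background *signed*, because the quadrature functionals
  are unbiased on zero-mean residuals whereas flooring biases late
  channels upward (at N = 200, N_ch = 64 flooring shifts the median mean
  lifetime by ≈ +0.2 ns).
- Pixel coordinates are (row, col); TIFF page k is gate k; the time origin
  is the window start and no per-pixel t₀ is estimated.
- Grey-level data are converted to photons via the S-factor (camera gain,
  grey levels/photon), estimated as the slope of a variance-vs-mean line
  over ≥3 exposure levels.
- Empty or background-dominated pixels (non-positive total) yield NaN maps
  with all validity flags false.

## Problem sizes

Simulation studies use 4096 decays (64×64 pixels) per condition — photon
budgets 100–1000 for the TCSPC sweep, gate counts {4, 8, 16, 32, 64} at
200 and 1000 photons for the gated grids. Theory/MC cross-checks use
2×10⁴ replicates routinely and 10⁵-scale draws where the quantity needs
them. The full test suite runs in well under a minute of CPU; the
from-scratch reproduction script in about one minute.

## Known limitations

- All three estimators require an accurate, spatially uniform τ_D; errors
  in τ_D propagate directly into f_D and τ_F.
- mf_D is a deliberate lower bound; its deficit grows as τ_F moves away
  from ⟨τ⟩/2 (up to ~0.1 at f_D = 0.75 for the study lifetimes).
- The moment route is unreliable for f_D ≲ 0.2, very low photon counts or
  4 gates; its outputs are masked rather than repaired.
- τ_F is statistically unidentifiable at low f_D with ≲200 photons
  regardless of estimator; fraction estimates degrade more gracefully.
- The IRF is accepted as a (small) bias rather than deconvolved; systems
  with IRF width comparable to the gate width at high gate counts would
  need an IRF-aware forward operator.
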