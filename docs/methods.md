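# Methods

This note documents the models, estimators, defaults and numerical choices
implemented in `raginfer`, and what the synthetic-data validation does and
does not demonstrate.

## Data model

The canonical input is a long-format delimited table, one row per cell per
frame (`cell_id,parent_id,time_min,length_um[,area_um2][,midcell_au]`),
grouped into per-cell records.  Internally, times are minutes since each
cell's birth; the colony-clock birth time is kept for genealogy checks.
Interior frames are uniformly spaced at the sampling interval (default
3 min); the final sample of a divided cell may close a *partial* interval,
because division is an event between frames.  In the synthetic generator the
division rule is honoured exactly at that event — quantizing division to the
frame grid would systematically distort size-control statistics (an "adder"
would no longer add a fixed length).

Division is encoded by the presence of daughters (or an explicit flag for
divided leaves); cells without either are censored and excluded from all
division-conditioned statistics.  Validation checks id uniqueness, time
monotonicity and grid uniformity, genealogy (acyclic, ≤ 2 children, birth
after the mother's division), and mass conservation at division.  The
conservation tolerance is exact (1e-9 µm) on noise-free data and widens to
6·√3·sd when the table declares a measurement-noise sd, since three
independently noisy lengths enter the daughter-sum check.

## Wavefront inference

For each discrete time-since-birth t, lengths of all cells still growing at
t are fit by least squares against birth length (polynomial order 1 by
default; higher orders are supported to verify that they add nothing, which
is also what the per-time scatter shows).  Times with fewer than 3 cells are
dropped.  The fitted family (a_t, b_t) defines the average length surface
L(t, l_b) = a_t + b_t·l_b on a conditioning grid (default 1.9:0.1:2.9 µm).

**Birth-length bias.**  Measurement noise in the conditioning variable
attenuates every slope by λ = var(true l_b)/var(observed l_b) (regression
dilution).  Because L(0) *is* the observed l_b, the t = 0 fit has slope 1 by
construction and carries no information about the noise; the noise variance
is instead estimated as half the residual variance of the first
positive-time wavefront, where the two axes carry independent noise copies
and biological scatter accumulated over one frame is negligible (at 3 min
and ~0.05 µm/min rates, growth-rate dispersion contributes ≪ the ~0.07 µm
residual scale).  Slopes are divided by λ, intercepts shifted by
−b_t·μ(1−λ)/λ, and the t = 0 fit pinned to the identity, so the corrected
family satisfies L(0, l_b) = l_b exactly.  If the estimated noise variance
exceeds the observed birth-length variance the correction is refused
(degenerate).  A user-supplied noise sd bypasses the estimate.

**Division cutoff.**  Only t up to the minimum generation time is valid.
Beyond it the average conditions on not-yet-divided survivors; when cells
differ in growth rate, fast growers divide first and the survivor average
underestimates the population (verified in simulation with per-cell rate
variability).  The surface is still computed past the cutoff but masked.

**Rates.**  Each trajectory is smoothed by a centered moving average
(default 5 frames = 15 min) whose half-width shrinks symmetrically toward
the mask edges — an asymmetric window would bias the ends of a curved
trajectory, exactly where the RAG model is most informative — and then
differentiated with central differences (second-order one-sided at the
edges).  On noise-free simulated colonies this reconstructs linear,
exponential and RAG rate laws to ≈ 0–2% RMS; the residual error is
smoothing/discretization bias, largest where curvature is strongest.

**Uncertainty.**  Bootstrap resamples whole cells with replacement
(preserving within-cell correlation) and reruns the entire pipeline per
replicate; bands are the point estimate ± 2 bootstrap sd per (t, l_b).
Replicates that lose support at some time contribute nothing there and are
counted.  In 100-colony simulation experiments the 2σ bands cover the true
rate at ≳ 90% of grid points.

**Reverse-time construction.**  Conditioning on division length uses
offsets τ = t − t_d ≤ 0; per-cell lengths are linearly interpolated onto the
offset grid (division times are off-grid by construction).  The family is
valid while |τ| does not exceed the shortest generation time.  No dilution
correction is applied on the division-length axis; the reverse family is
used for shape diagnostics (late-time linearity), not absolute calibration.

## RAG kinetics

Parameterization is (v_sat, s₀, β, γ): the Michaelis–Menten prefactor
α·C/(K_m+C) and N_max are not separately identifiable from rate curves and
never need to be.  Closed forms:

* γ = 0: v(t) = v_sat − v_sat(1−s₀)e^{−βt},
  L(t) = l_b + v_sat·t − v_sat(1−s₀)(1−e^{−βt})/β.
* γ > 0: v(t) = v_sat − v_sat(1−s₀)·exp(−(β/γ)(e^{γt}−1)); L by adaptive
  quadrature (absolute tolerance 1e-9 µm).  Both agree with independent ODE
  integration to < 1e-8.

Fitting is nonlinear least squares with β (and γ) shared across
birth-length curves and (v_sat, s₀) free per curve — the most parsimonious
scheme consistent with the observed robustness of the saturation timing
across birth lengths.  Residuals are weighted by inverse bootstrap band
widths when bands are present.  A deterministic multi-start over 8
log-spaced β ∈ [1e-3, 1] min⁻¹ (crossed with two γ starts for the
self-recruitment variant) guards against local minima; bounds keep
s₀ ∈ (0, 1].  Reported saturations are relative quantities (v(0)/v_sat),
not absolute site counts.  The γ = 0 model is nested in γ > 0, so the self-recruitment
residual never exceeds the constant-recruitment residual; a scalar least-squares ratio
between two rate families (`fit_scale_factor`) tests whether a mutant curve
family is a pure per-site-efficiency rescaling of another.

## Synthetic colonies

The generator emulates microfluidic time-lapse data: founders with
truncated-Gaussian birth lengths (2.3 ± 0.2 µm on [1.9, 2.9]); growth by a
linear (0.046 µm/min), exponential (ln2/50 min⁻¹) or RAG law
(v_sat = 0.05 µm/min, s₀ = 0.65, β = ln2/8 min⁻¹) — all tuned so a ~2.3 µm
cell doubles in ~50 min; division by adder / sizer / timer / near-adder
rules with Gaussian rule noise; septum fraction truncated-Gaussian
0.5 ± 0.05 on [0.2, 0.8]; additive Gaussian measurement noise (default
0.05 µm, a few percent of a cell length) applied to recorded lengths only,
while true lengths drive the dynamics.  An optional per-cell growth-rate
multiplier (`growth_rate_cv`, default 0) models cell-to-cell rate
variability; it is off by default so closed-form identities hold exactly,
and switched on where a property requires heterogeneity (survivorship
bias).  Division solves the rule exactly in continuous time (see above).
Output is deterministic given the seed.

Synthetic fluorescence profiles place a Gaussian insertion peak (sd
0.25 µm) at each pole whose integrated intensity is proportional to that
pole's share of the elongation rate, over a uniform cytoplasmic baseline,
with optional per-pixel noise; cells are sampled at a uniformly random age.

What this does *not* emulate: cell-width variation, curvature/V-snapping
geometry, segmentation artefacts with length-dependent error, photobleaching
or background drift in profiles, and biological correlations between
growth rate, asymmetry and generation time.  Passing recovery tests on
these colonies demonstrates correctness of the estimators under the stated
noise model, not robustness to every artefact of real imaging data.

## Population simulations

Generation-synchronous: every cell divides once per generation with
ld = l_b·e^{α(t_t+Δt)} + Δl (exponential) or ld = L_RAG(t_t+Δt; l_b) + Δl
(asymptotically linear), daughters take truncated-Gaussian fractions f and
1−f.  Defaults: α = ln2/50 min⁻¹, t_t = 50 min (so the noise-free
stationary birth length is ≈ 2.3 µm in both modes), Δt sd = 10 min (a wide
generation-time spread), Δl sd = 0.1 µm, asymmetry 0.5 ± 0.05, 200
founders, 12 generations with a 3-generation burn-in, population capped at
2000 by random subsampling.  `noise_scale` multiplies every noise sd.
Negative division lengths are redrawn and counted.

Interpretation note: with these division formulas the exponential mode has
no size homeostasis (the division length is proportional to birth length,
so log birth length performs a near-critical random walk), while the RAG
mode adds a birth-length-independent amount and is adder-like, hence
strongly homeostatic.  The contrast in distribution width between the modes
is therefore structural, and — because every noise term enters linearly at
small noise — the *ratio* of the two CVs is essentially invariant under
`noise_scale`; reducing noise narrows both distributions proportionally
(CV ratio ≈ 3 at these defaults, at any scale).  `compare_growth_modes`
refuses configurations whose noise parameters differ, and reports sd, CV
and upper-tail-mass (fraction beyond mean + 2 sd, per distribution) ratios.

## Profile analysis

Background: the minimum of the intensity profile within the central 30% of
the cell estimates the cytoplasmic contribution and is subtracted; negative
results are clipped to zero and counted; a minimum sitting on the mid-zone
boundary (e.g. a septal peak displacing it) is flagged.  The operation is
idempotent.  Note the minimum of a noisy baseline is biased low by order
the pixel noise sd, which induces a small positive offset in corrected
intensities — visible as a small intercept in proportionality fits on noisy
profiles and absent on noise-free ones.

Polar intensity is the mean corrected intensity within 0.77 µm of each tip
(a conventional ~60-pixel pole definition; results are insensitive to
widths near this value, and the width is a parameter).  Moving averages
over cell length use a ±0.7 µm window with within-window SEM.  Tip-segment
intensities average distance-from-tip bands per pole.  Proportionality is
tested by OLS with an intercept-within-2-SE flag plus the maximum relative
deviation of the OLS line from the best through-origin line.  Demographs
sort cells by length, resample each profile to 101 relative positions by
linear interpolation, and flip rows so the brighter pole points one way.
Septum onset is the first time a mid-cell signal exceeds its baseline mean
+ k·sd (default k = 3, baseline = first frames) for ≥ 2 consecutive frames
— a deliberately simple changepoint rule; `None` when no sustained rise
occurs, including the flat-signal degenerate case.

## Problem sizes and determinism

Default validation sizes — 400–2000-cell colonies, 50-replicate recovery
experiments, 100-colony × 100-replicate bootstrap coverage — were chosen as
the smallest sizes at which the targeted effects are resolved an order of
magnitude above their sampling noise.  Every stochastic routine takes an
explicit seed and is reproducible bit-for-bit; multi-start fitting is
deterministic.

## Known limitations

* The wavefront model assumes the population mean of L given l_b is linear
  in l_b; strong nonlinearity (e.g. distinct subpopulations) calls for
  order > 1 or stratified reruns, both supported but not automatic.
* The noise-variance estimator behind the bias correction assumes
  white measurement noise; correlated segmentation errors between
  consecutive frames would bias λ upward.
* `fit_rag` treats rate-curve samples as independent; smoothing-induced
  correlation makes its internal residuals optimistic, which is why
  uncertainty should come from the cell-level bootstrap instead.
* The population simulator is generation-synchronous rather than
  event-driven in continuous time; it reproduces stationary distributions,
  not age structure or colony-time correlations.
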