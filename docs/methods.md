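# Methods

`sptkinetics` quantifies protein–chromatin binding kinetics from three
live-cell single-molecule measurements — fast-tracking spaSPT, slow-tracking
dwell-time imaging, and FRAP — and ships a stochastic simulator that
generates data with exactly the statistical structure the estimators
assume, so every stage is validated by closed-loop parameter recovery.

## Jump-length mixture model (fast tracking)

Fast tracking records sparse single molecules at Δτ = 7.477 ms (133 Hz)
with stroboscopic illumination. For each time lag nΔτ (n = 1..4) the
package pools the planar displacements r between detections exactly n
frames apart; a displacement spanning a one-frame blink gap spans two
frames and therefore counts at lag 2, never lag 1.

A single Brownian state with diffusion coefficient D observed with static
1-D localization error σ has the jump-length CDF

    P(r ≤ R | D) = 1 − exp(−R² / (4 (D·nΔτ + σ²))),

(the σ² term appears because both endpoints carry independent Gaussian
noise). The data are modelled as a mixture of 2 or 3 such states
(bound / slow / fast). σ is fixed at the configured value (default
0.045 µm) rather than fitted.

**Defocalization.** Only molecules within an axial slab of thickness dz
around the focal plane are detected (default dz = 0.7 µm; HiLo
illumination does not pin this value down a priori, so it is an explicit
assumption of the benchmark conditions). A diffusing molecule leaves the slab and
ends its track, while a bound one does not, so at lag nΔτ the observed
mixture weight of state k is

    w_k(nΔτ) = F_k·Z_k(nΔτ) / Σ_j F_j·Z_j(nΔτ),

where Z_k is the probability that a state-k molecule starting from the
(uniform) steady-state axial distribution inside the slab is still
detected n frames later. `z_correction` computes Z by deterministic
propagation of the axial density on a cell-centred grid whose cell edges
align with the slab faces: each frame interval applies a Gaussian
convolution; at each frame time mass outside the slab accrues a "missed
frame" counter and is lost after more than `gaps_allowed` consecutive
misses, exactly matching how gap-tolerant trackers link detections. The
grid spacing adapts to ≲0.5 step-σ (capped at 400 cells inside the slab;
below the cap the unresolved error is bounded by the then-negligible
escape probability). This frame-discrete, re-entry-aware survival was
chosen over the closed-form continuous-absorption eigenseries
(`slab_survival_series`, kept as an analytic cross-check) because
continuous absorption discards molecules that re-enter within the gap
tolerance — at D = 5 µm²/s and 4 lags the series gives 0.04 where the
frame-discrete value is 0.39 — and that mismatch propagates directly
into the fitted bound fraction. The implementation agrees with an
independent Monte-Carlo slab simulation to within ±0.003 across
D ∈ [10⁻⁶, 15] µm²/s.

**Fitting.** Empirical CDFs on a uniform 200-point radius grid over
[0, 3 µm] are stacked across all retained lags (lags with fewer than 50
displacements are dropped with a warning) and the mixture parameters are
estimated by box-constrained least squares (`scipy.optimize.least_squares`,
TRF). Fractions are parametrized on the simplex; diffusivities are
bounded per state (defaults: bound [0, 0.08], slow [0.08, 2.5], fast
[2.5, 25] µm²/s) so the slowest state is identifiably "bound" — D_bound
is fitted within its small window rather than pinned to 0 because
chromatin-bound molecules retain residual motion. The objective is
multi-modal, so 10 Latin-hypercube starts (fixed starts-seed) are run and
the lowest-residual solution kept, near-ties resolved toward the smaller
fast fraction. The fit is deterministic given the distribution and spec.

**Model comparison.** 2- vs 3-state fits are compared by the Bayesian
information criterion computed from the Rayleigh-mixture log-likelihood
of the pooled displacement samples at the CDF-fitted parameters
(n_par = 3 and 5; n = number of displacements). A residual-based
criterion was rejected because CDF-grid residuals are strongly
autocorrelated and their count is an arbitrary grid density; with the
ln(n) penalty the criterion is model-selection consistent, and on
simulated data it identifies the generating model with margins of ≈ +19
(2-state truth) and ≈ −500 (3-state truth).

## Dwell-time survival analysis (slow tracking)

At 500 ms exposures diffusing molecules blur out; bound molecules appear
as spots whose track length measures time-until-unbinding-or-bleaching.
`extract_dwells` takes trajectories whose every consecutive displacement
is ≤ 0.22 µm and which span ≥ 2 frames (defaults, exposed in config);
dwell = frame span × 0.5 s, right-censored at the movie end (600 frames).

The empirical survival S(t) = fraction of events with duration ≥ t is
fitted with S(t) = A·e^(−k_fast·t) + (1−A)·e^(−k_slow·t); the slow
component is read as specific binding. Photobleaching is corrected by
subtracting the apparent off-rate of a histone-like control fitted the
same way: k_corrected = k_slow − k_slow(control), residence time =
1/k_corrected, apparent half-life = ln2/k_corrected (both are always
emitted; which one headlines a condition is a reporting convention).
If k_corrected ≤ 0 the measurement is bleach-limited and no number is
emitted.

Numerical choices that matter, found by measuring estimator behaviour on
simulated ground truth:

- *Origin anchoring.* Events shorter than one frame are unobservable, so
  the empirical curve is conditioned on surviving the first frame; its
  biexponential extension no longer passes through 1 at t = 0. The model
  constraint S = 1 is therefore anchored at the last grid point where the
  empirical curve equals 1. Without this, k_slow is biased low by 3–10%.
- *Weighting and truncation.* Residuals are weighted by √(events at risk)
  and points with fewer than 5 events at risk are dropped; after a first
  pass the weights are recomputed from the fitted model's at-risk counts
  so they are independent of the noise.
- *Likelihood polish.* The weighted curve fit is ~20% less efficient than
  the Cramér–Rao bound for these mixtures, so the solution is polished by
  maximizing the interval-censored multinomial likelihood of the at-risk
  counts (Nelder–Mead from the curve-fit solution plus two perturbed
  restarts). Events still at risk at the last grid point are treated as
  right-censored there.
- *Nested-model guard.* On effectively single-exponential data (the
  histone control) the second component only chases noise and splits the
  true rate; the mono-exponential fit is kept unless the biexponential at
  least halves the weighted residual. Rates slower than 0.5/record are
  bounded away as indistinguishable from a plateau.

## FRAP

Double normalization, I(t) = (bleach−bg)/(ref−bg) scaled to pre-bleach
mean 1, cancels acquisition photobleaching to first order. Bleach-depth
normalization, I′ = (I − I(0⁺))/(1 − I(0⁺)), maps the first post-bleach
point to 0 so recovery kinetics are comparable between conditions with
different bound fractions; it is idempotent. Curves are interpolated to a
common grid and averaged with SEM; curves whose pre-bleach coefficient of
variation exceeds 5% are rejected with a logged reason (explicit QC in
place of manual curation). T90 is the first time the mean curve crosses
90% of its plateau, located by linear interpolation; the plateau defaults
to the mean of the final 10% of time points (deterministic and
noise-robust), with fitted-asymptote and fixed-value alternatives. The
90% level is referenced to the recovery plateau, not the pre-bleach
level; both are computable, the plateau is the default. If the level is
not reached the result is "unresolved within record" (None).

## Stochastic simulator

The simulator emulates what the estimators assume, with known ground
truth:

- *spaSPT*: molecules photoactivate at uniformly random frames, perform
  3-D Brownian motion with a per-molecule state (drawn from the
  equilibrium fractions) or continuous-time Markov switching when a rate
  matrix Q is supplied (integrated at Δτ/10 substeps); observed x/y add
  Gaussian error of σ per axis; a molecule is recorded only while
  unbleached (exponential hazard), not blinking (per-frame Bernoulli),
  and within ±dz/2 of focus; detections are linked with the same gap
  tolerance as real tracking. The axial coordinate reflects at
  ±axial_range/2 (default 3 µm) so the stationary axial density is
  uniform and detections are proportional to state occupancy. Motion
  blur is deliberately not modelled: stroboscopic illumination
  point-samples positions at frame times.
- *Dwell times* are drawn directly as min(Exp(k_off), Exp(k_bleach)),
  floored to the 500 ms frame grid (sub-frame events dropped, movie-end
  censoring applied); the analysis consumes only durations, so spatial
  realism would add cost without test value.
- *FRAP* curves are reaction-dominant multi-exponentials (pre-bleach 1,
  post-bleach plateau − Σ aᵢe^(−rᵢt)) wrapped in synthetic reference and
  background channels, optionally with a common acquisition decay that
  the double ratio must cancel. No spatial reaction–diffusion model is
  generated because the analyses fit none.

Identical (seed, configuration) pairs produce byte-identical outputs; a
ground-truth record (seed, all parameters, optional per-molecule state
sequences) accompanies every dataset.

What the generator does **not** emulate — camera noise, PSF shape, drift,
nuclear geometry, anomalous or confined diffusion, state-dependent
bleaching — bounds what recovery tests show: they validate the estimators
under the model's own assumptions, not robustness to real-data artifacts.

## Benchmark conditions and problem sizes

Condition presets set the simulator's bound fraction to the published
per-condition estimates (27.1/13.3% TBP, 29.3/15.4% Pol II, 8.5%
HaloTag-only; fast-tracking Δτ = 7.477 ms, σ = 0.045 µm, dz = 0.7 µm,
1 gap, 4 lags). Fitted diffusion coefficients are not reported in the
source work, so the presets fix D = (0.0025, 0.5, 5.0) µm²/s
(bound/slow/fast; 0.8/8.0 for the free-dominated HaloTag-only control)
and split the non-bound mass 30/70-ish between slow and fast —
field-realistic values chosen once. Bound-fraction benchmarks use 8 cells
× ~3,000 trajectories (5,000 molecules, 300 frames, bleaching tuned for
~10-frame tracks); recovery is within ±2 percentage points with per-cell
SD ≈ 1.4 points. Residence-time benchmarks use 5,000-event samples with
k_off set so 1/k (TBP) or ln2/k (Pol II) equals the published value,
non-specific events 10× faster at 20% weight, bleaching 0.01 s⁻¹,
analysed in triplicate with the corrected rates averaged — mirroring the
conventional biological-triplicate design, and necessary because the Fisher
information of a single 5,000-event sample bounds sd(k_corrected) at
≈ 5–6% for the slowest conditions. The FRAP T90 benchmark is a noiseless
1 Hz, 600 s curve whose analytic crossing is known exactly.

## Known limitations

- The defocalization weight treats per-lag survival as independent of
  the jump-counting details within a track (the standard approximation);
  residual bound-fraction bias on synthetic data is ≈ 0.5 points.
- Bi-exponential dwell models with rate ratios ≲ 5 are weakly
  identifiable; worst-case recovery error at the triplicate design is
  ~14% for the slowest (mitotic-TBP-like) condition.
- T90 by first crossing is biased early on noisy mean curves; use more
  cells or lower noise rather than smoothing.
- No HMM-style per-trajectory state annotation, no Bayesian posteriors,
  no k_on/k_off extraction from FRAP (out of scope).
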