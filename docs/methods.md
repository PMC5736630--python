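# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `microrheo`. Everything quantitative below is computed by
the test-suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## The observable and the regimes

The central quantity is the time-averaged, ensemble-averaged mean-squared
displacement of interfacial probe particles,
⟨Δr²(t)⟩ = ⟨(x(t₀+t)−x(t₀))² + (y(t₀+t)−y(t₀))²⟩, fitted as a power law
⟨Δr²(t)⟩ = A·tⁿ on log₁₀–log₁₀ axes over the lag window
1.67×10⁻²–1.67 s. At 60 fps this window is exactly the camera-grid lags
1–100 frames; the printed endpoints are the rounded values of 1/60 s and
100/60 s, so the window bounds are applied with 1% relative slack to keep
the grid endpoints inside. The companion magnitude is the RMS displacement
d = √⟨Δr²(t)⟩ at the grid lag nearest 1.67 s — a measured value, not the
fitted curve's value, so that d² is literally the MSD sample at that lag.

Regime labels partition the n axis: n < 0.1 elastic (solid film);
0.1 ≤ n < 0.9 subdiffusive (viscoelastic); 0.9 ≤ n ≤ 1.1 diffusive;
n > 1.1 superdiffusive (active transport). The elastic threshold 0.1 is the
conventional solid-film criterion; the diffusive band [0.9, 1.1] is this
package's choice — a band of finite width is needed to make "diffusive" a
decidable label, and ±0.1 comfortably exceeds the exponent estimator's
standard error at the packaged ensemble sizes (≲0.05). Both thresholds are
configurable and are echoed into every label and output file.

## Simulators (the ground truth)

All simulators work in μm and seconds on an unbounded plane (trajectories
are short relative to the field of view; an optional reflecting or periodic
box exists for rendering). One master seed per config is split via
`numpy.random.SeedSequence(seed).spawn(3)` into independent streams for
initial positions, dynamics, and localization noise, so the same dynamics
realization can be studied with and without noise. Identical config + seed
is bit-identical.

* **Brownian** — i.i.d. Gaussian steps of variance 2D·dt per coordinate;
  ⟨Δr²(t)⟩ = 4Dt. The thermal reference uses D = 0.15 μm²/s, which puts
  d(1.67 s) at 1.0 μm — the packaged "bacteria-free interface" condition.
  For context, Stokes–Einstein for a 0.5 μm-radius probe in water at 298 K
  gives 0.49 μm²/s; interfacial drag reduces this severalfold, hence the
  smaller reference value.
* **Fractional Brownian motion** — per-coordinate fGn via the Davies–Harte
  circulant embedding (exact covariance when the embedding is
  nonnegative-definite, which holds for every case exercised here), with a
  Cholesky factorization of the Toeplitz covariance as fallback and as the
  independent oracle in tests. Convention: per-coordinate
  Var X(t) = scale·t²ᴴ, so the 2-D MSD is 2·scale·t²ᴴ and the fitted
  exponent is 2H. H = 0.2 reproduces the n = 0.4 viscoelastic-film regime.
* **Persistent random walk** — Ornstein–Uhlenbeck velocity with 2-D rms
  speed v (per-coordinate variance v²/2) and persistence time τ_p, sampled
  with the exact joint discretization of (velocity, integrated velocity)
  over each frame interval (2×2 Cholesky of the conditional covariance), so
  there is no time-step bias at any dt/τ_p. Ensemble MSD:
  2v²τ_p²(t/τ_p − 1 + e^(−t/τ_p)), ballistic (n→2) at t ≪ τ_p, diffusive
  (n→1) at t ≫ τ_p. This is a stand-in that produces superdiffusive probe
  statistics; it makes no claim about the swimming mechanics of any
  particular strain.
* **Arrested** — stationary OU position fluctuations about fixed anchors
  with equilibrium std σ_eq per coordinate and relaxation time τ_r ≪ dt, so
  successive positions are effectively independent and the MSD is flat at
  4σ_eq² (plus 4σ_noise² when localization noise is on). The elastic-limit
  calibration uses σ_eq = 0 with 0.05 μm noise: MSD = 0.010 μm², n = 0.

Common-mode drift is injected as a cumulative displacement series added to
every particle (`apply_drift`), or as a constant velocity in the config; the
true drift series is carried in the ground truth so drift-correction can be
checked exactly.

## Aging scenarios

A scenario is an ordered list of (surface age, simulator config) stanzas,
each an independent movie — matching how per-age recordings are made; there
is no continuous movie across ages. The packaged schedules encode the two
interface phenotypes the analysis must distinguish:

* **PAO1-like (film-forming)**: persistent random walks (superdiffusive) at
  ages 60–1500 s, an abrupt switch to subdiffusive fBm (H = 0.30 then 0.25)
  at 3600 s, and elastic arrest (σ_eq 0.05→0.02 μm) from 10⁴ s through
  8×10⁴ s. The exponent trajectory between 1800 s and 3600 s is not
  constrained by any measurement; the schedule simply jumps at 3600 s and is
  a synthetic convention.
* **PA14-like (persistently active)**: persistent random walks easing into
  Brownian motion with D well above thermal (an active bath), through
  8×10⁴ s, never subdiffusive or elastic; d decays mildly at late ages.

Stanzas default to 50 trajectories (inside the experimentally typical
25–200 range) of 360 frames (6 s) at 60 fps with 0.01 μm localization
noise. 360 frames keeps every trajectory above the 110-frame MSD inclusion
threshold while holding a full scenario to well under a second of compute;
the per-age exponent estimates at these sizes are accurate to ~±0.05, far
from every decision boundary in the schedule.

## Rendering and tracking

The renderer draws each particle as a 2-D Gaussian spot (σ 1.5 px, optional
x-elongation to exercise the eccentricity filter) on a constant background
with additive Gaussian pixel noise, 16-bit grayscale, μm→px via the pixel
size (0.1 μm/px in fixtures). The packaged signal-to-noise condition is
peak amplitude / noise std = 10.

Tracking is the classical chain: (1) bandpass — Gaussian smoothing at the
noise scale minus a boxcar background at the feature scale, clipped at
zero; (2) candidate detection — local maxima above an intensity percentile,
separated by at least the feature diameter (brighter candidate wins);
(3) refinement — iterated intensity-weighted centroid within a circular
mask of radius ⌊diameter/2⌋, with mass (integrated intensity), size (radius
of gyration) and eccentricity √(4m²ₓᵧ + (mₓₓ−m_yy)²)/(mₓₓ+m_yy) from second
central moments; (4) threshold filtering on mass, size and eccentricity
with per-criterion rejection tallies; (5) linking — per frame pair, the
one-to-one assignment minimizing total squared displacement (Hungarian
algorithm) with links beyond the search radius forbidden and an unmatched
penalty of radius²; unmatched features start new trajectories, and a memory
parameter (default 0) lets particles skip frames. Test oracles check the
assignment against exhaustive enumeration on small instances.

Localization accuracy: at the packaged SNR the per-coordinate Cramér–Rao
bound for this spot model is σ_noise·√(2/π)/amplitude ≈ 0.080 px; the
iterated centroid measures ~0.086 px per coordinate — near-efficient, and
the reason no PSF-fitting refinement is included. Quoted localization
errors are per coordinate (the σₓ convention); the 2-D Euclidean RMS is √2
larger. The tracked noise floor appears in MSDs as an additive plateau of
4σ_loc², which matters only at the shortest lags; the end-to-end
diffusivity check fits MSD = 4Dt + c so the floor lands in the intercept.

Detection defaults (diameter 9 px, percentile 99, min mass 10⁴, size
1–4 px, max eccentricity 0.3, search radius 5 px) were fixed once against
the packaged renderer, where true spots carry mass ≥ ~2×10⁴ and noise
maxima stay below ~8×10³. They are conventions for the fixture movies, not
reproductions of any instrument's settings, and every one is configurable
and echoed into the run manifest.

## Analysis estimators

* **Drift correction** subtracts, per consecutive frame pair, the mean x
  and y displacement over trajectories spanning both frames, rebuilding
  positions by cumulative summation; pairs with no spanning trajectory
  contribute zero (logged). Common-mode motion is removed exactly (machine
  precision) when particles span the frames. Mean-subtraction also removes
  1/N of each particle's own motion: recovered diffusivities carry an
  (N−1)/N factor, verified against paired-seed runs. Drift correction is
  applied before MSD by default; a flag disables it for diagnostics.
* **MSD**: per-trajectory time averages over all overlapping origins, then
  an unweighted mean over trajectories at each lag (with the contributing
  count recorded). Only trajectories of ≥ 110 frames enter, so the 100-frame
  reference lag always has ≥ 10 origins per trajectory. Whether one should
  instead weight trajectories by length is a genuine convention choice;
  unweighted per-trajectory averaging was adopted.
* **Power-law fit**: unweighted least squares of log₁₀ MSD on log₁₀ lag
  inside the window; zero MSD values are excluded (logged). Exact on
  noiseless power laws for any n ∈ [0, 2].
* **Time course**: per age, drift-correct → ensemble MSD → fit → classify.
  The subdiffusive onset is the first age with n below the diffusive band;
  the elastic transition is the first age labelled elastic. Both are
  first-crossings of the label sequence with no smoothing — the programmed
  transitions are abrupt, and any smoothing convention would be invented.
  Ages with fewer than the minimum trajectory count are skipped with a
  warning and recorded.
* **References**: apparent diffusivity D_app = MSD(t)/4t at a chosen lag;
  thermal diffusivity k_BT/(6πηR); trapping energy γΔA, also in k_BT
  (≈10⁷ k_BT for a micron-scale object at ~50 mN/m — why interfacial
  attachment is effectively irreversible). Temperature defaults to 298 K.

## What the synthetic data does and does not show

The generators produce the *dynamical regimes* with known exponents, exact
closed-form MSDs, controllable drift and noise, and movie rendering with
known ground truth — enough to validate every estimator in the chain and
the regime logic end to end. They do not emulate: hydrodynamic or elastic
coupling between probes, probe–bacterium collisions, heterogeneous
per-particle dynamics within an age, intermittent or aging dynamics inside
one movie, uneven illumination, photobleaching, or out-of-plane motion.
Passing tests therefore demonstrate that the analysis recovers what it
claims from data obeying its model assumptions, not that any particular
real interface obeys them.

## Numerical notes

* fBm embedding eigenvalues are clipped at −10⁻¹⁰/0 before use; an
  indefinite embedding falls back to Cholesky with 10⁻¹² jitter.
* The OU samplers guard the conditional covariances against negative
  round-off before taking square roots; τ ≪ dt and τ ≫ duration limits are
  exercised in tests.
* Linking ties are resolved deterministically (stable ordering by particle
  id); assignment uses a large-finite sentinel for forbidden links so the
  solver never prefers them over a death+birth pair.
* Centroid refinement clamps windows at image borders and flags
  non-converged refinements rather than discarding them.
* All randomness flows from explicit integer seeds; reruns are
  byte-identical including written CSV artifacts.
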