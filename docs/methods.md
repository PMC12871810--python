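# Methods

This note documents the models behind `neurostab`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the design was genuinely open. Every
empirical statement here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs check.

## Spike metrics

Spikes are detected as contiguous supra-threshold excursions (strict `>`;
a sample exactly at threshold does not trigger), one spike per excursion at
the sample of its extremum, with a refractory dead time (default 2 ms)
suppressing later peaks. A polarity flag handles negative-going
extracellular (MEA) peaks. The threshold is a required input: the source
recordings used manually chosen thresholds, so inventing an automatic rule
would misrepresent the procedure. A clearly labelled robust-SD heuristic
(`SpikeDetector.robust_threshold`) is offered as an extension only.

Peak onset rapidness is the maximum of the central-difference dV/dt
(one-sided at trace edges) over a window ending at the peak (default 2 ms).
Central differences attenuate a logistic rise of true maximum slope `r` by
`tanh(u)/u`, `u = dt/(2s)` with `s` the logistic time scale; at 10 kHz this
is a 1–8 % attenuation over the rapidness ranges used here, plus a few
percent when the rise midpoint falls between samples. Tests assert recovery
within that band, not exact equality.

Local variation is
`Lv = (1/(n-1)) Σ 3 (Tᵢ − Tᵢ₊₁)² / (Tᵢ + Tᵢ₊₁)²`.
Its gamma-renewal expectation `3/(2κ+1)` is the calibration target
(κ ∈ {1, 2, 4} at 10⁴ ISIs, tolerance ±0.03); Lv is exactly invariant to
uniform time rescaling.

## Quartile states and Markov chains

A per-spike scalar series (onset rapidness or per-spike λ) is discretized
by its own quartiles (linear-interpolation order statistics, the "type 7"
convention; configurable). Boundary rule: values exactly at Q1 belong to
class 1, exactly at Q3 to class 2. All-equal input is a degenerate case:
everything goes to class 2 with a flag. Transition probabilities are
row-normalized pair counts; rows whose source state never occurs get a
uniform placeholder and a flag — summaries (persistence index = mean
diagonal over non-flagged rows) skip them rather than fabricate
observations. The persistence index is an added summary for testing and
group comparison, not an established quantity.

Note that quartile discretization caps measurable persistence below the
generating chain's diagonal whenever the marginal class occupancies differ
from 25/50/25: the quartile boundaries then cut through state clusters.
The recovery tests therefore validate the estimator on state sequences
directly (max-abs error < 0.03 at n = 10⁴), while end-to-end membrane-trace
tests assert the direction of group contrasts, not absolute persistence.

## Lyapunov exponents

The trace is embedded as (V, dV/dt) with central differences; the two
coordinates have incommensurate units, so each is standardized to unit
variance before distances (recorded choice; invariant to uniform scaling of
the input). For each reference `i`, the nearest Euclidean neighbor `i*`
outside a Theiler window (default 10 samples) at admissible separation
defines

`λ(i) = 1/((K_max−K_min+1)·dt) · Σ_{K=K_min}^{K_max} (1/K) ln(‖Y_{i+K}−Y_{i*+K}‖/‖Y_i−Y_{i*}‖)`

with defaults K_min = 1, K_max = 10. References whose expansion window
crosses the series end are dropped; references with no admissible neighbor
are flagged, not imputed. Admissibility requires the initial separation to
exceed a floor: by default a negligible `1e-9 ×` RMS scale, which exists to
reject numerically identical points — e.g. a sine sampled commensurately
revisits its orbit to within float rounding, and log-ratios of rounding
noise amplified by `1/dt` would otherwise dominate. Benchmarks: the
logistic map at r = 4 yields a global λ in [0.55, 0.80] against the
analytic ln 2 ≈ 0.693; a sine stays within ±0.05·(2πf) of zero; a
constructed pair of orbits separating exactly as `d₀·e^{gK·dt}` returns `g`
to machine precision; the vectorized implementation matches a double-loop
oracle to float tolerance.

**Per-spike mode.** Two variants are provided. The default
(`neighbors='global'`) embeds the whole trace once; each spike's reference
points are its depolarization-phase samples (default 2 ms before to 0.5 ms
after the peak) and neighbors are searched across all peri-spike segments
of the trace. A reference on one spike then pairs with the matching phase
of *another* spike, so λ measures cross-spike trajectory reproducibility:
near zero or negative when every action potential follows the same orbit,
positive when orbits diverge. On noisy recordings the minimum admissible
separation is raised to 2× the trajectory's noise scale (estimated from
first differences, which noise dominates at high sampling rates); pairs
closer than the noise cloud would measure noise decorrelation — inflated,
direction-less values — rather than dynamics. The factor 2 is the smallest
multiple that clears the noise cloud; it is a fixed default, not a tuned
quantity. The alternative (`neighbors='windowed'`) analyzes each spike
window as an isolated trajectory; it measures within-waveform expansion
(useful for contrasting fast- versus slow-onset spike shapes — see the
bimodality test) but is insensitive to across-spike variability and more
noise-prone, which is why it is not the default.

## OU modeling and stationarity profiling

The field potential is modeled as an OU process parameterized by the
ACF decay constant τ and the stationary amplitude σ (an SD, not a
diffusion coefficient — the measured "noise amplitude" is a signal SD).
Estimation: τ by least-squares fit of `exp(−lag/τ)` to the empirical ACF of
the mean-centered signal over lags up to the first crossing of 1/e (capped
at `max_lag`, default 1 s); σ as the SD of the linearly detrended signal;
μ as the raw mean. The 1/e fit range is deliberate: beyond one decay time
the sample ACF's errors are large and serially correlated, and including
them raises the variance of τ̂ without reducing bias (measured: median
relative error 1.7/5.3/6.3 % for τ = 10/50/200 ms at 60 s, 1 kHz, versus
12 % at τ = 200 ms with a 0.05 floor). σ recovery is within 5 % (median)
on the same grid. The fit is exactly invariant to constant offsets.

Simulation uses the exact discrete transition
`X_{t+dt} = μ + (X_t − μ)e^{−dt/τ} + σ√(1−e^{−2dt/τ}) ξ`
(closed-form moments at any step, hence testable), with an Euler–Maruyama
scheme available to mirror fixed-step simulators; at dt ≪ τ the two agree
in SD within 2 % (Euler's stationary variance is inflated by
`1/(1 − dt/2τ)`).

The CWT uses a complex Morlet (`cmor1.5-1.0`), default log-spaced grid
0.5–100 Hz × 32 bands. Coefficients are normalized per band by the discrete
filter's impulse-response energy: the backend's raw filters drift from unit
L2 energy at large scales (measured ~8× power inflation at 0.5 Hz for white
noise), which would tilt any cross-band comparison; after normalization
white-noise expected band power is flat (max ≤ 3× median at n = 10⁵).
`normalization='raw'` exposes the backend output.

Per-band ADF tests (constant, no trend) run on the real part of the
coefficients by default (an envelope mode exists). The default lag order is
fixed at 5 rather than information-criterion selected: band series are
oversampled by fs/f per cycle, and AIC grows the augmentation until the
lagged differences reconstruct the band-pass filter, rejecting the unit
root for any input. With the fixed lag the lowest band of a random walk
retains its stochastic trend (high p) while a short-memory OU's lowest band
is called stationary — the discrimination the profile is for. Direct-series
ADF (`adf_test`) keeps AIC lag selection, appropriate for series sampled
near their information rate; detection rates there are ≥ 90 % in both
directions (100 replicates each, n = 2000). P-values are never aggregated
across bands; the profile itself is the result.

## Sodium-current analysis

Inward currents are negative; the per-voltage peak is the most negative
excursion of the repeat-averaged current inside the test-pulse window
(polarity configurable for exported-as-positive data). Peaks normalized by
the maximum magnitude are fitted with `1/(1+exp((V−V½)/k))`, k > 0 (the
availability convention for steady-state inactivation). The fit is exactly
equivariant under voltage shifts. Noise is the SD across repeats (divisor
n−1) of residuals from the repeat-averaged current, computed within each
voltage's own repeat block — hence exactly invariant to any waveform common
to all repeats. "Maximum noise variability" is the max of the SD trace over
time and voltage, within the test-pulse window by default (configurable to
the full sweep). No gating/thermal variance decomposition is attempted; the
residual SD is the deliverable. A diagnostic (`peak_alignment_check`)
reports where the SD trace peaks relative to the current peak, which
separates amplitude-scaled from purely additive noise.

## Pattern classification

Adjacent-ISI pairs (Tᵢ, Tᵢ₊₁) are pooled across trains (log scale optional;
ISI distributions are right-skewed) and clustered with a full-covariance
GMM (seeded k-means++ initialization, covariance floor on degeneracy,
flagged). The component count is a required user input — it was chosen by
visual inspection in the source analyses, which is not reproducible — and
an AIC/BIC table over k documents the choice.

The probabilistic distance between groups is defined here as
`2·(balanced out-of-bag accuracy − 0.5)` of a random forest (default 500
trees, √d features per split, bootstrap sampling) classifying
non-overlapping windows of 20 consecutive ISIs (or instantaneous
frequencies), clipped to [0, 1]. This definition is symmetric, bounded,
and ~0 for exchangeable groups; it is recorded in the result metadata
because no single established definition exists. The matrix feeds
average-linkage hierarchical clustering; the dendrogram is exported as
newick. Windows never cross train boundaries; each group needs ≥ 50
windows.

## Synthetic data: what it emulates, and what it does not

Generators mirror the study's four input classes with known parameters:

* **Gamma-renewal trains** calibrate Lv exactly.
* **Membrane traces**: stereotyped biphasic spike templates (logistic rise
  whose maximum slope is the controlled onset rapidness — the one waveform
  feature the downstream analyses read — and exponential repolarization,
  1.5 ms default), placed at gamma ISIs on top of a refractory offset equal
  to the template width so templates never overlap, with per-spike
  rapidness = Markov-state class mean + Gaussian jitter, plus white
  measurement noise. Two presets define the study conditions for the
  end-to-end contrast: *control* (diagonal-0.95 chain, class means
  150/200/250 V/s, jitter 5 V/s, gamma shape 10) and *unstable*
  (uniform chain, class means 80/200/420 V/s, jitter 40 V/s, gamma
  shape 1). The magnitudes of these shifts are qualitative design choices
  — the source figures print no effect sizes — so tests assert directions
  and significance, never magnitudes.
* **OU series / random walks** with exact discretization (closed-form
  moments) and cumulative Gaussian steps respectively.
* **Inactivation sweep sets**: Boltzmann-scaled double-exponential test
  currents (−100…−20 mV prepulses in 10 mV steps, 0 mV test pulse),
  repeats = mean waveform + iid Gaussian noise, with optional per-voltage
  noise scaling and an amplitude-proportional noise mode.

Not emulated: conductance-based spike generation, channel-level stochastic
gating (residual-SD recovery needs only additive trace noise), synaptic
input structure, electrode drift and line noise, bursting, and
multi-unit/MEA spike-sorting ambiguity. Passing tests therefore demonstrate
estimator correctness and sensitivity under controlled conditions, not
robustness to every artifact of real recordings.

## Problem sizes and reproducibility

Default test/acceptance scales: 10⁴ ISIs for Lv and Markov recovery;
5000 points for the map/sine Lyapunov benchmarks; 60 s at 1 kHz × 20 seeds
(10 in the acceptance script) for OU recovery; 100 replicates × 2000
samples for ADF rates; 9 voltages × 20 repeats for sweep analyses;
20 traces per group × 20 s at 10 kHz for the end-to-end contrast. All
randomness flows through per-call `numpy` generators seeded from a master
seed; identical spec + seed reproduces byte-identical outputs, and the CLI
logs one structured line per stage with the config hash and seed.

## Known limitations

* The divergence-based λ depends on the separation floor on noisy data;
  values are comparable across recordings analyzed with the same settings,
  but are not absolute invariants of the underlying system.
* Quartile-based state sequences understate true persistence (see above).
* The OU fit assumes a single dominant relaxation time; multi-timescale
  ACFs will be summarized by their initial decay.
* Band-wise ADF conclusions depend on the lag-order convention for
  oversampled series; the default is chosen for cross-band comparability,
  not as an optimal test of any single band.
* The probabilistic distance saturates at 1 and is not a metric in the
  triangle-inequality sense; the dendrogram is descriptive.
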