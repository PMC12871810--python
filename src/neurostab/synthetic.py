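"""Synthetic data with known ground truth for every pipeline input class.

The study's raw recordings (intracellular fly clock-neuron traces, LFP near
the pars intercerebralis, voltage-clamp sodium-current sweeps, MEA spike
trains from iPSC-derived cultures) are not publicly deposited, so every
analysis here is exercised against generators with controllable, known
parameters:

* gamma-renewal spike trains (known expected Lv = 3/(2*kappa+1));
* spiking membrane traces whose per-spike peak onset rapidness follows a
  known 3-state Markov chain;
* Ornstein-Uhlenbeck series with known (tau, sigma) and Gaussian random
  walks (unit-root positive controls);
* Boltzmann steady-state-inactivation current sweeps with injected
  trace-to-trace noise.

Every generator is reproducible (identical spec + seed gives identical
output) and emits its ground truth alongside the data, enabling
parameter-recovery tests downstream. All randomness flows through one
seeded ``numpy`` generator per call; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .io import TraceRecord
from .markov import StateSequence, sample_states
from .na_noise import SweepSet, boltzmann
from .spikes import SpikeTrain


# ---------------------------------------------------------------------------
# Gamma-renewal spike trains
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrainSpec:
    """Gamma-renewal train: rate (spikes/s), ISI shape kappa, spike count."""

    rate: float = 5.0
    shape: float = 1.0  # kappa; 1 = Poisson, large = regular
    n_spikes: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0 or self.shape <= 0:
            raise ValueError("rate and shape must be positive")
        if self.n_spikes < 2:
            raise ValueError("need at least 2 spikes")


def gen_gamma_train(spec: SpikeTrainSpec) -> SpikeTrain:
    """ISIs are iid gamma(kappa, scale=1/(kappa*rate)); mean ISI = 1/rate."""
    rng = np.random.default_rng(spec.seed)
    isis = rng.gamma(spec.shape, 1.0 / (spec.shape * spec.rate), size=spec.n_spikes)
    return SpikeTrain(times=np.cumsum(isis))


# ---------------------------------------------------------------------------
# Spiking membrane traces with Markov onset-rapidness states
# ---------------------------------------------------------------------------


@dataclass
class MembraneTraceSpec:
    """Spiking membrane trace with Markov-modulated onset rapidness.

    Each spike's rising phase is a logistic segment whose maximum slope is
    the spike's target rapidness (the waveform shape beyond that is
    stereotyped: logistic rise to the peak, exponential repolarization).
    Per-spike target rapidness = class mean of the current Markov state plus
    Gaussian jitter. ISIs are gamma-distributed on top of a refractory
    offset equal to the template width, so templates never overlap.
    """

    dt: float = 1e-4  # s (10 kHz)
    duration: float = 20.0  # s
    amplitude: float = 100.0  # mV, spike height above baseline
    baseline: float = -70.0  # mV
    repol_tau: float = 1.5e-3  # s, exponential repolarization constant
    class_rapidness: tuple = (150.0, 200.0, 250.0)  # V/s per class
    transition: tuple = (
        (0.95, 0.025, 0.025),
        (0.025, 0.95, 0.025),
        (0.025, 0.025, 0.95),
    )
    isi_rate: float = 5.0  # spikes/s of the gamma part
    isi_shape: float = 10.0
    rapidness_jitter_sd: float = 5.0  # V/s
    noise_sd: float = 0.3  # mV
    seed: int = 0

    def __post_init__(self):
        P = np.asarray(self.transition, dtype=float)
        if P.shape != (3, 3) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 3x3 row-stochastic")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration/dt must be an integer sample count")
        if len(self.class_rapidness) != 3 or min(self.class_rapidness) <= 0:
            raise ValueError("three positive class rapidness means required")


def _logistic_scale(amplitude_mv: float, rapidness_v_per_s: float) -> float:
    # max slope of A*expit(t/s) is A/(4s) mV/s; convert target V/s -> mV/s
    return amplitude_mv / (4.0 * rapidness_v_per_s * 1e3)


def expected_discrete_rapidness(rapidness: float, amplitude: float, dt: float) -> float:
    """Central-difference value of the logistic rise at its midpoint.

    The continuous max slope r is attenuated to r * tanh(u)/u with
    u = dt/(2s); this is the finite-difference error bound for the template
    at sampling interval dt (grid misalignment can lower it slightly more).
    """
    s = _logistic_scale(amplitude, rapidness)
    u = dt / (2.0 * s)
    return rapidness * np.tanh(u) / u


def gen_membrane_trace(
    spec: MembraneTraceSpec,
) -> tuple[TraceRecord, SpikeTrain, StateSequence]:
    """Emit (voltage trace, ground-truth spike train, ground-truth states).

    The returned SpikeTrain carries the exact emitted peak indices and the
    continuous-time target rapidness per spike; the StateSequence is the
    Markov state path that generated them.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.dt))
    P = np.asarray(spec.transition, dtype=float)

    # template extent: slowest class has the widest rise
    s_max = _logistic_scale(spec.amplitude, min(spec.class_rapidness))
    rise_span = 8.0 * s_max
    decay_span = 6.0 * spec.repol_tau
    template_width = rise_span + decay_span

    # ISIs: refractory offset (template width) + gamma
    mean_gamma = 1.0 / spec.isi_rate
    n_expect = int(spec.duration / (template_width + mean_gamma) * 1.3) + 20
    isis = template_width + rng.gamma(
        spec.isi_shape, mean_gamma / spec.isi_shape, size=n_expect
    )
    if np.min(isis) < template_width:
        raise ValueError("spike template wider than the minimum ISI")
    times = rise_span + 1e-3 + np.cumsum(isis)
    times = times[times < spec.duration - decay_span - 1e-3]
    n_spikes = times.size
    if n_spikes < 2:
        raise ValueError("duration too short for at least 2 spikes")

    states = sample_states(P, n_spikes, seed=rng)
    class_means = np.asarray(spec.class_rapidness, dtype=float)
    rapidness = class_means[states - 1] + rng.normal(0, spec.rapidness_jitter_sd, n_spikes)
    rapidness = np.maximum(rapidness, 10.0)

    v = np.full(n, spec.baseline)
    peak_idx = np.round(times / spec.dt).astype(int)
    a_pk = spec.amplitude * expit(4.0)
    for p, r in zip(peak_idx, rapidness):
        s = _logistic_scale(spec.amplitude, r)
        t_peak = p * spec.dt
        t_mid = t_peak - 4.0 * s
        i0 = max(int(np.ceil((t_peak - 8.0 * s) / spec.dt)), 0)
        t_rise = np.arange(i0, p + 1) * spec.dt
        v[i0 : p + 1] += spec.amplitude * expit((t_rise - t_mid) / s)
        i1 = min(p + 1 + int(np.ceil(decay_span / spec.dt)), n)
        t_dec = np.arange(p + 1, i1) * spec.dt
        v[p + 1 : i1] += a_pk * np.exp(-(t_dec - t_peak) / spec.repol_tau)
    if spec.noise_sd > 0:
        v = v + rng.normal(0, spec.noise_sd, n)

    trace = TraceRecord(v, spec.dt, channel_id="synthetic_membrane", units="mV")
    truth = SpikeTrain(
        times=peak_idx * spec.dt,
        peak_indices=peak_idx,
        onset_rapidness=rapidness,
        dt=spec.dt,
    )
    seq = StateSequence(states=states, source="synthetic")
    return trace, truth, seq


def control_membrane_spec(seed: int = 0, **overrides) -> MembraneTraceSpec:
    """Stable phenotype: persistent onset-rapidness states (diagonal 0.95),
    narrow class spread, small jitter, regular firing (gamma shape 10)."""
    kw = dict(
        class_rapidness=(150.0, 200.0, 250.0),
        transition=(
            (0.95, 0.025, 0.025),
            (0.025, 0.95, 0.025),
            (0.025, 0.025, 0.95),
        ),
        isi_shape=10.0,
        rapidness_jitter_sd=5.0,
        seed=seed,
    )
    kw.update(overrides)
    return MembraneTraceSpec(**kw)


def unstable_membrane_spec(seed: int = 0, **overrides) -> MembraneTraceSpec:
    """Destabilized phenotype: memoryless state switching (uniform rows),
    wide class spread, large jitter, irregular firing (gamma shape 1).
    Effect sizes are qualitative design choices, not calibrated magnitudes."""
    u = (1 / 3, 1 / 3, 1 / 3)
    kw = dict(
        class_rapidness=(80.0, 200.0, 420.0),
        transition=(u, u, u),
        isi_shape=1.0,
        rapidness_jitter_sd=40.0,
        seed=seed,
    )
    kw.update(overrides)
    return MembraneTraceSpec(**kw)


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck series and random walks
# ---------------------------------------------------------------------------


@dataclass
class OUSpec:
    """OU series: tau (s), sigma (stationary SD), mu, sampling, scheme.

    ``scheme='exact'`` uses the exact discrete-time transition
    X_{t+dt} = mu + (X_t - mu) e^{-dt/tau} + sigma sqrt(1 - e^{-2dt/tau}) xi,
    whose sample moments match the closed-form OU moments at any dt;
    ``'euler'`` is the Euler-Maruyama scheme of a fixed-step simulator.
    ``x0=None`` starts from the stationary law.
    """

    tau: float = 0.05
    sigma: float = 1.0
    mu: float = 0.0
    dt: float = 1e-3
    n: int = 10000
    scheme: str = "exact"
    x0: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 2:
            raise ValueError("need at least 2 samples")
        if self.scheme not in ("exact", "euler"):
            raise ValueError("scheme must be 'exact' or 'euler'")


def gen_ou(spec: OUSpec) -> TraceRecord:
    rng = np.random.default_rng(spec.seed)
    if spec.scheme == "exact":
        a = np.exp(-spec.dt / spec.tau)
        noise_sd = spec.sigma * np.sqrt(1.0 - a * a)
    else:
        if spec.dt >= spec.tau:
            raise ValueError("euler scheme needs dt < tau")
        a = 1.0 - spec.dt / spec.tau
        noise_sd = spec.sigma * np.sqrt(2.0 * spec.dt / spec.tau)
    x0 = (
        spec.mu + spec.sigma * rng.standard_normal()
        if spec.x0 is None
        else float(spec.x0)
    )
    eps = rng.standard_normal(spec.n - 1) * noise_sd
    # x_t - mu follows an AR(1) recursion; lfilter runs it in C
    drive = np.r_[x0 - spec.mu, eps]
    x = spec.mu + lfilter([1.0], [1.0, -a], drive)
    return TraceRecord(x, spec.dt, channel_id="synthetic_ou", units="mV")


def gen_random_walk(n: int, step_sd: float = 1.0, seed: int = 0,
                    dt: float = 1e-3) -> TraceRecord:
    """Cumulative sum of iid Gaussian steps — a unit-root positive control."""
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(0, step_sd, n))
    return TraceRecord(x, dt, channel_id="synthetic_rw", units="mV")


# ---------------------------------------------------------------------------
# Steady-state inactivation sweep sets
# ---------------------------------------------------------------------------


@dataclass
class SweepSetSpec:
    """Boltzmann-inactivation sweeps with injected trace-to-trace noise.

    The per-voltage mean waveform is an inward (negative) current
    -peak_current * availability(V) * h(t), with h a normalized
    activation/decay double exponential. Each repeat adds iid Gaussian noise
    of SD ``noise_sd`` (optionally scaled per voltage via ``noise_scale`` to
    emulate a disease phenotype, or made proportional to |mean current| with
    ``noise_model='amplitude_scaled'``).
    """

    voltages: tuple = (-100, -90, -80, -70, -60, -50, -40, -30, -20)  # mV
    v_half: float = -50.0  # mV
    slope_k: float = 5.0  # mV
    peak_current: float = 500.0  # pA
    tau_act: float = 5e-4  # s
    tau_decay: float = 3e-3  # s
    n_repeats: int = 20
    noise_sd: float = 10.0  # pA
    noise_scale: Optional[tuple] = None  # per-voltage multiplier
    noise_model: str = "additive"  # additive | amplitude_scaled
    dt: float = 1e-5  # s
    baseline_s: float = 2e-3
    test_s: float = 2.5e-2
    seed: int = 0

    def __post_init__(self):
        v = np.asarray(self.voltages, dtype=float)
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.n_repeats < 2:
            raise ValueError("need at least 2 repeats")
        if self.noise_scale is not None and len(self.noise_scale) != v.size:
            raise ValueError("noise_scale must have one entry per voltage")
        if self.noise_model not in ("additive", "amplitude_scaled"):
            raise ValueError("unknown noise model")


def gen_inactivation_sweeps(spec: SweepSetSpec) -> SweepSet:
    rng = np.random.default_rng(spec.seed)
    volts = np.asarray(spec.voltages, dtype=float)
    n_base = int(round(spec.baseline_s / spec.dt))
    n_test = int(round(spec.test_s / spec.dt))
    t = np.arange(n_test) * spec.dt
    h = (1.0 - np.exp(-t / spec.tau_act)) * np.exp(-t / spec.tau_decay)
    h /= h.max()

    avail = boltzmann(volts, spec.v_half, spec.slope_k)
    mean_waves = np.zeros((volts.size, n_base + n_test))
    mean_waves[:, n_base:] = -spec.peak_current * avail[:, None] * h[None, :]

    scale = np.ones(volts.size) if spec.noise_scale is None else np.asarray(
        spec.noise_scale, dtype=float
    )
    cube = np.empty((volts.size, spec.n_repeats, n_base + n_test))
    for i in range(volts.size):
        if spec.noise_model == "additive":
            sd_t = spec.noise_sd * scale[i]
            noise = rng.normal(0, 1, (spec.n_repeats, n_base + n_test)) * sd_t
        else:
            amp = np.abs(mean_waves[i])
            ref = amp.max() if amp.max() > 0 else 1.0
            sd_t = spec.noise_sd * scale[i] * amp / ref
            noise = rng.normal(0, 1, (spec.n_repeats, n_base + n_test)) * sd_t[None, :]
        cube[i] = mean_waves[i][None, :] + noise

    return SweepSet(
        currents=cube,
        voltages=volts,
        dt=spec.dt,
        test_window=(n_base, n_base + n_test),
    )
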