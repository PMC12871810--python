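"""Spike detection and spike-train statistics.

Covers threshold-crossing spike detection on intracellular or extracellular
voltage traces, per-spike peak onset rapidness (the maximum dV/dt of the
depolarizing phase, in V/s), and train-level statistics: interspike
intervals, instantaneous frequency, mean rate, ISI histogram, and the
local-variation (Lv) irregularity statistic.

Lv compares each pair of adjacent interspike intervals:

    Lv = (1/(n-1)) * sum_i 3 * (T_i - T_{i+1})^2 / (T_i + T_{i+1})^2

It is 0 for a perfectly regular train, 1 in expectation for Poisson firing,
and 3/(2*kappa+1) in expectation for a gamma-renewal train of shape kappa.
Unlike the coefficient of variation it is insensitive to slow rate drift,
which makes it a local (adjacent-interval) irregularity measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import ArrayEqMixin
from .io import TraceRecord, register_result


@register_result
@dataclass(eq=False)
class SpikeTrain(ArrayEqMixin):
    """Ordered spike times with optional per-spike features.

    ``onset_rapidness`` (V/s) and ``lyapunov`` (1/s) are aligned 1:1 with
    ``times``; NaN marks spikes flagged out of a feature computation (for
    example a spike too close to the trace start for its analysis window).
    """

    times: np.ndarray  # s, strictly increasing
    peak_indices: Optional[np.ndarray] = None
    onset_rapidness: Optional[np.ndarray] = None  # V/s
    lyapunov: Optional[np.ndarray] = None  # 1/s
    dt: Optional[float] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        for name in ("peak_indices", "onset_rapidness", "lyapunov"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=int if name == "peak_indices" else float)
                if arr.shape != self.times.shape:
                    raise ValueError(f"{name} must align 1:1 with spike times")
                if name != "peak_indices" and np.any(np.isinf(arr)):
                    raise ValueError(f"{name} contains non-finite (inf) values")
                setattr(self, name, arr)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        if self.peak_indices is not None:
            df["peak_index"] = self.peak_indices
        if self.onset_rapidness is not None:
            df["rapidness_V_per_s"] = self.onset_rapidness
        if self.lyapunov is not None:
            df["lyapunov_per_s"] = self.lyapunov
        return df

    def to_dict(self) -> dict:
        return {
            "times": self.times,
            "peak_indices": self.peak_indices,
            "onset_rapidness": self.onset_rapidness,
            "lyapunov": self.lyapunov,
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpikeTrain":
        return cls(
            times=np.asarray(d["times"], dtype=float),
            peak_indices=None if d.get("peak_indices") is None else np.asarray(d["peak_indices"]),
            onset_rapidness=None
            if d.get("onset_rapidness") is None
            else np.asarray(d["onset_rapidness"], dtype=float),
            lyapunov=None if d.get("lyapunov") is None else np.asarray(d["lyapunov"], dtype=float),
            dt=d.get("dt"),
        )


@register_result
@dataclass(eq=False)
class SpikeStats(ArrayEqMixin):
    """Train-level statistics derived from a SpikeTrain."""

    isis: np.ndarray  # s
    inst_freq: np.ndarray  # Hz, 1/ISI
    mean_rate: float  # Hz
    lv: float  # dimensionless; NaN when < 3 spikes
    isi_hist_probs: np.ndarray = field(default_factory=lambda: np.empty(0))
    isi_hist_edges: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "isis": self.isis,
            "inst_freq": self.inst_freq,
            "mean_rate": self.mean_rate,
            "lv": self.lv,
            "isi_hist_probs": self.isi_hist_probs,
            "isi_hist_edges": self.isi_hist_edges,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpikeStats":
        return cls(
            isis=np.asarray(d["isis"], dtype=float),
            inst_freq=np.asarray(d["inst_freq"], dtype=float),
            mean_rate=float(d["mean_rate"]),
            lv=float(d["lv"]) if d["lv"] is not None else float("nan"),
            isi_hist_probs=np.asarray(d["isi_hist_probs"], dtype=float),
            isi_hist_edges=np.asarray(d["isi_hist_edges"], dtype=float),
        )


def detect_spikes(
    trace: TraceRecord,
    threshold: float,
    refractory: float = 2e-3,
    polarity: int = 1,
) -> SpikeTrain:
    """Threshold-crossing spike detection.

    One spike is registered per contiguous supra-threshold excursion, at the
    sample of the excursion's extremum. Crossing is strict (``sample >
    threshold`` for positive polarity): a trace touching the threshold
    exactly does not trigger. A peak arriving within ``refractory`` seconds
    of the previously registered peak is suppressed. ``polarity=-1`` detects
    negative-going peaks (extracellular MEA signatures), in which case
    ``threshold`` is the (negative) level the signal must drop below.
    """
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("trace contains non-finite samples")
    if refractory < 0:
        raise ValueError("refractory must be >= 0")
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")

    x = polarity * trace.samples
    thr = polarity * threshold
    above = x > thr
    if not above.any():
        return SpikeTrain(times=np.empty(0), peak_indices=np.empty(0, dtype=int), dt=trace.dt)

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]

    peaks = []
    last_t = -np.inf
    for s, e in zip(starts, ends):
        p = s + int(np.argmax(x[s:e]))
        t = p * trace.dt
        if t - last_t > refractory:
            peaks.append(p)
            last_t = t
    peaks = np.asarray(peaks, dtype=int)
    return SpikeTrain(times=peaks * trace.dt, peak_indices=peaks, dt=trace.dt)


def onset_rapidness(
    trace: TraceRecord,
    spikes: SpikeTrain,
    window: float = 2e-3,
) -> np.ndarray:
    """Peak depolarization rapidness (max dV/dt, V/s) per spike.

    dV/dt is computed by central finite differences (one-sided at the trace
    edges) and the value is the maximum over the ``window`` seconds ending
    at each spike peak. Spikes closer than ``window`` to the trace start are
    flagged with NaN and excluded from the rapidness series. Assumes the
    trace is in mV.
    """
    if spikes.peak_indices is None:
        raise ValueError("spike train has no peak indices; detect on the same trace first")
    n_w = int(round(window / trace.dt))
    if n_w < 3:
        raise ValueError("rapidness window must cover at least 3 samples")
    grad = np.gradient(trace.samples, trace.dt)  # mV/s
    out = np.full(spikes.n_spikes, np.nan)
    for k, p in enumerate(spikes.peak_indices):
        if p - n_w < 0:
            continue  # flagged: window would run off the trace start
        out[k] = np.max(grad[p - n_w : p + 1]) / 1e3  # mV/s -> V/s
    return out


def local_variation(isis) -> float:
    """Local variation Lv of an ISI series (see module docstring)."""
    t = np.asarray(isis, dtype=float)
    if t.size < 2:
        raise ValueError("Lv needs at least 2 interspike intervals")
    if np.any(t <= 0):
        raise ValueError("all interspike intervals must be positive")
    a, b = t[:-1], t[1:]
    return float(np.mean(3.0 * (a - b) ** 2 / (a + b) ** 2))


def spike_stats(spikes: SpikeTrain, duration: float, n_bins: int = 50) -> SpikeStats:
    """Mean rate, ISIs, instantaneous frequency, ISI histogram, and Lv."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    isis = spikes.isis
    mean_rate = spikes.n_spikes / duration
    if isis.size == 0:
        return SpikeStats(
            isis=isis, inst_freq=np.empty(0), mean_rate=mean_rate, lv=float("nan")
        )
    inst_freq = 1.0 / isis
    # a (numerically) constant ISI series cannot support n_bins finite bins
    if np.ptp(isis) <= 1e-12 * np.max(isis):
        center = float(np.mean(isis))
        counts, edges = np.histogram(isis, bins=1, range=(0.5 * center, 1.5 * center))
    else:
        counts, edges = np.histogram(isis, bins=n_bins)
    probs = counts / counts.sum()
    lv = local_variation(isis) if isis.size >= 2 else float("nan")
    return SpikeStats(
        isis=isis,
        inst_freq=inst_freq,
        mean_rate=mean_rate,
        lv=lv,
        isi_hist_probs=probs,
        isi_hist_edges=edges,
    )


class SpikeDetector(BaseEstimator):
    """Estimator wrapper around spike detection + onset rapidness.

    Parameters
    ----------
    threshold : float
        Detection level in trace units (mV). Required: thresholds were set
        manually in the source recordings, so no automatic rule is implied.
    refractory : float
        Dead time after a registered peak, seconds.
    polarity : int
        +1 for positive-going (intracellular) peaks, -1 for negative-going
        (extracellular) peaks.
    rapidness_window : float
        Window (s) before each peak over which max dV/dt is taken.
    """

    def __init__(self, threshold: float = -20.0, refractory: float = 2e-3,
                 polarity: int = 1, rapidness_window: float = 2e-3):
        self.threshold = threshold
        self.refractory = refractory
        self.polarity = polarity
        self.rapidness_window = rapidness_window

    def fit(self, trace: TraceRecord, y=None):
        train = detect_spikes(trace, self.threshold, self.refractory, self.polarity)
        if train.n_spikes:
            rap = onset_rapidness(trace, train, self.rapidness_window)
        else:
            rap = np.empty(0)
        self.spike_train_ = SpikeTrain(
            times=train.times,
            peak_indices=train.peak_indices,
            onset_rapidness=rap,
            dt=trace.dt,
        )
        self.n_spikes_ = train.n_spikes
        return self

    def transform(self, trace: TraceRecord) -> SpikeTrain:
        self.fit(trace)
        return self.spike_train_

    def robust_threshold(self, trace: TraceRecord, k: float = 5.0) -> float:
        """Optional heuristic (extension, not part of the recorded protocol):
        median + k * MAD-based robust SD, sign-flipped for negative polarity."""
        med = np.median(trace.samples)
        mad = np.median(np.abs(trace.samples - med)) * 1.4826
        return float(med + self.polarity * k * mad)
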