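"""Steady-state inactivation and non-stationary noise analysis of
voltage-clamp sodium-current sweeps.

A steady-state inactivation protocol conditions the channel population with
prepulses (here -100 to -20 mV in 10 mV steps) and reads out availability
with a fixed 0 mV test pulse. The normalized test-pulse peak current versus
prepulse voltage follows a Boltzmann curve

    I/Imax = 1 / (1 + exp((V - V_half) / k)),   k > 0

whose half-inactivation voltage V_half summarizes channel availability.

Non-stationary noise is quantified per prepulse voltage as the standard
deviation, across repeated sweeps, of the residuals after subtracting the
repeat-averaged current at each time point; the maximum of that SD trace
over time and voltage is the "maximum noise variability" summary. No
variance-vs-mean decomposition into gating versus instrumentation sources
is attempted — only the residual SD is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from ._utils import ArrayEqMixin
from .io import register_result


@dataclass(eq=False)
class SweepSet(ArrayEqMixin):
    """Current sweeps indexed by (prepulse voltage, repeat, time).

    ``test_window`` is the (start, stop) sample range of the test pulse.
    Inward sodium currents are negative by convention.
    """

    currents: np.ndarray  # (n_voltages, n_repeats, n_samples), pA
    voltages: np.ndarray  # mV, strictly increasing
    dt: float  # s
    test_window: tuple  # (start, stop) sample indices

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.currents.ndim != 3:
            raise ValueError("currents must be (voltage, repeat, time)")
        if self.currents.shape[0] != self.voltages.size:
            raise ValueError("one sweep block per prepulse voltage required")
        if self.currents.shape[1] < 2:
            raise ValueError("need at least 2 repeats per voltage")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        lo, hi = self.test_window
        if not (0 <= lo < hi <= self.currents.shape[2]):
            raise ValueError("test window must lie inside the sweeps")
        self.test_window = (int(lo), int(hi))

    @property
    def n_repeats(self) -> int:
        return self.currents.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: voltage_mV, repeat, t_s, i_pA."""
        nv, nr, nt = self.currents.shape
        t = np.arange(nt) * self.dt
        return pd.DataFrame(
            {
                "voltage_mV": np.repeat(self.voltages, nr * nt),
                "repeat": np.tile(np.repeat(np.arange(nr), nt), nv),
                "t_s": np.tile(t, nv * nr),
                "i_pA": self.currents.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, test_window: tuple) -> "SweepSet":
        volts = np.sort(df["voltage_mV"].unique())
        reps = np.sort(df["repeat"].unique())
        ts = np.sort(df["t_s"].unique())
        dt = float(np.median(np.diff(ts)))
        cube = np.empty((volts.size, reps.size, ts.size))
        pivot = df.sort_values(["voltage_mV", "repeat", "t_s"])
        cube[:] = pivot["i_pA"].to_numpy().reshape(volts.size, reps.size, ts.size)
        return cls(currents=cube, voltages=volts, dt=dt, test_window=test_window)


@register_result
@dataclass(eq=False)
class InactivationCurve(ArrayEqMixin):
    """Normalized availability curve with its Boltzmann fit."""

    voltages: np.ndarray  # mV
    peak_current: np.ndarray  # pA (signed extremum per voltage)
    normalized: np.ndarray  # I/Imax in [0, 1] up to noise
    v_half: float  # mV
    slope_k: float  # mV
    fit_rmse: float
    flagged: bool = False  # fit failed or V_half outside the voltage span

    def to_dict(self) -> dict:
        return {
            "voltages": self.voltages,
            "peak_current": self.peak_current,
            "normalized": self.normalized,
            "v_half": self.v_half,
            "slope_k": self.slope_k,
            "fit_rmse": self.fit_rmse,
            "flagged": self.flagged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InactivationCurve":
        return cls(
            voltages=np.asarray(d["voltages"], dtype=float),
            peak_current=np.asarray(d["peak_current"], dtype=float),
            normalized=np.asarray(d["normalized"], dtype=float),
            v_half=float(d["v_half"]),
            slope_k=float(d["slope_k"]),
            fit_rmse=float(d["fit_rmse"]),
            flagged=bool(d["flagged"]),
        )


@register_result
@dataclass(eq=False)
class NoiseProfile(ArrayEqMixin):
    """Residual-SD traces per prepulse voltage and their maximum."""

    voltages: np.ndarray  # mV
    times: np.ndarray  # s, within the analysis window
    sd_traces: np.ndarray  # (n_voltages, n_times), pA
    time_avg_sd: np.ndarray  # pA per voltage
    max_noise_variability: float  # pA
    voltage_at_max: float  # mV
    time_at_max: float  # s

    def to_dict(self) -> dict:
        return {
            "voltages": self.voltages,
            "times": self.times,
            "sd_traces": self.sd_traces,
            "time_avg_sd": self.time_avg_sd,
            "max_noise_variability": self.max_noise_variability,
            "voltage_at_max": self.voltage_at_max,
            "time_at_max": self.time_at_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseProfile":
        return cls(
            voltages=np.asarray(d["voltages"], dtype=float),
            times=np.asarray(d["times"], dtype=float),
            sd_traces=np.asarray(d["sd_traces"], dtype=float),
            time_avg_sd=np.asarray(d["time_avg_sd"], dtype=float),
            max_noise_variability=float(d["max_noise_variability"]),
            voltage_at_max=float(d["voltage_at_max"]),
            time_at_max=float(d["time_at_max"]),
        )


def boltzmann(v, v_half: float, k: float):
    """Steady-state availability: 1 / (1 + exp((V - V_half)/k)), k > 0."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - v_half) / k))


def inactivation_curve(sweeps: SweepSet, polarity: int = -1) -> InactivationCurve:
    """Normalized inactivation curve and Boltzmann fit.

    The per-voltage peak is the extremum of the repeat-averaged current in
    the test window (most negative for the default inward ``polarity=-1``).
    Peaks are normalized by the maximum magnitude across voltages and fit
    with the Boltzmann availability function by least squares. A diverging
    fit is flagged and the raw curve still returned.
    """
    lo, hi = sweeps.test_window
    mean_tr = sweeps.currents.mean(axis=1)[:, lo:hi]
    if np.all(mean_tr == 0):
        raise ValueError("all-zero currents in the test window")
    if polarity == -1:
        peaks = mean_tr.min(axis=1)
    elif polarity == 1:
        peaks = mean_tr.max(axis=1)
    else:
        raise ValueError("polarity must be +1 or -1")
    mags = np.abs(peaks)
    normalized = mags / mags.max()

    v = sweeps.voltages
    flagged = False
    try:
        popt, _ = curve_fit(
            boltzmann, v, normalized,
            p0=[float(np.median(v)), 5.0],
            bounds=([-500.0, 1e-6], [500.0, 200.0]),
            maxfev=20000,
        )
        v_half, k = float(popt[0]), float(popt[1])
        rmse = float(np.sqrt(np.mean((boltzmann(v, v_half, k) - normalized) ** 2)))
        if not (v.min() <= v_half <= v.max()):
            flagged = True
    except RuntimeError:
        v_half, k, rmse, flagged = float("nan"), float("nan"), float("nan"), True
    return InactivationCurve(
        voltages=v, peak_current=peaks, normalized=normalized,
        v_half=v_half, slope_k=k, fit_rmse=rmse, flagged=flagged,
    )


def noise_profile(sweeps: SweepSet, window: str = "test") -> NoiseProfile:
    """Residual-SD noise profile across repeats.

    For each voltage and time point the residual of repeat k is
    x_k(t) - mean_over_repeats(t); the SD across repeats (divisor n-1) gives
    the noise trace. ``window='test'`` restricts to the test pulse (the
    default for the maximum-variability summary); ``'full'`` uses the whole
    sweep. Residuals are computed within each voltage's own repeat block, so
    adding any common waveform to all repeats at a voltage leaves the
    profile unchanged.
    """
    if sweeps.n_repeats < 2:
        raise ValueError("residual SD needs at least 2 repeats")
    if window == "test":
        lo, hi = sweeps.test_window
    elif window == "full":
        lo, hi = 0, sweeps.currents.shape[2]
    else:
        raise ValueError("window must be 'test' or 'full'")
    block = sweeps.currents[:, :, lo:hi]
    sd = block.std(axis=1, ddof=1)  # (n_voltages, n_times)
    times = np.arange(lo, hi) * sweeps.dt
    iv, it = np.unravel_index(np.argmax(sd), sd.shape)
    return NoiseProfile(
        voltages=sweeps.voltages,
        times=times,
        sd_traces=sd,
        time_avg_sd=sd.mean(axis=1),
        max_noise_variability=float(sd[iv, it]),
        voltage_at_max=float(sweeps.voltages[iv]),
        time_at_max=float(times[it]),
    )


def peak_alignment_check(sweeps: SweepSet) -> pd.DataFrame:
    """Per-voltage diagnostics: where does the residual SD peak relative to
    the mean-current peak?

    Columns: voltage_mV, t_peak_s (time of max |mean current| in the test
    window), t_max_sd_s, offset_s, degenerate (all-zero SD trace).
    """
    lo, hi = sweeps.test_window
    mean_tr = sweeps.currents.mean(axis=1)[:, lo:hi]
    sd = sweeps.currents[:, :, lo:hi].std(axis=1, ddof=1)
    # identical repeats leave float-rounding residue in the SD; treat SD
    # below rounding scale as zero
    sd_tol = 1e-9 * max(1.0, float(np.abs(sweeps.currents).max()))
    rows = []
    for i, v in enumerate(sweeps.voltages):
        t_peak = (lo + int(np.argmax(np.abs(mean_tr[i])))) * sweeps.dt
        degenerate = bool(np.all(sd[i] <= sd_tol))
        t_sd = float("nan") if degenerate else (lo + int(np.argmax(sd[i]))) * sweeps.dt
        rows.append(
            {
                "voltage_mV": float(v),
                "t_peak_s": t_peak,
                "t_max_sd_s": t_sd,
                "offset_s": t_sd - t_peak if not degenerate else float("nan"),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


class BoltzmannInactivation(BaseEstimator):
    """Estimator: fit the inactivation curve and noise profile of a SweepSet."""

    def __init__(self, polarity: int = -1, window: str = "test"):
        self.polarity = polarity
        self.window = window

    def fit(self, X: SweepSet, y=None):
        curve = inactivation_curve(X, self.polarity)
        noise = noise_profile(X, self.window)
        self.curve_ = curve
        self.noise_ = noise
        self.v_half_ = curve.v_half
        self.slope_k_ = curve.slope_k
        self.max_noise_variability_ = noise.max_noise_variability
        return self

    def predict(self, voltages) -> np.ndarray:
        """Predicted normalized availability at the given prepulse voltages."""
        return boltzmann(voltages, self.v_half_, self.slope_k_)
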