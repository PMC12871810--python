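"""Ornstein-Uhlenbeck modeling and stationarity profiling of LFP series.

The local field potential is modeled as an OU process

    dX = -(X - mu)/tau dt + sqrt(2/tau) * sigma dW

parameterized by the mean-reversion time constant tau (seconds) and the
stationary noise amplitude sigma (signal SD, not the diffusion
coefficient). tau is estimated by least-squares fit of exp(-lag/tau) to
the empirical autocorrelation function of the mean-centered signal; sigma
is the SD of the linearly detrended signal. The fitted process can be
re-simulated at the original sampling interval, decomposed by a complex
Morlet continuous wavelet transform, and each frequency band profiled for
non-stationarity with augmented Dickey-Fuller tests (null: a unit root,
i.e. a stochastic trend, is present — higher p-values mean less evidence
for stationarity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy.optimize import curve_fit
from scipy.signal import detrend
from sklearn.base import BaseEstimator
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import adfuller

from ._utils import ArrayEqMixin
from .io import TraceRecord, register_result


@register_result
@dataclass(eq=False)
class OUParams(ArrayEqMixin):
    """Fitted OU parameters with fit diagnostics."""

    tau: float  # s
    sigma: float  # signal units (stationary SD)
    mu: float
    acf_fit_rmse: float = float("nan")
    n_lags_fit: int = 0

    def __post_init__(self):
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "sigma": self.sigma,
            "mu": self.mu,
            "acf_fit_rmse": self.acf_fit_rmse,
            "n_lags_fit": self.n_lags_fit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OUParams":
        return cls(
            tau=float(d["tau"]),
            sigma=float(d["sigma"]),
            mu=float(d["mu"]),
            acf_fit_rmse=float(d.get("acf_fit_rmse", float("nan"))),
            n_lags_fit=int(d.get("n_lags_fit", 0)),
        )


@dataclass(eq=False)
class WaveletDecomposition(ArrayEqMixin):
    """Complex Morlet CWT coefficients, (band x time), highest band first."""

    coefficients: np.ndarray
    frequencies: np.ndarray  # Hz, strictly decreasing with scale
    scales: np.ndarray
    wavelet: str
    dt: float

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    def time_avg_power(self) -> np.ndarray:
        return self.power.mean(axis=1)


@register_result
@dataclass(eq=False)
class StationarityProfile(ArrayEqMixin):
    """Per-band ADF results; p in [0,1], NaN for degenerate (constant) bands."""

    band_hz: np.ndarray
    adf_stat: np.ndarray
    p_value: np.ndarray
    n_lags: np.ndarray
    degenerate: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_hz": self.band_hz,
                "adf_stat": self.adf_stat,
                "p_value": self.p_value,
                "lags": self.n_lags,
                "degenerate": self.degenerate,
            }
        )

    def to_dict(self) -> dict:
        return {
            "band_hz": self.band_hz,
            "adf_stat": self.adf_stat,
            "p_value": self.p_value,
            "n_lags": self.n_lags,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StationarityProfile":
        return cls(
            band_hz=np.asarray(d["band_hz"], dtype=float),
            adf_stat=np.asarray(d["adf_stat"], dtype=float),
            p_value=np.asarray(d["p_value"], dtype=float),
            n_lags=np.asarray(d["n_lags"], dtype=int),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
        )


def fit_acf_decay(acf_values, dt: float, acf_floor: float = 1 / np.e) -> tuple[float, float, int]:
    """Fit exp(-lag/tau) to an empirical ACF.

    The fit range runs from lag 0 up to (and including) the first lag where
    the ACF drops below ``acf_floor``; at least two lags are always used.
    The default floor of 1/e restricts the fit to the first e-fold of the
    decay: beyond that the sample ACF is dominated by slowly-mixing,
    strongly correlated estimation noise, which inflates the variance of
    the fitted decay constant without reducing its bias.
    Returns (tau, rmse, n_lags_used).
    """
    rho = np.asarray(acf_values, dtype=float)
    below = np.flatnonzero(rho < acf_floor)
    cut = int(below[0]) if below.size else rho.size - 1
    cut = max(cut, 1)
    lags_t = np.arange(cut + 1) * dt
    y = rho[: cut + 1]

    rho1 = min(max(rho[1] if rho.size > 1 else 0.5, 1e-6), 1 - 1e-9)
    tau0 = -dt / np.log(rho1)
    popt, _ = curve_fit(
        lambda t, tau: np.exp(-t / tau),
        lags_t,
        y,
        p0=[tau0],
        bounds=(1e-12, np.inf),
        maxfev=10000,
    )
    tau = float(popt[0])
    rmse = float(np.sqrt(np.mean((np.exp(-lags_t / tau) - y) ** 2)))
    return tau, rmse, cut + 1


def fit_ou(trace: TraceRecord, max_lag: float = 1.0, acf_floor: float = 1 / np.e) -> OUParams:
    """Estimate OU parameters (tau, sigma, mu) from a trace.

    The signal is mean-centered before the ACF; sigma is the SD of the
    linearly detrended signal, so the estimate is invariant to constant
    offsets (and to slow linear drift in sigma).
    """
    x = trace.samples
    if np.var(x) == 0:
        raise ValueError("constant trace: autocorrelation degenerate")
    nlags = int(round(max_lag / trace.dt))
    nlags = min(max(nlags, 2), x.size - 2)
    rho = sm_acf(x - x.mean(), nlags=nlags, fft=True)
    if rho[0] <= 0 or not np.isfinite(rho[0]):
        raise ValueError("degenerate autocorrelation at lag 0")
    tau, rmse, used = fit_acf_decay(rho, trace.dt, acf_floor)
    sigma = float(np.std(detrend(x), ddof=1))
    return OUParams(tau=tau, sigma=sigma, mu=float(x.mean()),
                    acf_fit_rmse=rmse, n_lags_fit=used)


def simulate_fitted(params: OUParams, n: int, dt: float, seed: int = 0,
                    scheme: str = "exact") -> TraceRecord:
    """Simulate the fitted OU process at the given sampling interval."""
    from .synthetic import OUSpec, gen_ou

    spec = OUSpec(tau=params.tau, sigma=params.sigma, mu=params.mu, dt=dt, n=n,
                  scheme=scheme, seed=seed)
    return gen_ou(spec)


def default_freq_grid(fmin: float = 0.5, fmax: float = 100.0, n_bands: int = 32) -> np.ndarray:
    return np.geomspace(fmax, fmin, n_bands)


def _band_filter_norms(scales: np.ndarray, wavelet: str, dt: float) -> np.ndarray:
    """L2 energy of each band's effective discrete filter, measured from the
    impulse response (the discrete filters drift from unit energy at large
    scales, which would otherwise tilt band-power comparisons)."""
    support = int(np.ceil(17 * scales.max()))
    imp = np.zeros(2 * support + 1)
    imp[support] = 1.0
    coefs, _ = pywt.cwt(imp, scales, wavelet, sampling_period=dt, method="fft")
    return np.sqrt((np.abs(coefs) ** 2).sum(axis=1))


def cwt(
    trace: TraceRecord,
    freq_grid: Optional[Sequence[float]] = None,
    wavelet: str = "cmor1.5-1.0",
    method: str = "fft",
    normalization: str = "energy",
) -> WaveletDecomposition:
    """Continuous wavelet transform on a frequency grid (complex Morlet).

    Frequencies must lie strictly inside (0, Nyquist). The grid is sorted
    high-to-low so frequency decreases as scale increases. With the default
    ``normalization='energy'`` each band is scaled so its effective filter
    has unit energy: white noise then has flat expected time-averaged power
    across bands. ``'raw'`` returns the backend coefficients untouched.
    """
    freqs = default_freq_grid() if freq_grid is None else np.asarray(freq_grid, dtype=float)
    nyquist = 0.5 / trace.dt
    if np.any(freqs <= 0) or np.any(freqs >= nyquist):
        raise ValueError(f"frequencies must lie in (0, {nyquist} Hz)")
    if normalization not in ("energy", "raw"):
        raise ValueError("normalization must be 'energy' or 'raw'")
    freqs = np.sort(freqs)[::-1]
    scales = pywt.frequency2scale(wavelet, freqs * trace.dt)
    coefs, freqs_out = pywt.cwt(
        trace.samples, scales, wavelet, sampling_period=trace.dt, method=method
    )
    if normalization == "energy":
        coefs = coefs / _band_filter_norms(scales, wavelet, trace.dt)[:, None]
    return WaveletDecomposition(
        coefficients=coefs,
        frequencies=np.asarray(freqs_out, dtype=float),
        scales=np.asarray(scales, dtype=float),
        wavelet=wavelet,
        dt=trace.dt,
    )


def adf_test(x, lag_order="auto", regression: str = "c") -> tuple[float, float, int]:
    """Augmented Dickey-Fuller test; returns (statistic, p_value, lags_used).

    ``lag_order='auto'`` selects the lag by AIC; an integer fixes it. The
    regression includes a constant and no trend by default. Constant series
    are degenerate and return (nan, nan, 0).
    """
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        return float("nan"), float("nan"), 0
    if lag_order == "auto":
        stat, p, used, *_ = adfuller(x, regression=regression, autolag="AIC")
    else:
        stat, p, used, *_ = adfuller(
            x, maxlag=int(lag_order), regression=regression, autolag=None
        )
    return float(stat), float(p), int(used)


def adf_profile(
    decomp: WaveletDecomposition,
    lag_order=5,
    component: str = "real",
) -> StationarityProfile:
    """Per-band ADF stationarity profile of a wavelet decomposition.

    By default the test runs on the real part of each band's coefficients
    (preserving signed fluctuation structure); ``component='magnitude'``
    uses the envelope instead. No aggregation across bands is performed:
    the full p-value profile is the result.

    The default lag order is a fixed small value rather than
    information-criterion selection: band series are strongly oversampled
    relative to their bandwidth, and AIC-selected augmentation grows until
    the lagged differences reconstruct the band-pass filter itself, which
    rejects the unit root for any input. ``lag_order='auto'`` restores
    AIC selection for series sampled near their information rate.
    """
    if component == "real":
        series = decomp.coefficients.real
    elif component == "magnitude":
        series = np.abs(decomp.coefficients)
    else:
        raise ValueError("component must be 'real' or 'magnitude'")
    if series.shape[1] < 50:
        raise ValueError("each band series needs at least 50 samples")
    stats, ps, lags, degen = [], [], [], []
    for band in series:
        s, p, used = adf_test(band, lag_order=lag_order)
        stats.append(s)
        ps.append(p)
        lags.append(used)
        degen.append(not np.isfinite(s))
    return StationarityProfile(
        band_hz=decomp.frequencies,
        adf_stat=np.asarray(stats),
        p_value=np.asarray(ps),
        n_lags=np.asarray(lags),
        degenerate=np.asarray(degen),
    )


def raw_power(trace: TraceRecord, freq_grid: Optional[Sequence[float]] = None,
              wavelet: str = "cmor1.5-1.0") -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged wavelet power per band of the raw signal.

    Returns (frequencies, power), frequencies high-to-low.
    """
    dec = cwt(trace, freq_grid, wavelet)
    return dec.frequencies, dec.time_avg_power()


class OUFitter(BaseEstimator):
    """Estimator: fit OU parameters to a trace; ``sample`` re-simulates."""

    def __init__(self, max_lag: float = 1.0, acf_floor: float = 1 / np.e):
        self.max_lag = max_lag
        self.acf_floor = acf_floor

    def fit(self, X: TraceRecord, y=None):
        params = fit_ou(X, self.max_lag, self.acf_floor)
        self.params_ = params
        self.tau_ = params.tau
        self.sigma_ = params.sigma
        self.mu_ = params.mu
        return self

    def sample(self, n: int, dt: float, seed: int = 0, scheme: str = "exact") -> TraceRecord:
        return simulate_fitted(self.params_, n, dt, seed, scheme)
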