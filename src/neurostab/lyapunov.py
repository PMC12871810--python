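"""Local-divergence Lyapunov exponent of membrane-potential dynamics.

The voltage trace is embedded in the two-dimensional phase space
(V, dV/dt). For each reference point Y_i the nearest phase-space neighbor
Y_i* (outside a Theiler exclusion window, at strictly positive separation)
is tracked forward, and the per-reference exponent is

    lambda(i) = 1 / ((Kmax - Kmin + 1) * dt)
                * sum_{K=Kmin}^{Kmax} (1/K) * ln(||Y_{i+K} - Y_{i*+K}|| / ||Y_i - Y_{i*}||)

i.e. the average exponential rate at which initially close trajectories
separate over the expansion range [Kmin, Kmax]. Positive values indicate
divergence (dynamical instability); a neutral periodic orbit gives values
near zero. The global exponent is the mean of lambda(i) over references.
Because only distance ratios enter, the estimate is invariant to uniform
rescaling of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from ._utils import ArrayEqMixin
from .io import TraceRecord
from .spikes import SpikeTrain


@dataclass
class LyapunovConfig:
    """Expansion range (samples), Theiler window, and distance norm."""

    kmin: int = 1
    kmax: int = 10
    theiler: int = 10
    min_separation_rel: float = 1e-9  # floor on d0, relative to coordinate scale

    def __post_init__(self):
        if not (1 <= self.kmin <= self.kmax):
            raise ValueError("need 1 <= kmin <= kmax")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")
        if self.min_separation_rel < 0:
            raise ValueError("min_separation_rel must be >= 0")


@dataclass(eq=False)
class PhaseTrajectory(ArrayEqMixin):
    """Point series in phase space; shape (n, d) with d = 1 or 2."""

    points: np.ndarray
    dt: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim == 1:
            self.points = self.points[:, None]
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trajectory contains non-finite coordinates")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self):
        return self.points.shape[0]


@dataclass(eq=False)
class LyapunovSeries(ArrayEqMixin):
    """Per-reference exponents (1/s; NaN where no admissible neighbor) and
    their mean."""

    lambda_i: np.ndarray
    reference_indices: np.ndarray
    global_lambda: float
    n_skipped: int


def embed(trace: TraceRecord, standardize: bool = True) -> PhaseTrajectory:
    """Embed a voltage trace as (V, dV/dt) phase-space points.

    dV/dt uses central differences (one-sided at the edges). Because V (mV)
    and dV/dt (V/s) have incommensurate units, each coordinate is
    standardized to unit variance before distance computations; an all-equal
    coordinate is left untouched (the degenerate case surfaces downstream as
    zero separations).
    """
    if len(trace.samples) < 3:
        raise ValueError("embedding needs at least 3 samples")
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("trace contains non-finite samples")
    v = trace.samples
    dv = np.gradient(v, trace.dt)
    pts = np.column_stack([v, dv])
    if standardize:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        pts = pts / sd
    return PhaseTrajectory(points=pts, dt=trace.dt)


def lyapunov_exponent(
    traj: PhaseTrajectory,
    config: LyapunovConfig | None = None,
    chunk: int = 256,
) -> LyapunovSeries:
    """Per-reference and global Lyapunov exponents of a phase trajectory.

    For each reference index i (with i + Kmax inside the series) the nearest
    neighbor i* is chosen among indices j with |i - j| > theiler,
    j + Kmax inside the series, and strictly positive separation. To keep
    log-distance ratios meaningful, separations below
    ``min_separation_rel`` times the RMS coordinate scale (numerically
    indistinguishable points, e.g. exact orbit revisits) are also
    inadmissible. References with no admissible neighbor, or whose
    divergence hits an exact zero distance, are skipped (NaN) and counted
    in ``n_skipped``.
    """
    cfg = config or LyapunovConfig()
    pts = traj.points
    n = pts.shape[0]
    m = n - cfg.kmax  # indices whose expansion window fits
    if m < 2:
        raise ValueError(
            f"trajectory too short: {n} points for kmax={cfg.kmax} (need >= kmax + 2)"
        )
    scale = float(np.sqrt(np.mean((pts - pts.mean(axis=0)) ** 2)))
    d_floor = cfg.min_separation_rel * scale
    base = pts[:m]
    ks = np.arange(cfg.kmin, cfg.kmax + 1)
    norm = (cfg.kmax - cfg.kmin + 1) * traj.dt
    lam = np.full(m, np.nan)

    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        D = cdist(base[lo:hi], base)
        idx = np.arange(lo, hi)
        # Theiler exclusion band and zero separations are inadmissible
        band = np.abs(idx[:, None] - np.arange(m)[None, :]) <= cfg.theiler
        D[band] = np.inf
        D[D <= d_floor] = np.inf
        j = np.argmin(D, axis=1)
        d0 = D[np.arange(hi - lo), j]
        ok = np.isfinite(d0)
        if not ok.any():
            continue
        i_ok = idx[ok]
        j_ok = j[ok]
        acc = np.zeros(i_ok.size)
        valid = np.ones(i_ok.size, dtype=bool)
        for K in ks:
            dk = np.linalg.norm(pts[i_ok + K] - pts[j_ok + K], axis=1)
            good = dk > 0
            valid &= good
            with np.errstate(divide="ignore", invalid="ignore"):
                acc += np.where(good, np.log(np.where(good, dk, 1.0) / d0[ok]) / K, 0.0)
        lam_chunk = np.full(hi - lo, np.nan)
        vals = acc / norm
        vals[~valid] = np.nan
        lam_chunk[ok] = vals
        lam[lo:hi] = lam_chunk

    defined = np.isfinite(lam)
    if not defined.any():
        raise ValueError("no reference point had an admissible neighbor")
    return LyapunovSeries(
        lambda_i=lam,
        reference_indices=np.arange(m),
        global_lambda=float(np.mean(lam[defined])),
        n_skipped=int((~defined).sum()),
    )


def trajectory_noise_scale(pts: np.ndarray) -> float:
    """Robust per-axis noise SD of a trajectory, from first differences.

    At high sampling rates consecutive-point differences are dominated by
    measurement noise; the median absolute difference per axis (scaled to a
    Gaussian SD) combined across axes estimates the radius of the noise
    cloud around the underlying deterministic trajectory.
    """
    d = np.diff(pts, axis=0)
    sig = np.median(np.abs(d), axis=0) / 0.6745 / np.sqrt(2.0)
    return float(np.linalg.norm(sig))


def _lambda_references(
    pts: np.ndarray,
    dt: float,
    refs: np.ndarray,
    cfg: LyapunovConfig,
    candidates: np.ndarray | None = None,
    tree=None,
    d_floor: float | None = None,
) -> np.ndarray:
    """lambda(i) for chosen reference indices.

    Neighbors are the nearest admissible points among ``candidates``
    (trajectory indices; defaults to every index whose expansion window
    fits), searched with a KD-tree built once and reusable via ``tree``.
    ``d_floor`` is the absolute minimum admissible initial separation.
    """
    from scipy.spatial import cKDTree

    n = pts.shape[0]
    m = n - cfg.kmax
    if d_floor is None:
        scale = float(np.sqrt(np.mean((pts - pts.mean(axis=0)) ** 2)))
        d_floor = cfg.min_separation_rel * scale
    if candidates is None:
        candidates = np.arange(m)
    else:
        candidates = candidates[(candidates >= 0) & (candidates < m)]
    if tree is None:
        tree = cKDTree(pts[candidates])
    refs = refs[(refs >= 0) & (refs < m)]
    if refs.size == 0 or candidates.size == 0:
        return np.empty(0)
    k_query = min(2 * cfg.theiler + 40, candidates.size)
    dists, idxs = tree.query(pts[refs], k=k_query)
    dists = np.atleast_2d(dists)
    idxs = np.atleast_2d(idxs)
    ks = np.arange(cfg.kmin, cfg.kmax + 1)
    norm = (cfg.kmax - cfg.kmin + 1) * dt
    out = np.full(refs.size, np.nan)
    for r, i in enumerate(refs):
        cand_idx = candidates[idxs[r]]
        ok = (np.abs(cand_idx - i) > cfg.theiler) & (dists[r] > d_floor)
        if not ok.any():
            # all k_query nearest are inadmissible: brute-force this reference
            D = np.linalg.norm(pts[candidates] - pts[i], axis=1)
            D[np.abs(candidates - i) <= cfg.theiler] = np.inf
            D[D <= d_floor] = np.inf
            b = int(np.argmin(D))
            if not np.isfinite(D[b]):
                continue
            j, d0 = int(candidates[b]), float(D[b])
        else:
            first = int(np.flatnonzero(ok)[0])
            j, d0 = int(cand_idx[first]), float(dists[r, first])
        dk = np.linalg.norm(pts[i + ks] - pts[j + ks], axis=1)
        if np.any(dk <= 0):
            continue
        out[r] = float(np.sum(np.log(dk / d0) / ks) / norm)
    return out


def lyapunov_per_spike(
    trace: TraceRecord,
    spikes: SpikeTrain,
    window: float | tuple = (2e-3, 5e-4),
    config: LyapunovConfig | None = None,
    neighbors: str = "global",
    noise_floor_factor: float = 2.0,
) -> np.ndarray:
    """Lyapunov exponent around each spike, one value per spike.

    ``window`` is (pre, post) seconds around the peak (a scalar ``w`` means
    a centered window (w/2, w/2)); the default covers the depolarization
    phase, where the trajectory carries the onset kinetics.

    ``neighbors='global'`` (default) embeds the whole trace once and, for
    the reference points inside each spike's window, searches nearest
    neighbors over the entire phase trajectory. A spike's neighbors then
    typically lie on *other* spikes at the matching waveform phase, so the
    exponent measures how reproducible the action-potential trajectory is
    across spikes: near zero or negative when every spike follows the same
    orbit, positive when orbits diverge. On noisy recordings an initial
    separation below the measurement-noise cloud would measure noise
    decorrelation instead of trajectory divergence, so the minimum
    admissible separation is ``noise_floor_factor`` times the estimated
    noise scale (see :func:`trajectory_noise_scale`).

    ``neighbors='windowed'`` analyzes each window as an isolated trajectory
    (neighbors confined to the same window), measuring within-waveform
    expansion only.

    The series is aligned 1:1 with the spikes and feeds quartile-based
    state classification; spikes without a full window (or with no
    admissible neighbors) are flagged with NaN.
    """
    if spikes.peak_indices is None:
        raise ValueError("spike train has no peak indices")
    cfg = config or LyapunovConfig(kmin=1, kmax=5, theiler=5)
    if np.isscalar(window):
        pre = post = int(round(window / 2 / trace.dt))
    else:
        pre = int(round(window[0] / trace.dt))
        post = int(round(window[1] / trace.dt))
    n = trace.n_samples
    out = np.full(spikes.n_spikes, np.nan)
    if neighbors == "global":
        from scipy.spatial import cKDTree

        pts = embed(trace).points
        m = pts.shape[0] - cfg.kmax
        d_floor = noise_floor_factor * trajectory_noise_scale(pts)
        # candidate neighbors: the union of all peri-spike segments (the
        # baseline between spikes carries no onset-kinetics information)
        windows = [
            np.arange(max(p - pre, 0), min(p + post + 1, m))
            for p in spikes.peak_indices
        ]
        if not windows:
            return out
        candidates = np.unique(np.concatenate(windows))
        tree = cKDTree(pts[candidates])
        for k, p in enumerate(spikes.peak_indices):
            lo, hi = p - pre, p + post + 1
            if lo < 0 or hi > n:
                continue
            lam = _lambda_references(
                pts, trace.dt, np.arange(lo, hi), cfg,
                candidates=candidates, tree=tree, d_floor=d_floor,
            )
            if lam.size and np.isfinite(lam).any():
                out[k] = float(np.nanmean(lam))
        return out
    if neighbors != "windowed":
        raise ValueError("neighbors must be 'global' or 'windowed'")
    for k, p in enumerate(spikes.peak_indices):
        lo, hi = p - pre, p + post + 1
        if lo < 0 or hi > n:
            continue
        seg = TraceRecord(trace.samples[lo:hi], trace.dt, trace.channel_id, trace.units)
        try:
            res = lyapunov_exponent(embed(seg), cfg)
        except ValueError:
            continue
        out[k] = res.global_lambda
    return out


class LyapunovEstimator(BaseEstimator):
    """Estimator: fit on a TraceRecord or PhaseTrajectory, exposing the
    per-reference series and global exponent as fitted attributes."""

    def __init__(self, kmin: int = 1, kmax: int = 10, theiler: int = 10,
                 standardize: bool = True):
        self.kmin = kmin
        self.kmax = kmax
        self.theiler = theiler
        self.standardize = standardize

    def _config(self) -> LyapunovConfig:
        return LyapunovConfig(kmin=self.kmin, kmax=self.kmax, theiler=self.theiler)

    def fit(self, X, y=None):
        traj = embed(X, self.standardize) if isinstance(X, TraceRecord) else X
        res = lyapunov_exponent(traj, self._config())
        self.lambda_series_ = res.lambda_i
        self.global_lambda_ = res.global_lambda
        self.n_skipped_ = res.n_skipped
        return self

    def fit_per_spike(self, trace: TraceRecord, spikes: SpikeTrain,
                      window: float | tuple = (2e-3, 5e-4)):
        self.per_spike_lambda_ = lyapunov_per_spike(
            trace, spikes, window, LyapunovConfig(self.kmin, self.kmax, self.theiler)
        )
        defined = np.isfinite(self.per_spike_lambda_)
        self.global_lambda_ = float(np.mean(self.per_spike_lambda_[defined])) if defined.any() else float("nan")
        return self
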