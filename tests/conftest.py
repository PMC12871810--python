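"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from neurostab import LyapunovConfig, PhaseTrajectory


def logistic_map(n: int, x0: float = 0.1234, r: float = 4.0) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for t in range(n - 1):
        x[t + 1] = r * x[t] * (1.0 - x[t])
    return x


def lyapunov_double_loop(traj: PhaseTrajectory, cfg: LyapunovConfig) -> np.ndarray:
    """Naive double-loop oracle for the local-divergence exponent.

    Independent of the vectorized implementation: explicit loops over
    references and neighbor candidates, literal evaluation of the formula.
    """
    pts = traj.points
    n = pts.shape[0]
    m = n - cfg.kmax
    scale = float(np.sqrt(np.mean((pts - pts.mean(axis=0)) ** 2)))
    floor = cfg.min_separation_rel * scale
    lam = np.full(m, np.nan)
    for i in range(m):
        best_j, best_d = -1, np.inf
        for j in range(m):
            if abs(i - j) <= cfg.theiler:
                continue
            d = float(np.sqrt(np.sum((pts[i] - pts[j]) ** 2)))
            if d <= floor:
                continue
            if d < best_d:
                best_j, best_d = j, d
        if best_j < 0:
            continue
        total, valid = 0.0, True
        for K in range(cfg.kmin, cfg.kmax + 1):
            dk = float(np.sqrt(np.sum((pts[i + K] - pts[best_j + K]) ** 2)))
            if dk <= 0:
                valid = False
                break
            total += np.log(dk / best_d) / K
        if valid:
            lam[i] = total / ((cfg.kmax - cfg.kmin + 1) * traj.dt)
    return lam


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
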