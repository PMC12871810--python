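"""Latent spike-pattern analysis for extracellular (MEA-style) trains.

Two complementary views of temporal spike structure:

* **Adjacent-ISI mixture structure.** Consecutive interspike-interval pairs
  (T_i, T_{i+1}) are clustered with a Gaussian mixture model; the mixture
  weights are the "emergence probabilities" of the recurring local firing
  motifs. Because the component count was chosen by eye in the source
  analyses, it is a required input here, and an information-criterion table
  (AIC/BIC over k) is emitted to document the choice.

* **Probabilistic distance between groups.** Windows of consecutive ISIs
  (or instantaneous frequencies) are classified between group pairs by a
  bootstrap-aggregated decision-tree ensemble (a random forest). The
  distance is defined as 2 * (balanced out-of-bag accuracy - 0.5), clipped
  to [0, 1]: 0 when the groups are statistically exchangeable, 1 when they
  are perfectly separable. The pairwise distance matrix is summarized by an
  average-linkage dendrogram. This operational definition is symmetric,
  bounded, and zero under exchangeability; it is recorded in the result
  metadata because "probabilistic distance" has no single established
  definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.mixture import GaussianMixture

from ._utils import ArrayEqMixin, child_seed
from .io import register_result
from .spikes import SpikeTrain


@dataclass(eq=False)
class AdjacentISIData(ArrayEqMixin):
    """Paired consecutive ISIs (T_i, T_{i+1}) pooled across trains."""

    points: np.ndarray  # (n, 2), s (or log10 s)
    train_ids: np.ndarray  # provenance per point
    log_scale: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")


@register_result
@dataclass(eq=False)
class GMMResult(ArrayEqMixin):
    """Fitted mixture: weights are the cluster emergence probabilities."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    ic_table: Optional[pd.DataFrame] = None  # k, aic, bic
    regularized: bool = False

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "weights": self.weights,
            "means": self.means,
            "covariances": self.covariances,
            "responsibilities": self.responsibilities,
            "log_likelihood": self.log_likelihood,
            "ic_table": None if self.ic_table is None else self.ic_table.to_dict("list"),
            "regularized": self.regularized,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMMResult":
        return cls(
            n_components=int(d["n_components"]),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            responsibilities=np.asarray(d["responsibilities"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            ic_table=None if d.get("ic_table") is None else pd.DataFrame(d["ic_table"]),
            regularized=bool(d.get("regularized", False)),
        )


@register_result
@dataclass(eq=False)
class DistanceMatrix(ArrayEqMixin):
    """Pairwise probabilistic distances with their dendrogram."""

    labels: list
    distances: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    balanced_accuracy: np.ndarray  # per pair, same layout
    linkage: np.ndarray  # scipy average-linkage matrix
    newick: str
    metadata: dict

    def __post_init__(self):
        D = np.asarray(self.distances, dtype=float)
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(D < 0) or np.any(D > 1):
            raise ValueError("distances must lie in [0, 1]")
        self.distances = D

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "distances": self.distances,
            "balanced_accuracy": self.balanced_accuracy,
            "linkage": self.linkage,
            "newick": self.newick,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceMatrix":
        return cls(
            labels=list(d["labels"]),
            distances=np.asarray(d["distances"], dtype=float),
            balanced_accuracy=np.asarray(d["balanced_accuracy"], dtype=float),
            linkage=np.asarray(d["linkage"], dtype=float),
            newick=str(d["newick"]),
            metadata=dict(d["metadata"]),
        )


def _train_isis(train) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return train.isis
    return np.asarray(train, dtype=float)


def adjacent_isi(trains: Sequence, log_scale: bool = False) -> AdjacentISIData:
    """Consecutive ISI pairs per train, concatenated with provenance.

    Accepts SpikeTrains or raw ISI arrays. Trains contributing fewer than 2
    ISIs (3 spikes) are skipped with a warning. ``log_scale`` applies log10
    to both coordinates (ISI distributions are right-skewed).
    """
    pts, ids = [], []
    for k, train in enumerate(trains):
        isis = _train_isis(train)
        if isis.size < 2:
            warnings.warn(f"train {k} has fewer than 3 spikes; skipped", stacklevel=2)
            continue
        if np.any(isis <= 0):
            raise ValueError(f"train {k} has non-positive ISIs")
        pairs = np.column_stack([isis[:-1], isis[1:]])
        pts.append(pairs)
        ids.append(np.full(pairs.shape[0], k))
    if not pts:
        raise ValueError("no train contributed any ISI pair")
    points = np.vstack(pts)
    if log_scale:
        points = np.log10(points)
    return AdjacentISIData(points=points, train_ids=np.concatenate(ids), log_scale=log_scale)


def fit_gmm(
    data: AdjacentISIData,
    n_components: int,
    seed: int = 0,
    ic_kmax: int = 6,
) -> GMMResult:
    """EM fit of a Gaussian mixture to adjacent-ISI pairs.

    Initialization is k-means++-style and seeded. Singular covariances are
    regularized by a floor on the covariance eigenvalues and flagged. An
    AIC/BIC table for k = 1..ic_kmax documents the component-count choice,
    which is a required input rather than an automatic selection.
    """
    X = data.points
    if X.shape[0] < 10 * n_components:
        raise ValueError("need at least 10 points per mixture component")

    def _fit(k, reg):
        return GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=seed,
            n_init=3,
            init_params="k-means++",
            reg_covar=reg,
        ).fit(X)

    regularized = False
    try:
        gm = _fit(n_components, 1e-6)
    except ValueError:
        gm = _fit(n_components, 1e-3)
        regularized = True

    rows = []
    for k in range(1, ic_kmax + 1):
        if X.shape[0] < 10 * k:
            break
        g = _fit(k, 1e-6)
        rows.append({"k": k, "aic": g.aic(X), "bic": g.bic(X)})

    return GMMResult(
        n_components=n_components,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        responsibilities=gm.predict_proba(X),
        log_likelihood=float(gm.score(X) * X.shape[0]),
        ic_table=pd.DataFrame(rows),
        regularized=regularized,
    )


def _windows(trains: Sequence, window_len: int, feature: str) -> np.ndarray:
    """Non-overlapping windows of consecutive ISIs (or 1/ISI), per train."""
    wins = []
    for train in trains:
        vals = _train_isis(train)
        if feature == "rate":
            vals = 1.0 / vals
        n_w = vals.size // window_len
        if n_w:
            wins.append(vals[: n_w * window_len].reshape(n_w, window_len))
    if not wins:
        return np.empty((0, window_len))
    return np.vstack(wins)


def probabilistic_distance(
    groups: Mapping[str, Sequence],
    window_len: int = 20,
    n_trees: int = 500,
    seed: int = 0,
    feature: str = "isi",
    min_windows: int = 50,
) -> DistanceMatrix:
    """Ensemble-classifier probabilistic distance between labeled groups.

    Each group (a list of SpikeTrains or ISI arrays) is cut into
    non-overlapping windows of ``window_len`` consecutive ISIs; the ordered
    values in a window are the features. For every group pair a random
    forest (bootstrap-aggregated decision trees, sqrt(d) features per split)
    classifies the windows, and the pair distance is
    2 * (balanced out-of-bag accuracy - 0.5) clipped to [0, 1]. The matrix
    is summarized by an average-linkage dendrogram (also exported as a
    newick string).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if feature not in ("isi", "rate"):
        raise ValueError("feature must be 'isi' or 'rate'")
    labels = list(groups)
    wins = {}
    for name in labels:
        W = _windows(groups[name], window_len, feature)
        if W.shape[0] < min_windows:
            raise ValueError(
                f"group {name!r} yields only {W.shape[0]} windows of length "
                f"{window_len} (need >= {min_windows})"
            )
        wins[name] = W

    g = len(labels)
    D = np.zeros((g, g))
    B = np.full((g, g), 0.5)
    np.fill_diagonal(B, 1.0)
    for i in range(g):
        for j in range(i + 1, g):
            X = np.vstack([wins[labels[i]], wins[labels[j]]])
            y = np.r_[
                np.zeros(wins[labels[i]].shape[0], dtype=int),
                np.ones(wins[labels[j]].shape[0], dtype=int),
            ]
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                bootstrap=True,
                oob_score=True,
                random_state=child_seed(seed, i * g + j),
                n_jobs=1,
            ).fit(X, y)
            proba = rf.oob_decision_function_
            valid = ~np.isnan(proba).any(axis=1)
            bal = balanced_accuracy_score(y[valid], np.argmax(proba[valid], axis=1))
            B[i, j] = B[j, i] = bal
            D[i, j] = D[j, i] = float(np.clip(2.0 * (bal - 0.5), 0.0, 1.0))

    Z = linkage(squareform(D, checks=False), method="average")
    nwk = linkage_to_newick(Z, labels)
    return DistanceMatrix(
        labels=labels,
        distances=D,
        balanced_accuracy=B,
        linkage=Z,
        newick=nwk,
        metadata={
            "distance_definition": "2*(balanced OOB accuracy - 0.5), clipped to [0,1]",
            "window_len": window_len,
            "n_trees": n_trees,
            "feature": feature,
            "seed": seed,
        },
    )


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string with branch
    lengths (half the cophenetic distance at each merge)."""
    root = to_tree(Z)

    def render(node, parent_height):
        if node.is_leaf():
            name = str(labels[node.id]).replace(" ", "_")
            return f"{name}:{(parent_height or 0.0) / 2.0:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        if parent_height is None:
            return f"({left},{right});"
        return f"({left},{right}):{(parent_height - node.dist) / 2.0:.6g}"

    return render(root, None)


class AdjacentIsiGMM(BaseEstimator):
    """Estimator: GMM over adjacent-ISI pairs of a set of trains."""

    def __init__(self, n_components: int = 2, log_scale: bool = False, seed: int = 0):
        self.n_components = n_components
        self.log_scale = log_scale
        self.seed = seed

    def fit(self, trains, y=None):
        data = adjacent_isi(trains, self.log_scale)
        res = fit_gmm(data, self.n_components, self.seed)
        self.result_ = res
        self.weights_ = res.weights
        self.means_ = res.means
        return self


class PatternDistance(BaseEstimator):
    """Estimator: pairwise probabilistic distance between spike-train groups."""

    def __init__(self, window_len: int = 20, n_trees: int = 500, seed: int = 0,
                 feature: str = "isi", min_windows: int = 50):
        self.window_len = window_len
        self.n_trees = n_trees
        self.seed = seed
        self.feature = feature
        self.min_windows = min_windows

    def fit(self, groups: Mapping[str, Sequence], y=None):
        res = probabilistic_distance(
            groups, self.window_len, self.n_trees, self.seed, self.feature,
            self.min_windows,
        )
        self.result_ = res
        self.distances_ = res.distances
        self.labels_ = res.labels
        self.linkage_ = res.linkage
        return self
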