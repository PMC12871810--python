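"""Trace and result I/O, run configuration, and structured logging.

On-disk formats are deliberately plain: delimited text (CSV/TSV with a
header row, ``.`` decimal) for traces and per-spike tables, JSON for
structured results, and NumPy ``.npz`` as the binary array container.
Proprietary acquisition formats (pCLAMP ABF, MED64) must be converted
upstream; NWB input is available only when :mod:`pynwb` is installed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from ._utils import ArrayEqMixin, jsonable

logger = logging.getLogger("neurostab")

VALID_UNITS = ("mV", "pA", "uV", "µV")

SCHEMA_VERSION = 1


@dataclass(eq=False)
class TraceRecord(ArrayEqMixin):
    """A uniformly sampled signal (voltage or current).

    Parameters
    ----------
    samples : array of float
        Signal values, in ``units``.
    dt : float
        Sampling interval in seconds (10 kHz intracellular/LFP data has
        ``dt=1e-4``; 20 kHz MEA data ``dt=5e-5``).
    channel_id : str
        Free-form channel label.
    units : str
        One of ``mV``, ``pA``, ``uV``.
    """

    samples: np.ndarray
    dt: float
    channel_id: str = "ch0"
    units: str = "mV"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


def read_trace(
    path,
    format: str = "delimited",
    *,
    dt: float | None = None,
    units: str = "mV",
    channel_id: str | None = None,
) -> TraceRecord:
    """Read a trace from disk.

    ``delimited`` files carry either two columns (time in seconds, value)
    with ``dt`` inferred from the time column, or a single value column in
    which case ``dt`` must be supplied. The time column must be strictly
    increasing and uniformly spaced.
    """
    path = Path(path)
    if format == "delimited":
        df = pd.read_csv(path, sep=None, engine="python")
        df = df.dropna(axis=1, how="all")  # delimiter sniffing on a single
        # column can fabricate an empty second column
        if df.shape[1] >= 2:
            t = df.iloc[:, 0].to_numpy(dtype=float)
            v = df.iloc[:, 1].to_numpy(dtype=float)
            if t.size < 2:
                raise ValueError(f"{path}: a trace needs at least 2 samples")
            dts = np.diff(t)
            if np.any(dts <= 0):
                raise ValueError(f"{path}: time column is not strictly increasing")
            step = float(np.median(dts))
            if np.max(np.abs(dts - step)) > 1e-3 * step:
                raise ValueError(f"{path}: time column is not uniformly sampled")
            return TraceRecord(v, step, channel_id or path.stem, units)
        if dt is None:
            raise ValueError(
                f"{path}: single-column file needs an explicit dt (sampling interval)"
            )
        v = df.iloc[:, 0].to_numpy(dtype=float)
        return TraceRecord(v, dt, channel_id or path.stem, units)
    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            if "dt" not in z:
                raise ValueError(f"{path}: npz container is missing 'dt'")
            return TraceRecord(
                z["samples"],
                float(z["dt"]),
                str(z["channel_id"]) if "channel_id" in z else (channel_id or path.stem),
                str(z["units"]) if "units" in z else units,
            )
    if format == "nwb":
        try:
            import pynwb  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "NWB input requires the optional pynwb package; convert the file "
                "to delimited text or npz instead"
            ) from exc
        raise NotImplementedError("NWB reading requires pynwb at run time")
    raise ValueError(f"unknown trace format {format!r}")


def write_trace(trace: TraceRecord, path, format: str = "delimited") -> Path:
    path = Path(path)
    if format == "delimited":
        pd.DataFrame(
            {"time_s": trace.times, f"value_{trace.units}": trace.samples}
        ).to_csv(path, index=False)
    elif format == "npz":
        np.savez(
            path,
            samples=trace.samples,
            dt=trace.dt,
            channel_id=trace.channel_id,
            units=trace.units,
        )
    else:
        raise ValueError(f"unknown trace format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Result serialization: every result dataclass registers itself with
# to_dict/from_dict so write_results/read_results round-trip field-for-field.
# ---------------------------------------------------------------------------

_RESULT_REGISTRY: dict[str, type] = {}


def register_result(cls):
    """Class decorator adding a type to the JSON result registry."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


def write_results(results: Any, path) -> Path:
    """Serialize a registered result object (or plain dict/list) as JSON."""
    path = Path(path)
    if type(results).__name__ in _RESULT_REGISTRY:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "type": type(results).__name__,
            "data": jsonable(results.to_dict()),
        }
    elif isinstance(results, (dict, list)):
        payload = {"schema_version": SCHEMA_VERSION, "type": "json", "data": jsonable(results)}
    else:
        raise TypeError(f"cannot serialize {type(results).__name__}; not a registered result")
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_results(path) -> Any:
    payload = json.loads(Path(path).read_text())
    kind = payload.get("type")
    if kind == "json":
        return payload["data"]
    cls = _RESULT_REGISTRY.get(kind)
    if cls is None:
        raise ValueError(f"unknown result type {kind!r} in {path}")
    return cls.from_dict(payload["data"])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def _default_stage_params() -> dict:
    return {
        "spike": {"threshold": -20.0, "refractory_s": 2e-3, "polarity": 1,
                  "rapidness_window_s": 2e-3},
        "markov": {"quartile_convention": "linear"},
        "lyapunov": {"kmin": 1, "kmax": 10, "theiler": 10,
                     "window_pre_s": 2e-3, "window_post_s": 5e-4},
        "ou": {"max_lag_s": 1.0, "acf_floor": 0.3679},
        "cwt": {"fmin_hz": 0.5, "fmax_hz": 100.0, "n_bands": 32,
                "wavelet": "cmor1.5-1.0"},
        "adf": {"lag_order": 5, "regression": "c"},
        "na": {"polarity": -1, "window": "test"},
        "patterns": {"window_len": 20, "n_trees": 500, "feature": "isi"},
    }


@dataclass
class AnalysisConfig:
    """Per-stage parameters plus the master seed for a pipeline run."""

    seed: int = 0
    stages: dict = field(default_factory=_default_stage_params)

    def __post_init__(self):
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        self.seed = int(self.seed)
        defaults = _default_stage_params()
        for name, params in defaults.items():
            merged = dict(params)
            merged.update(self.stages.get(name, {}))
            self.stages[name] = merged
        self.validate()

    def validate(self):
        ly = self.stages["lyapunov"]
        if not (1 <= ly["kmin"] <= ly["kmax"]):
            raise ValueError("lyapunov expansion range needs 1 <= kmin <= kmax")
        if ly["theiler"] < 0:
            raise ValueError("theiler window must be >= 0")
        sp = self.stages["spike"]
        if sp["refractory_s"] < 0:
            raise ValueError("refractory must be >= 0")
        ou = self.stages["ou"]
        if ou["max_lag_s"] <= 0:
            raise ValueError("OU ACF lag range must be positive")
        cw = self.stages["cwt"]
        if not (0 < cw["fmin_hz"] < cw["fmax_hz"]):
            raise ValueError("CWT frequency grid must satisfy 0 < fmin < fmax")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        return cls(seed=raw.get("seed", 0), stages=raw.get("stages", {}))

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"seed": self.seed, "stages": self.stages}, indent=1))
        return path

    def hash(self) -> str:
        canon = json.dumps({"seed": self.seed, "stages": self.stages}, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def log_stage(stage: str, config: AnalysisConfig | None = None, seed: int | None = None,
              **extra) -> None:
    """One structured log line per pipeline stage, so runs are auditable."""
    record = {"stage": stage}
    if config is not None:
        record["config_hash"] = config.hash()
    if seed is not None:
        record["seed"] = int(seed)
    record.update(jsonable(extra))
    logger.info(json.dumps(record, sort_keys=True))


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def group_values(values_by_group: Mapping[str, Any]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        out[str(name)] = arr
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out
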