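"""Shared helpers: array-aware equality, seeding, serialization plumbing."""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np


def as_float_array(x, name: str = "array") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    return arr


def fields_equal(a: Any, b: Any) -> bool:
    """Field-for-field equality that treats numpy arrays by value.

    NaNs compare equal (they mark flagged entries, not corruption).
    """
    if a is b:
        return True
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        a, b = np.asarray(a), np.asarray(b)
        if a.shape != b.shape:
            return False
        if a.dtype.kind == "f" or b.dtype.kind == "f":
            return bool(np.array_equal(a, b, equal_nan=True))
        return bool(np.array_equal(a, b))
    if isinstance(a, float) and isinstance(b, float):
        return (a == b) or (np.isnan(a) and np.isnan(b))
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(fields_equal(x, y) for x, y in zip(a, b))
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(fields_equal(a[k], b[k]) for k in a)
    return bool(a == b)


class ArrayEqMixin:
    """Dataclass mixin giving value-based ``==`` with numpy array fields."""

    def __eq__(self, other):
        if type(other) is not type(self):
            return NotImplemented
        for f in dataclasses.fields(self):
            if not fields_equal(getattr(self, f.name), getattr(other, f.name)):
                return False
        return True

    __hash__ = None


def jsonable(x: Any) -> Any:
    """Convert numpy scalars/arrays to plain Python for JSON output."""
    if isinstance(x, np.ndarray):
        return [jsonable(v) for v in x.tolist()] if x.dtype == object else x.tolist()
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, dict):
        return {k: jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [jsonable(v) for v in x]
    return x


def child_seed(seed: int, stream: int) -> int:
    """Deterministic per-stream seed below 2**31 derived from a master seed."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
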