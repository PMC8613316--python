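"""Shared validation errors and helpers."""

from __future__ import annotations

import numpy as np


class InvalidConfigError(ValueError):
    """A generator or stage configuration violates its invariants."""


class InsufficientDataError(ValueError):
    """Too little usable data to compute the requested quantity."""


class UndefinedResultError(ValueError):
    """The requested quantity is mathematically undefined on this input."""


def as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def check_positive(value: float, name: str) -> None:
    if not value > 0:
        raise InvalidConfigError(f"{name} must be positive, got {value!r}")


def frame_index(t_s: float, fps: float) -> int:
    """Map a time in seconds to a frame index: floor(t * fps).

    One convention everywhere; all windows are half-open [start, end).
    """
    return int(np.floor(t_s * fps))
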