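"""Population synchrony against a circular-shuffle surrogate null, plus
pairwise correlation structure.

The population trace is the per-frame sum of the binarized (denoised,
nonzero -> 1) single-neuron traces.  The null preserves each neuron's total
activity exactly: every surrogate applies an independent uniform circular
shift to each neuron's binary trace and sums the rows.  The synchrony
threshold is the 95th percentile of the pooled frame values of all surrogate
population traces.  Synchronous events are maximal runs where the observed
population trace strictly exceeds the threshold; a neuron participates in an
event if it is active at the event's peak frame.

Pairwise structure: Pearson rho between dF/F0 traces, distance
d = sqrt(1 - rho), complete-linkage hierarchy, and the resulting leaf order
for correlation-matrix display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "BinaryRaster",
    "SynchronyNull",
    "SynchronyEvent",
    "SynchronyEvents",
    "CorrelationResult",
    "binarize",
    "build_null",
    "detect_events",
    "correlation_structure",
]


@dataclass(frozen=True)
class BinaryRaster:
    """neurons x frames binary activity matrix."""

    data: np.ndarray
    fps: float

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x frames)")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        object.__setattr__(self, "data", arr.astype(np.int8))

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def population_trace(self) -> np.ndarray:
        return self.data.sum(axis=0).astype(np.int64)


@dataclass(frozen=True)
class SynchronyNull:
    threshold: float
    n_surrogates: int
    percentile: float
    seed: int


@dataclass(frozen=True)
class SynchronyEvent:
    start_frame: int
    end_frame: int  # exclusive
    peak_frame: int
    participants: tuple[int, ...]


@dataclass(frozen=True)
class SynchronyEvents:
    events: tuple[SynchronyEvent, ...]
    fps: float
    n_frames: int
    n_neurons: int

    def __len__(self) -> int:
        return len(self.events)

    @property
    def mean_duration_s(self) -> float:
        if not self.events:
            return 0.0
        return float(np.mean([(e.end_frame - e.start_frame) / self.fps for e in self.events]))

    @property
    def fraction_time_in_synchrony(self) -> float:
        frames = sum(e.end_frame - e.start_frame for e in self.events)
        return frames / self.n_frames

    @property
    def mean_participant_fraction(self) -> float:
        if not self.events:
            return 0.0
        return float(np.mean([len(e.participants) / self.n_neurons for e in self.events]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [e.start_frame / self.fps for e in self.events],
                "end_s": [e.end_frame / self.fps for e in self.events],
                "peak_s": [e.peak_frame / self.fps for e in self.events],
                "n_participants": [len(e.participants) for e in self.events],
                "participant_ids": [
                    ";".join(map(str, e.participants)) for e in self.events
                ],
            }
        )


@dataclass(frozen=True)
class CorrelationResult:
    rho: np.ndarray
    distance: np.ndarray
    leaf_order: np.ndarray


def binarize(denoised: np.ndarray, fps: float) -> BinaryRaster:
    """Indicator of nonzero on a denoised dF/F0 matrix (neurons x frames)."""
    arr = np.asarray(denoised, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return BinaryRaster((arr != 0).astype(np.int8), fps)


def build_null(
    raster: BinaryRaster,
    n_surrogates: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> SynchronyNull:
    """Surrogate-null synchrony threshold.

    Each surrogate circularly shifts every neuron's binary trace by an
    independent uniform draw from {0, ..., T-1} (0 included) and sums the
    rows; the threshold is the given percentile of the pooled frame values of
    all surrogate population traces.  Row sums are conserved exactly in every
    surrogate.
    """
    if raster.n_neurons < 2 or raster.n_frames < 2:
        raise ValueError("need at least 2 neurons and 2 frames")
    rng = np.random.default_rng(seed)
    T = raster.n_frames
    pop = np.zeros((n_surrogates, T), dtype=np.int32)
    cols = np.arange(T)
    for row in raster.data:
        shifts = rng.integers(0, T, size=n_surrogates)
        # shifted[s, t] = row[(t - shift_s) mod T]
        idx = (cols[None, :] - shifts[:, None]) % T
        pop += row[idx]
    theta = float(np.percentile(pop, percentile))
    return SynchronyNull(threshold=theta, n_surrogates=n_surrogates, percentile=percentile, seed=seed)


def enumerate_null_exact(raster: BinaryRaster, percentile: float = 95.0) -> float:
    """Exact pooled-percentile threshold by exhaustive enumeration of all
    T^n circular-shift combinations.  Feasible only for tiny rasters; serves
    as the oracle for :func:`build_null`.
    """
    T = raster.n_frames
    rows = [np.stack([np.roll(r, s) for s in range(T)]) for r in raster.data]
    pools = rows[0].astype(np.int32)  # combos x frames
    for r in rows[1:]:
        pools = (pools[:, None, :] + r[None, :, :]).reshape(-1, T)
    return float(np.percentile(pools, percentile))


def detect_events(raster: BinaryRaster, null: SynchronyNull) -> SynchronyEvents:
    """Maximal runs where the population trace strictly exceeds the threshold.

    Peak = argmax within the run (earliest frame on ties); participants =
    neurons active at the peak frame.
    """
    pop = raster.population_trace()
    above = pop > null.threshold
    events: list[SynchronyEvent] = []
    t = 0
    T = above.size
    while t < T:
        if above[t]:
            start = t
            while t < T and above[t]:
                t += 1
            seg = pop[start:t]
            peak = start + int(np.argmax(seg))
            participants = tuple(int(i) for i in np.flatnonzero(raster.data[:, peak]))
            events.append(SynchronyEvent(start, t, peak, participants))
        else:
            t += 1
    return SynchronyEvents(tuple(events), raster.fps, raster.n_frames, raster.n_neurons)


def correlation_structure(dff_matrix: np.ndarray, neuron_ids: list[str] | None = None) -> CorrelationResult:
    """Pearson rho matrix, distance d = sqrt(1 - rho), complete-linkage leaf
    order for display.

    Raises
    ------
    ValueError
        Naming the first zero-variance neuron (undefined correlation).
    """
    X = np.asarray(dff_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 neurons")
    ids = neuron_ids or [f"n{i}" for i in range(X.shape[0])]
    var = X.var(axis=1)
    if np.any(var == 0):
        bad = ids[int(np.argmax(var == 0))]
        raise ValueError(f"neuron {bad} has zero variance; correlation undefined")
    rho = np.corrcoef(X)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    d = np.sqrt(np.clip(1.0 - rho, 0.0, None))
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="complete")
    order = leaves_list(Z)
    return CorrelationResult(rho=rho, distance=d, leaf_order=order)
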