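"""ROI fluorescence processing: dF/F0, transient detection, activity metrics.

The fractional fluorescence change dF/F0 is computed against a slowly varying
baseline F0 estimated as a sliding-window percentile (default: 50th percentile
over 300 s, centered, truncated at the recording edges).  Calcium transients
are detected on dF/F0 with three thresholds — minimum peak height of
4 x the baseline noise SD, minimum inter-peak interval of 0.5 s, minimum
transient width of 0.3 s — and a transient's extent is the contiguous run of
samples above 2 x the baseline SD around its peak.  Denoising zeroes every
sample below that same 2 x SD level.

The baseline noise SD is estimated robustly as 1.4826 x the median absolute
deviation of dF/F0, which is insensitive to the sparse large transients the
detector is looking for (a naive SD would be inflated by them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._validate import InsufficientDataError, as_1d_float, check_positive

__all__ = [
    "RawTrace",
    "DffTrace",
    "Transient",
    "TransientSet",
    "compute_dff",
    "estimate_baseline_sd",
    "detect_transients",
    "denoise",
    "activity_metrics",
    "downsample_frames",
]

MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass(frozen=True)
class RawTrace:
    """Raw mean-pixel fluorescence of one ROI."""

    F: np.ndarray
    fps: float
    neuron_id: str = "n0"

    def __post_init__(self):
        object.__setattr__(self, "F", as_1d_float(self.F, "F"))
        check_positive(self.fps, "fps")
        if self.F.size < 2:
            raise ValueError("trace must have at least 2 frames")


@dataclass(frozen=True)
class DffTrace:
    """dF/F0 trace with its per-frame baseline and noise estimate."""

    dff: np.ndarray
    f0: np.ndarray
    baseline_sd: float
    fps: float
    neuron_id: str = "n0"

    @property
    def duration_s(self) -> float:
        return self.dff.size / self.fps


@dataclass(frozen=True)
class Transient:
    peak_frame: int
    start_frame: int
    end_frame: int  # exclusive
    size: float  # sum of dF/F0 over the extent

    def peak_s(self, fps: float) -> float:
        return self.peak_frame / fps


@dataclass(frozen=True)
class TransientSet:
    transients: tuple[Transient, ...]
    fps: float
    n_frames: int
    neuron_id: str = "n0"

    def __len__(self) -> int:
        return len(self.transients)

    @property
    def frequency_per_min(self) -> float:
        duration_min = self.n_frames / self.fps / 60.0
        return len(self.transients) / duration_min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_id,
                "peak_s": [t.peak_frame / self.fps for t in self.transients],
                "start_s": [t.start_frame / self.fps for t in self.transients],
                "end_s": [t.end_frame / self.fps for t in self.transients],
                "size": [t.size for t in self.transients],
            }
        )


def _sliding_percentile(F: np.ndarray, window_frames: int, percentile: float) -> np.ndarray:
    """Centered sliding percentile with edge truncation.

    The window is forced to an odd frame count (+/- half on each side) so the
    centering is unambiguous; windows are clipped at the trace boundaries.
    Uses the pandas rolling skiplist implementation, O(n log w).
    """
    if window_frames % 2 == 0:
        window_frames += 1
    window_frames = min(window_frames, 2 * F.size - 1)
    s = pd.Series(F)
    out = s.rolling(window_frames, center=True, min_periods=1).quantile(
        percentile / 100.0, interpolation="linear"
    )
    return out.to_numpy()


def compute_dff(trace: RawTrace, window_s: float = 300.0, percentile: float = 50.0) -> DffTrace:
    """Compute dF/F0 with a sliding-percentile baseline.

    F0[t] is the given percentile of F over a window of ``window_s`` seconds
    centered at t (truncated at the edges; recordings shorter than the window
    use the whole trace for every frame).  dF/F0 = (F - F0) / F0.

    Raises
    ------
    ValueError
        If any fluorescence sample is <= 0 (the ratio contract requires a
        positive baseline).
    """
    check_positive(window_s, "window_s")
    F = trace.F
    if np.any(F <= 0):
        bad = int(np.argmax(F <= 0))
        raise ValueError(
            f"non-positive fluorescence at frame {bad} (neuron {trace.neuron_id}); "
            "dF/F0 requires F > 0"
        )
    window_frames = max(int(round(window_s * trace.fps)), 1)
    f0 = _sliding_percentile(F, window_frames, percentile)
    dff = (F - f0) / f0
    sd = estimate_baseline_sd(dff) if dff.size >= 10 else float(np.std(dff))
    return DffTrace(dff=dff, f0=f0, baseline_sd=sd, fps=trace.fps, neuron_id=trace.neuron_id)


def estimate_baseline_sd(dff: np.ndarray) -> float:
    """Robust spread of the transient-free portion of dF/F0.

    1.4826 x median absolute deviation: equals the SD for Gaussian noise and
    is essentially unchanged by sparse large transients.
    """
    dff = as_1d_float(dff, "dff")
    if dff.size < 10:
        raise InsufficientDataError(f"need >= 10 frames to estimate baseline SD, got {dff.size}")
    med = np.median(dff)
    return float(MAD_TO_SD * np.median(np.abs(dff - med)))


def _extent(dff: np.ndarray, peak: int, level: float) -> tuple[int, int]:
    """Contiguous run of samples strictly above ``level`` containing ``peak``."""
    lo = peak
    while lo > 0 and dff[lo - 1] > level:
        lo -= 1
    hi = peak + 1
    while hi < dff.size and dff[hi] > level:
        hi += 1
    return lo, hi


def detect_transients(
    dff: np.ndarray,
    baseline_sd: float,
    fps: float,
    min_height_sd: float = 4.0,
    min_ipi_s: float = 0.5,
    min_width_s: float = 0.3,
    neuron_id: str = "n0",
) -> TransientSet:
    """Detect calcium transients on a dF/F0 trace.

    A transient's peak must exceed ``min_height_sd`` x ``baseline_sd``; peaks
    closer than ``min_ipi_s`` collapse to the larger (earlier wins ties); the
    extent — the contiguous run above 2 x ``baseline_sd`` around the peak —
    must last at least ``min_width_s``.  Overlapping extents merge into one
    transient keeping the taller peak.  size = sum of dF/F0 over the extent.
    """
    dff = as_1d_float(dff, "dff")
    check_positive(baseline_sd, "baseline_sd")
    check_positive(fps, "fps")
    height = min_height_sd * baseline_sd
    # plateau_size=1 makes flat-topped (rectangular) transients detectable
    cand, props = find_peaks(dff, height=height, plateau_size=1)
    if cand.size == 0:
        return TransientSet((), fps, dff.size, neuron_id)
    # flat peaks: take the left edge of the plateau (earliest frame)
    cand = props["left_edges"]
    heights = dff[cand]

    # greedy inter-peak pruning: taller first, earlier wins ties
    order = np.lexsort((cand, -heights))
    min_ipi = min_ipi_s * fps
    kept: list[int] = []
    for i in order:
        if all(abs(int(cand[i]) - k) >= min_ipi for k in kept):
            kept.append(int(cand[i]))
    kept.sort()

    level = 2.0 * baseline_sd
    min_width = min_width_s * fps
    raw: list[tuple[int, int, int]] = []
    for pk in kept:
        lo, hi = _extent(dff, pk, level)
        if hi - lo >= min_width:
            raw.append((lo, hi, pk))
    # merge overlapping extents, keeping the taller peak (earlier on ties)
    merged: list[tuple[int, int, int]] = []
    for lo, hi, pk in sorted(raw):
        if merged and lo < merged[-1][1]:
            plo, phi, ppk = merged[-1]
            best = ppk if dff[ppk] >= dff[pk] else pk
            merged[-1] = (plo, max(phi, hi), best)
        else:
            merged.append((lo, hi, pk))
    out = tuple(
        Transient(peak_frame=pk, start_frame=lo, end_frame=hi, size=float(dff[lo:hi].sum()))
        for lo, hi, pk in merged
    )
    return TransientSet(out, fps, dff.size, neuron_id)


def denoise(dff: np.ndarray, baseline_sd: float) -> np.ndarray:
    """Zero every sample below 2 x baseline_sd.  Idempotent."""
    dff = as_1d_float(dff, "dff")
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be >= 0")
    out = np.where(dff >= 2.0 * baseline_sd, dff, 0.0)
    return out


def activity_metrics(transients: TransientSet, duration_s: float) -> tuple[float, float]:
    """(mean transient size, frequency in transients/minute).

    Mean size is 0 when there are no transients; frequency = count / minutes.
    """
    check_positive(duration_s, "duration_s")
    n = len(transients)
    mean_size = float(np.mean([t.size for t in transients.transients])) if n else 0.0
    freq = n / (duration_s / 60.0)
    return mean_size, freq


def downsample_frames(x: np.ndarray, factor: int = 3) -> np.ndarray:
    """Non-overlapping block means along the last axis (30 -> 10 fps uses
    factor 3); trailing frames that do not fill a block are dropped."""
    x = np.asarray(x, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = (x.shape[-1] // factor) * factor
    trimmed = x[..., :n]
    shape = trimmed.shape[:-1] + (n // factor, factor)
    return trimmed.reshape(shape).mean(axis=-1)
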