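"""Mesoscopic (widefield) activity and whisking-locked quantification.

Whisking magnitude comes from a grid-based optic-flow (block-matching)
estimate on consecutive behavior frames; the whole-field activity trace
Ca_WF is the spatial mean dF/F0 over an activity mask built by thresholding
each pixel's lag-1 autocorrelation.  Whisking-locked metrics: the
whisking-modulation of Ca_WF (post-onset [0.3, 1.3) s mean minus pre-onset
[-1, 0) s mean, averaged over whisking episodes), the response delay
(time-of-maximum of post-onset Ca_WF, averaged over episodes), and the
Pearson cross-correlation profile between Ca_WF and whisking magnitude.

Behavior runs at 30 fps and imaging at 10 fps; alignment uses non-overlapping
3-frame block means.  All windows are half-open [a, b) with the frame of a
time t given by floor(t * fps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._validate import InsufficientDataError, as_1d_float, check_positive, frame_index
from .traces import MAD_TO_SD, downsample_frames

__all__ = [
    "OnsetLockedSummary",
    "grid_optic_flow",
    "activity_mask",
    "whole_field_trace",
    "resample_behavior",
    "detect_whisking_onsets",
    "whisking_correlation",
    "onset_locked_summary",
]


def grid_optic_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    grid_spacing: int = 16,
    block_size: int = 11,
    search_radius: int = 8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Block-matching motion between two frames on a regular grid.

    For each grid point, the integer displacement minimising the sum of
    squared differences between the block around the point in ``frame_a`` and
    the shifted block in ``frame_b`` is taken (ties: smallest displacement
    first in raster order of the search).  Returns (grid points, vectors,
    mean Euclidean magnitude).  Grid points whose search window would leave
    the frame are skipped.
    """
    A = np.asarray(frame_a, dtype=float)
    B = np.asarray(frame_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"frames differ in shape: {A.shape} vs {B.shape}")
    if A.ndim != 2:
        raise ValueError("frames must be 2-D")
    half = block_size // 2
    margin = half + search_radius
    ys = np.arange(margin, A.shape[0] - margin, grid_spacing)
    xs = np.arange(margin, A.shape[1] - margin, grid_spacing)
    if ys.size == 0 or xs.size == 0:
        raise ValueError("frame too small for the given block size and search radius")
    shifts = [
        (dy, dx)
        for dy in range(-search_radius, search_radius + 1)
        for dx in range(-search_radius, search_radius + 1)
    ]
    # order by magnitude so ties resolve to the smallest displacement
    shifts.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s))
    points, vectors = [], []
    for y in ys:
        for x in xs:
            block = A[y - half : y + half + 1, x - half : x + half + 1]
            best, best_ssd = (0, 0), np.inf
            for dy, dx in shifts:
                cand = B[y + dy - half : y + dy + half + 1, x + dx - half : x + dx + half + 1]
                ssd = float(np.sum((block - cand) ** 2))
                if ssd < best_ssd:
                    best_ssd, best = ssd, (dy, dx)
            points.append((y, x))
            vectors.append(best)
    vec = np.asarray(vectors, dtype=float)
    mean_mag = float(np.mean(np.hypot(vec[:, 0], vec[:, 1])))
    return np.asarray(points), vec, mean_mag


def whisking_magnitude_series(frames: np.ndarray, **flow_kwargs) -> np.ndarray:
    """Mean optic-flow magnitude for each consecutive frame pair of a stack.

    Output has ``len(frames) - 1`` entries (magnitude of motion into each
    subsequent frame).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of >= 2 frames")
    return np.array(
        [grid_optic_flow(frames[i], frames[i + 1], **flow_kwargs)[2] for i in range(frames.shape[0] - 1)]
    )


def activity_mask(pixel_dff: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Mask of pixels whose lag-1 autocorrelation reaches ``threshold``.

    ``pixel_dff`` is (n_pixels, n_frames) or (H, W, n_frames); the mask has
    the matching spatial shape.  Constant pixels (undefined autocorrelation)
    are excluded with a warning.
    """
    arr = np.asarray(pixel_dff, dtype=float)
    spatial_shape = arr.shape[:-1]
    flat = arr.reshape(-1, arr.shape[-1])
    if flat.shape[1] < 10:
        raise InsufficientDataError("need >= 10 frames per pixel")
    x0 = flat[:, :-1]
    x1 = flat[:, 1:]
    sd0 = x0.std(axis=1)
    sd1 = x1.std(axis=1)
    const = (sd0 == 0) | (sd1 == 0)
    if const.any():
        warnings.warn(f"{int(const.sum())} constant pixel trace(s) excluded from mask")
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = ((x0 - x0.mean(axis=1, keepdims=True)) * (x1 - x1.mean(axis=1, keepdims=True))).mean(
            axis=1
        ) / (sd0 * sd1)
    mask = np.where(const, False, ac >= threshold)
    return mask.reshape(spatial_shape)


def whole_field_trace(pixel_dff: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Ca_WF: spatial mean dF/F0 over masked pixels, per frame."""
    arr = np.asarray(pixel_dff, dtype=float)
    flat = arr.reshape(-1, arr.shape[-1])
    m = np.asarray(mask, dtype=bool).reshape(-1)
    if m.size != flat.shape[0]:
        raise ValueError("mask shape does not match pixel array")
    if not m.any():
        raise InsufficientDataError("empty activity mask")
    return flat[m].mean(axis=0)


def resample_behavior(series: np.ndarray, behavior_fps: int = 30, imaging_fps: int = 10) -> np.ndarray:
    """Block-mean a behavior-rate series down to the imaging rate."""
    if behavior_fps % imaging_fps != 0:
        raise ValueError(f"{behavior_fps} fps is not an integer multiple of {imaging_fps} fps")
    return downsample_frames(np.asarray(series, dtype=float), behavior_fps // imaging_fps)


def detect_whisking_onsets(
    magnitude: np.ndarray,
    fps: float = 30.0,
    on_threshold: float | None = None,
    threshold_mad: float = 3.0,
    min_quiet_s: float = 0.5,
    min_bout_s: float = 0.5,
) -> np.ndarray:
    """Whisking-episode onset times (s).

    An onset is the first frame at or above the threshold after at least
    ``min_quiet_s`` below it, with the magnitude staying at or above
    threshold for at least ``min_bout_s``.  The default threshold is
    ``threshold_mad`` x 1.4826 x MAD of the series (config-exposed; the
    criteria are package choices, not field standards).
    """
    mag = as_1d_float(magnitude, "magnitude")
    check_positive(fps, "fps")
    if on_threshold is None:
        med = np.median(mag)
        mad = np.median(np.abs(mag - med))
        if mad > 0:
            on_threshold = float(med + threshold_mad * MAD_TO_SD * mad)
        elif mag.max() > med:
            # degenerate quiet baseline (MAD 0, e.g. noiseless square bouts):
            # halfway between the quiet level and the maximum
            on_threshold = float(med + 0.5 * (mag.max() - med))
        else:
            return np.asarray([])  # constant series: no episodes
    if on_threshold <= 0:
        raise ValueError("on_threshold must be positive")
    above = mag >= on_threshold
    n_quiet = max(int(round(min_quiet_s * fps)), 1)
    n_bout = max(int(round(min_bout_s * fps)), 1)
    onsets = []
    for t in range(mag.size):
        if not above[t]:
            continue
        if t < n_quiet or above[t - n_quiet : t].any():
            continue
        if t + n_bout <= mag.size and above[t : t + n_bout].all():
            onsets.append(t / fps)
    return np.asarray(onsets)


def whisking_correlation(
    ca_wf: np.ndarray,
    whisking: np.ndarray,
    fps: float = 10.0,
    max_lag_s: float = 2.0,
) -> dict:
    """Pearson correlation between Ca_WF and (resampled) whisking magnitude.

    Returns the zero-lag r, the profile of r over integer frame lags within
    +/- ``max_lag_s``, and the peak (lag, r).  A positive peak lag means
    Ca_WF follows whisking by that many seconds.
    """
    ca = as_1d_float(ca_wf, "ca_wf")
    wh = as_1d_float(whisking, "whisking")
    if ca.size != wh.size:
        raise ValueError("series must have equal length")
    if ca.std() == 0 or wh.std() == 0:
        raise ValueError("constant input; correlation undefined")
    max_lag = int(round(max_lag_s * fps))
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = wh[: wh.size - lag], ca[lag:]
        else:
            a, b = wh[-lag:], ca[: ca.size + lag]
        if a.std() == 0 or b.std() == 0:
            rs[i] = np.nan
        else:
            rs[i] = np.corrcoef(a, b)[0, 1]
    peak_i = int(np.nanargmax(rs))
    return {
        "r_zero_lag": float(rs[lags == 0][0]),
        "lags_s": lags / fps,
        "r_profile": rs,
        "peak_lag_s": float(lags[peak_i] / fps),
        "peak_r": float(rs[peak_i]),
    }


@dataclass(frozen=True)
class OnsetLockedSummary:
    segments: np.ndarray  # episodes x frames, Ca_WF aligned to onset (-2 s .. +2 s)
    segment_times_s: np.ndarray
    modulation: float  # dF/F0 units
    response_delay_s: float
    n_episodes: int


def onset_locked_summary(
    ca_wf: np.ndarray,
    onsets_s: np.ndarray,
    fps: float = 10.0,
    pre_window: tuple[float, float] = (-1.0, 0.0),
    post_window: tuple[float, float] = (0.3, 1.3),
    align_window: tuple[float, float] = (-2.0, 2.0),
    delay_mode: str = "argmax_time",
) -> OnsetLockedSummary:
    """Whisking-onset-locked Ca_WF metrics.

    modulation = mean over episodes of (mean Ca_WF on [0.3, 1.3) s) minus
    (mean Ca_WF on [-1, 0) s).  The response delay is, per episode, the time
    of the post-onset maximum relative to onset (``delay_mode='argmax_time'``,
    the default since the quantity is reported in seconds); with
    ``delay_mode='peak_value'`` the per-episode post-onset maximum *value*
    is averaged instead.  Episodes without the full alignment margin are
    dropped with a warning.
    """
    ca = as_1d_float(ca_wf, "ca_wf")
    check_positive(fps, "fps")
    if delay_mode not in ("argmax_time", "peak_value"):
        raise ValueError("delay_mode must be 'argmax_time' or 'peak_value'")
    lo_f = frame_index(align_window[0], fps)
    hi_f = frame_index(align_window[1], fps)
    segments, mods, delays, times = [], [], [], []
    dropped = 0
    for t0 in np.atleast_1d(onsets_s):
        f0 = frame_index(t0, fps)
        if f0 + lo_f < 0 or f0 + hi_f > ca.size:
            dropped += 1
            continue
        segments.append(ca[f0 + lo_f : f0 + hi_f])
        pre = ca[f0 + frame_index(pre_window[0], fps) : f0 + frame_index(pre_window[1], fps)]
        post = ca[f0 + frame_index(post_window[0], fps) : f0 + frame_index(post_window[1], fps)]
        mods.append(post.mean() - pre.mean())
        if delay_mode == "argmax_time":
            delays.append(post_window[0] + int(np.argmax(post)) / fps)
        else:
            delays.append(float(np.max(post)))
        times.append(t0)
    if dropped:
        warnings.warn(f"dropped {dropped} episode(s) without the full +/- alignment margin")
    if not segments:
        raise InsufficientDataError("no usable whisking episodes")
    return OnsetLockedSummary(
        segments=np.asarray(segments),
        segment_times_s=np.asarray(times),
        modulation=float(np.mean(mods)),
        response_delay_s=float(np.mean(delays)),
        n_episodes=len(segments),
    )
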