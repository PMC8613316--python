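"""Touch-event extraction, touch responses, and ROC-based texture
selectivity classification.

A touch event is a whisker-contact interval lasting strictly more than 1 s
(shorter contacts are discarded as incidental).  The per-neuron touch
response subtracts the pre-contact baseline (mean dF/F0 over [-1, 0) s) from
the contact response (mean over [0.3, 1.3) s after contact onset), averaged
over contacts.  Selectivity uses the detection probability (DP): the area
under the ROC curve for discriminating contact-period decision variables
(window-mean dF/F0) from pre-contact ones, with ties counting 1/2 —
equivalently the Mann-Whitney U statistic divided by n1*n2.  Significance
comes from a label permutation test (default 1000 shuffles, add-one
p-estimator, one-sided for elevated contact activity).  A neuron responsive
(p < alpha) to exactly one texture is novel- (NTS) or familiar-texture-
selective (FTS); to both, non-selective; to neither, non-responsive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._validate import InsufficientDataError, as_1d_float, frame_index
from .traces import RawTrace, compute_dff, detect_transients

__all__ = [
    "Contact",
    "ContactSchedule",
    "extract_touch_events",
    "touch_response",
    "dp_score",
    "dp_from_dvs",
    "permutation_test",
    "classify",
    "interaction_activity",
    "classify_population",
    "TextureResponseProfile",
]

TEXTURES = ("novel", "familiar")
CATEGORIES = ("NTS", "FTS", "non-selective", "non-responsive")


@dataclass(frozen=True)
class Contact:
    texture: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError(f"contact end ({self.end_s}) must exceed start ({self.start_s})")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture label {self.texture!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ContactSchedule:
    contacts: tuple[Contact, ...]
    phase: str = "testing"

    def __post_init__(self):
        for tex in TEXTURES:
            ivs = sorted((c.start_s, c.end_s) for c in self.contacts if c.texture == tex)
            for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping {tex} contacts at {s1} s")

    def for_texture(self, texture: str) -> list[Contact]:
        return [c for c in self.contacts if c.texture == texture]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [c.texture for c in self.contacts],
                "start_s": [c.start_s for c in self.contacts],
                "end_s": [c.end_s for c in self.contacts],
            }
        )


def extract_touch_events(
    annotations, min_duration_s: float = 1.0, phase: str = "testing"
) -> ContactSchedule:
    """Keep only contacts lasting strictly more than ``min_duration_s``.

    ``annotations`` is an iterable of (texture, start_s, end_s) or a
    DataFrame with those columns.  Malformed intervals (end <= start) raise.
    """
    if isinstance(annotations, pd.DataFrame):
        rows = annotations[["label", "start_s", "end_s"]].itertuples(index=False)
    else:
        rows = annotations
    kept = []
    for label, start, end in rows:
        c = Contact(str(label), float(start), float(end))
        if c.duration_s > min_duration_s:
            kept.append(c)
    return ContactSchedule(tuple(kept), phase=phase)


def _episode_dvs(
    dff: np.ndarray,
    fps: float,
    contacts: list[Contact],
    pre_window: tuple[float, float] = (-1.0, 0.0),
    contact_window: tuple[float, float] = (0.3, 1.3),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-episode (pre, contact) window-mean decision variables.

    Episodes whose pre-window would leave the recording, or whose contact
    window would, are dropped (returned count of drops).
    """
    pre_dvs, con_dvs, dropped = [], [], 0
    n = dff.size
    for c in contacts:
        f0 = frame_index(c.start_s, fps)
        p0, p1 = f0 + frame_index(pre_window[0], fps), f0 + frame_index(pre_window[1], fps)
        c0, c1 = f0 + frame_index(contact_window[0], fps), f0 + frame_index(contact_window[1], fps)
        if p0 < 0 or c1 > n:
            dropped += 1
            continue
        pre_dvs.append(dff[p0:p1].mean())
        con_dvs.append(dff[c0:c1].mean())
    return np.asarray(pre_dvs), np.asarray(con_dvs), dropped


def touch_response(
    dff: np.ndarray, fps: float, schedule: ContactSchedule
) -> dict[str, float]:
    """Mean touch response per texture: mean over contacts of (contact-window
    mean dF/F0 minus pre-contact-window mean)."""
    dff = as_1d_float(dff, "dff")
    out = {}
    for tex in TEXTURES:
        contacts = schedule.for_texture(tex)
        pre, con, dropped = _episode_dvs(dff, fps, contacts)
        if dropped:
            warnings.warn(f"dropped {dropped} {tex} contact(s) without a full pre-contact margin")
        if pre.size == 0:
            raise InsufficientDataError(f"no usable {tex} contacts")
        out[tex] = float(np.mean(con - pre))
    return out


def dp_from_dvs(pre_dvs: np.ndarray, contact_dvs: np.ndarray) -> float:
    """DP = (wins + ties/2) / (n1*n2) for contact vs. pre decision variables,
    computed as the Mann-Whitney U from average ranks."""
    pre = np.asarray(pre_dvs, dtype=float)
    con = np.asarray(contact_dvs, dtype=float)
    n1, n2 = con.size, pre.size
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("need at least one DV in each group")
    ranks = rankdata(np.concatenate([con, pre]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def dp_score(
    dff: np.ndarray, fps: float, schedule: ContactSchedule, texture: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """DP for one texture plus the (pre, contact) DV samples it used."""
    dff = as_1d_float(dff, "dff")
    contacts = schedule.for_texture(texture)
    pre, con, _ = _episode_dvs(dff, fps, contacts)
    if pre.size < 2:
        raise InsufficientDataError(
            f"need >= 2 usable {texture} episodes, got {pre.size}"
        )
    return dp_from_dvs(pre, con), pre, con


def permutation_test(
    pre_dvs: np.ndarray,
    contact_dvs: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    paired: bool = False,
    two_sided: bool = False,
) -> float:
    """Permutation p-value for the observed DP.

    Default scheme pools all DVs and reassigns group labels preserving group
    sizes; ``paired=True`` instead swaps the (pre, contact) pair within each
    episode with probability 1/2.  One-sided by default (responsiveness =
    elevated contact activity); ``two_sided`` tests |DP - 0.5|.  The add-one
    estimator p = (1 + #extreme) / (1 + n_perm) avoids p = 0.
    """
    pre = np.asarray(pre_dvs, dtype=float)
    con = np.asarray(contact_dvs, dtype=float)
    n1, n2 = con.size, pre.size
    obs = dp_from_dvs(pre, con)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([con, pre])
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    denom = n1 * n2
    if paired:
        if n1 != n2:
            raise ValueError("paired permutation requires equal group sizes")
        flips = rng.integers(0, 2, size=(n_perm, n1)).astype(bool)
        perm_dp = np.empty(n_perm)
        for k in range(n_perm):
            c = np.where(flips[k], pre, con)
            p = np.where(flips[k], con, pre)
            perm_dp[k] = dp_from_dvs(p, c)
    else:
        # vectorised label reshuffle: random subsets of size n1 get the
        # 'contact' label; U from precomputed pooled ranks
        u = np.argsort(rng.random((n_perm, n1 + n2)), axis=1)[:, :n1]
        perm_dp = (ranks[u].sum(axis=1) - offset) / denom
    if two_sided:
        extreme = np.abs(perm_dp - 0.5) >= abs(obs - 0.5)
    else:
        extreme = perm_dp >= obs
    return float((1 + int(extreme.sum())) / (1 + n_perm))


def classify(p_novel: float, p_familiar: float, alpha: float = 0.05) -> str:
    """NTS / FTS / non-selective / non-responsive from the two p-values."""
    rn, rf = p_novel < alpha, p_familiar < alpha
    if rn and rf:
        return "non-selective"
    if rn:
        return "NTS"
    if rf:
        return "FTS"
    return "non-responsive"


def interaction_activity(
    dff: np.ndarray, fps: float, schedule: ContactSchedule
) -> tuple[float, float]:
    """Frame-weighted mean dF/F0 during the union of contact intervals and
    during its complement."""
    dff = as_1d_float(dff, "dff")
    mask = np.zeros(dff.size, dtype=bool)
    for c in schedule.contacts:
        mask[max(frame_index(c.start_s, fps), 0) : min(frame_index(c.end_s, fps), dff.size)] = True
    if mask.all():
        raise InsufficientDataError("schedule covers the entire recording; no non-interaction frames")
    if not mask.any():
        raise InsufficientDataError("schedule covers no frames of the recording")
    return float(dff[mask].mean()), float(dff[~mask].mean())


@dataclass(frozen=True)
class TextureResponseProfile:
    table: pd.DataFrame  # neuron_id, resp_*, dp_*, p_*, category, n_transients
    alpha: float
    n_perm: int

    def category_fractions(self, include_excluded: bool = False) -> dict[str, float]:
        tab = self.table if include_excluded else self.table[self.table.category != "excluded"]
        n = len(tab)
        return {cat: float((tab.category == cat).sum()) / n for cat in CATEGORIES}


def classify_population(
    traces_F: np.ndarray,
    fps: float,
    schedule: ContactSchedule,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    neuron_ids: list[str] | None = None,
    dff_window_s: float = 300.0,
    screen_transients: bool = True,
    paired: bool = False,
) -> TextureResponseProfile:
    """Full per-neuron texture-selectivity pipeline on raw fluorescence.

    dF/F0 -> trace-quality screen (neurons with zero detected transients are
    excluded before classification, mirroring the manual removal of silent /
    noisy ROIs) -> per-texture touch response, DP, permutation p ->
    category.  Each neuron draws its permutation seed from ``seed`` via a
    SeedSequence so results are reproducible yet streams are independent.
    """
    F = np.asarray(traces_F, dtype=float)
    if F.ndim == 1:
        F = F[None, :]
    ids = neuron_ids or [f"n{i}" for i in range(F.shape[0])]
    child_seeds = np.random.SeedSequence(seed).spawn(F.shape[0])
    rows = []
    for i, nid in enumerate(ids):
        d = compute_dff(RawTrace(F[i], fps, nid), window_s=dff_window_s)
        seeds = child_seeds[i].generate_state(2)
        row = {"neuron_id": nid}
        ts = detect_transients(d.dff, d.baseline_sd, fps, neuron_id=nid)
        row["n_transients"] = len(ts)
        if screen_transients and len(ts) == 0:
            row.update(
                {
                    "resp_novel": np.nan,
                    "resp_familiar": np.nan,
                    "dp_novel": np.nan,
                    "dp_familiar": np.nan,
                    "p_novel": np.nan,
                    "p_familiar": np.nan,
                    "category": "excluded",
                }
            )
            rows.append(row)
            continue
        resp = touch_response(d.dff, fps, schedule)
        ps = {}
        for j, tex in enumerate(TEXTURES):
            dp, pre, con = dp_score(d.dff, fps, schedule, tex)
            p = permutation_test(pre, con, n_perm=n_perm, seed=int(seeds[j] % (2**31)), paired=paired)
            row[f"resp_{tex}"] = resp[tex]
            row[f"dp_{tex}"] = dp
            row[f"p_{tex}"] = p
            ps[tex] = p
        row["category"] = classify(ps["novel"], ps["familiar"], alpha)
        rows.append(row)
    return TextureResponseProfile(pd.DataFrame(rows), alpha=alpha, n_perm=n_perm)
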