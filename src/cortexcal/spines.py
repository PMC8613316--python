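"""Longitudinal dendritic protrusion accounting.

A protrusion record gives, per imaging session, whether a given spine or
filopodium (identified by ID, on a dendrite, at a position in micrometres
along it) is present.  Turnover between a session pair counts spines formed
(absent then present) and eliminated (present then absent), both expressed
as percentages of the spine count in the *previous* session; filopodium
turnover uses the all-protrusion (spines + filopodia) denominator instead.
Survival follows a cohort of newly formed spines to a later session.
Re-emergence asks whether new spines appear within 2 micrometres (strictly)
of a site where a spine was previously eliminated, on the same dendrite —
and, conversely, what fraction of eliminated spines is later recovered by a
nearby new spine.  A re-emerged spine is a new identity, never a
resurrection of the old record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import UndefinedResultError

__all__ = [
    "SPINE_CLASSES",
    "validate_spine_table",
    "present_ids",
    "turnover",
    "survival",
    "reemergence",
    "class_composition",
    "match_protrusions_by_position",
]

SPINE_CLASSES = ("mushroom", "stubby", "thin", "other")
ALL_CLASSES = SPINE_CLASSES + ("filopodium",)

REQUIRED_COLUMNS = ["protrusion_id", "session_index", "dendrite_id", "position_um", "class", "present"]


def validate_spine_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format protrusion table invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spine table missing column(s): {missing}")
    if (table["position_um"] < 0).any():
        raise ValueError("positions must be >= 0")
    bad = set(table["class"].unique()) - set(ALL_CLASSES)
    if bad:
        raise ValueError(f"unknown protrusion class(es): {sorted(bad)}")
    n_dend = table.groupby("protrusion_id")["dendrite_id"].nunique()
    if (n_dend > 1).any():
        offender = n_dend[n_dend > 1].index[0]
        raise ValueError(f"protrusion {offender!r} maps to more than one dendrite")
    return table


def present_ids(table: pd.DataFrame, session: int, spines_only: bool = True) -> set:
    """IDs of protrusions present at a session (spines only by default)."""
    sel = (table["session_index"] == session) & table["present"].astype(bool)
    if spines_only:
        sel &= table["class"] != "filopodium"
    return set(table.loc[sel, "protrusion_id"])


def turnover(table: pd.DataFrame, s_prev: int, s_next: int) -> dict:
    """Formation/elimination percentages between two sessions.

    Spine percentages use the previous-session *spine* count as denominator;
    filopodium percentages use the previous-session count of all protrusions
    (spines plus filopodia).
    """
    validate_spine_table(table)
    for s in (s_prev, s_next):
        if s not in set(table["session_index"]):
            raise ValueError(f"session {s} not in table")
    prev_spines = present_ids(table, s_prev)
    next_spines = present_ids(table, s_next)
    if not prev_spines:
        raise UndefinedResultError(f"no spines present at session {s_prev}; rates undefined")
    prev_filo = present_ids(table, s_prev, spines_only=False) - prev_spines
    next_filo = present_ids(table, s_next, spines_only=False) - next_spines
    n_prev_prot = len(prev_spines) + len(prev_filo)
    formed = next_spines - prev_spines
    eliminated = prev_spines - next_spines
    filo_formed = next_filo - prev_filo
    filo_elim = prev_filo - next_filo
    return {
        "pct_formed": 100.0 * len(formed) / len(prev_spines),
        "pct_eliminated": 100.0 * len(eliminated) / len(prev_spines),
        "n_formed": len(formed),
        "n_eliminated": len(eliminated),
        "n_prev_spines": len(prev_spines),
        "pct_filopodia_formed": 100.0 * len(filo_formed) / n_prev_prot,
        "pct_filopodia_eliminated": 100.0 * len(filo_elim) / n_prev_prot,
        "n_prev_protrusions": n_prev_prot,
        "formed_ids": formed,
        "eliminated_ids": eliminated,
    }


def survival(table: pd.DataFrame, cohort_session: int, later_session: int) -> dict:
    """Percentage of spines newly formed at ``cohort_session`` (absent at the
    preceding session) still present at ``later_session``."""
    validate_spine_table(table)
    sessions = sorted(set(table["session_index"]))
    if cohort_session not in sessions or later_session not in sessions:
        raise ValueError("both sessions must be in the table")
    if later_session <= cohort_session:
        raise ValueError("later_session must follow cohort_session")
    i = sessions.index(cohort_session)
    if i == 0:
        raise ValueError("cohort_session has no preceding session to define new spines")
    prev = present_ids(table, sessions[i - 1])
    cohort = present_ids(table, cohort_session) - prev
    if not cohort:
        raise UndefinedResultError("empty new-spine cohort; survival undefined")
    surviving = cohort & present_ids(table, later_session)
    return {
        "pct_surviving": 100.0 * len(surviving) / len(cohort),
        "n_surviving": len(surviving),
        "n_cohort": len(cohort),
    }


def _last_position(table: pd.DataFrame, ids: set, session: int) -> pd.DataFrame:
    sel = table[(table["session_index"] == session) & table["protrusion_id"].isin(ids)]
    return sel.drop_duplicates("protrusion_id")[["protrusion_id", "dendrite_id", "position_um"]]


def reemergence(
    table: pd.DataFrame,
    elimination_window: tuple[int, int],
    formation_window: tuple[int, int],
    radius_um: float = 2.0,
) -> dict:
    """Positional re-emergence between an elimination and a formation window.

    Eliminations: spines present at ``elimination_window[0]`` and absent at
    ``elimination_window[1]`` (site = last observed position).  Formations:
    spines absent at ``formation_window[0]`` and present at
    ``formation_window[1]``.  Proximity = same dendrite and |dx| strictly
    below ``radius_um``.  Returns both directions — the fraction of new
    spines near an elimination site and the fraction of eliminated spines
    recovered by a nearby new spine — with counts; a direction with an empty
    denominator is reported as None, not 0.
    """
    validate_spine_table(table)
    e0, e1 = elimination_window
    f0, f1 = formation_window
    if not (e0 < e1 <= f0 < f1):
        raise ValueError("windows must be ordered and non-overlapping")
    eliminated = present_ids(table, e0) - present_ids(table, e1)
    formed = present_ids(table, f1) - present_ids(table, f0)
    sites = _last_position(table, eliminated, e0)
    news = _last_position(table, formed, f1)
    pct_new_near = pct_elim_recovered = None
    n_new_near = n_elim_recovered = 0
    if len(news) and len(sites):
        merged = news.merge(sites, on="dendrite_id", suffixes=("_new", "_site"))
        merged = merged[(merged.position_um_new - merged.position_um_site).abs() < radius_um]
        n_new_near = merged["protrusion_id_new"].nunique()
        n_elim_recovered = merged["protrusion_id_site"].nunique()
    if len(news):
        pct_new_near = 100.0 * n_new_near / len(news)
    if len(sites):
        pct_elim_recovered = 100.0 * n_elim_recovered / len(sites)
    return {
        "pct_new_near_elimination": pct_new_near,
        "pct_eliminated_recovered": pct_elim_recovered,
        "n_new": len(news),
        "n_eliminated": len(sites),
        "n_new_near": n_new_near,
        "n_eliminated_recovered": n_elim_recovered,
        "radius_um": radius_um,
    }


def class_composition(table: pd.DataFrame, cohort_ids) -> dict[str, float]:
    """Fractions of a spine cohort per morphological class; sums to 1 over
    {mushroom, stubby, thin, other}."""
    validate_spine_table(table)
    cohort_ids = set(cohort_ids)
    if not cohort_ids:
        raise UndefinedResultError("empty cohort; composition undefined")
    classes = (
        table[table["protrusion_id"].isin(cohort_ids)]
        .drop_duplicates("protrusion_id")
        .set_index("protrusion_id")["class"]
    )
    missing = cohort_ids - set(classes.index)
    if missing:
        raise ValueError(f"cohort id(s) not in table: {sorted(missing)[:5]}")
    filo = classes[classes == "filopodium"]
    if len(filo):
        raise ValueError("class composition is defined over spines, not filopodia")
    n = len(classes)
    return {cls: float((classes == cls).sum()) / n for cls in SPINE_CLASSES}


def match_protrusions_by_position(
    table: pd.DataFrame, tolerance_um: float = 0.5
) -> pd.DataFrame:
    """Assign protrusion IDs to an ID-free longitudinal table by positional
    matching: records on the same dendrite within ``tolerance_um`` (inclusive)
    across consecutive sessions are the same protrusion (greedy
    nearest-first matching).  The matching tolerance is a package decision —
    manual annotation pipelines relocate dendrites by eye and publish no
    tolerance.

    Input columns: session_index, dendrite_id, position_um, class, present.
    Returns a copy with a ``protrusion_id`` column.
    """
    df = table.copy().reset_index(drop=True)
    df["protrusion_id"] = -1
    next_id = 0
    sessions = sorted(df["session_index"].unique())
    prev_rows = pd.DataFrame()
    for s in sessions:
        cur = df[df["session_index"] == s]
        taken: set[int] = set()
        for idx in cur.index:
            if len(prev_rows):
                same = prev_rows[prev_rows["dendrite_id"] == df.at[idx, "dendrite_id"]]
                same = same[~same.index.isin(taken)]
                if len(same):
                    dist = (same["position_um"] - df.at[idx, "position_um"]).abs()
                    j = dist.idxmin()
                    if dist[j] <= tolerance_um:
                        df.at[idx, "protrusion_id"] = df.at[j, "protrusion_id"]
                        taken.add(j)
                        continue
            df.at[idx, "protrusion_id"] = next_id
            next_id += 1
        prev_rows = df[df["session_index"] == s]
    df["protrusion_id"] = "p" + df["protrusion_id"].astype(str)
    return df
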