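"""Reading, cleaning and structuring of fixation event tables.

Cleaning follows the acquisition protocol of the emulated study: fixations
landing off the presentation monitor are dropped, and the first fixation of
a trial is dropped when it overlaps the inter-trial fixation cross (the
gaze is still parked on the cross when the stimulus appears).  "Overlaps"
is operationalized as falling within a disk of configurable radius around
the trial's cross center, defaulting to 0.75 x (cross size / 2).

The temporal analysis splits each trial at the fifth/sixth fixation into an
``early`` and a ``late`` period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gazesal.cohort import (
    CROSS_SIZE_PX,
    CROSS_STROKE_PX,
    SCREEN_H,
    SCREEN_W,
    cross_positions,
)
from gazesal.scoring import sdd

MANDATORY_COLUMNS = [
    "subject_id", "group", "stimulus_id", "category",
    "fix_index", "x_px", "y_px", "duration_ms",
]
NUMERIC_COLUMNS = ["fix_index", "x_px", "y_px", "duration_ms"]

EARLY_MAX_INDEX = 5  # fixations 1..5 are "early"; 6..end are "late"


class SchemaError(ValueError):
    """The input table does not match the expected fixation-report schema."""


@dataclass(frozen=True)
class ScreenGeometry:
    width_px: int = SCREEN_W
    height_px: int = SCREEN_H


@dataclass(frozen=True)
class CrossGeometry:
    """Fixation-cross geometry and the overlap criterion used by cleaning."""

    size_px: float = CROSS_SIZE_PX
    stroke_px: float = CROSS_STROKE_PX
    overlap_radius_frac: float = 0.75  # fraction of size/2
    positions: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(map(tuple, cross_positions())))

    @property
    def overlap_radius_px(self) -> float:
        return self.overlap_radius_frac * self.size_px / 2.0


def read_fixation_table(path, screen: ScreenGeometry | None = None,
                        return_rejects: bool = False):
    """Read a CSV fixation report (EyeLink-export-like dialect).

    Mandatory columns are checked by name; extra columns are kept.  Rows
    whose numeric fields fail to parse are collected into a rejects frame
    (returned when ``return_rejects`` is true) rather than raising.
    """
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty fixation file: {path}") from None
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise SchemaError(f"fixation file has a header but no rows: {path}")

    table = raw.copy()
    for col in NUMERIC_COLUMNS + [c for c in ("onset_ms", "cross_x_px", "cross_y_px")
                                  if c in raw.columns]:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    if "is_start_cross" in table.columns:
        table["is_start_cross"] = table["is_start_cross"].astype(str).str.lower().isin(
            ("true", "1", "t", "yes"))
    bad = table[NUMERIC_COLUMNS].isna().any(axis=1)
    rejects = raw.loc[bad].copy()
    table = table.loc[~bad].reset_index(drop=True)
    table["fix_index"] = table["fix_index"].astype(int)
    if return_rejects:
        return table, rejects
    return table


@dataclass
class CleaningReport:
    rows_in: int = 0
    rows_kept: int = 0
    off_screen_dropped: int = 0
    cross_dropped: int = 0
    trials_excluded: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


_TRIAL_KEYS = ["subject_id", "stimulus_id"]


def clean_fixations(table: pd.DataFrame, screen: ScreenGeometry | None = None,
                    cross: CrossGeometry | None = None
                    ) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop off-monitor fixations and leading on-cross fixations; re-rank.

    Within each trial (subject x stimulus), only the *first* fixation is
    eligible for cross-removal: it is dropped iff it falls within the
    overlap disk around the trial's cross center (columns ``cross_x_px`` /
    ``cross_y_px`` when present, otherwise the nearest of the protocol's
    eight cross positions).  ``fix_index`` is re-ranked consecutively from
    1.  Trials left without fixations are excluded (counted, not an error).
    """
    screen = screen or ScreenGeometry()
    cross = cross or CrossGeometry(positions=tuple(
        map(tuple, cross_positions(screen.width_px if screen else SCREEN_W,
                                   screen.height_px if screen else SCREEN_H))))
    report = CleaningReport(rows_in=len(table))
    t = table.sort_values(_TRIAL_KEYS + ["fix_index"], kind="stable").reset_index(drop=True)

    on_screen = ((t["x_px"] >= 0) & (t["x_px"] < screen.width_px)
                 & (t["y_px"] >= 0) & (t["y_px"] < screen.height_px))
    report.off_screen_dropped = int((~on_screen).sum())
    t = t.loc[on_screen].reset_index(drop=True)

    first = t.groupby(_TRIAL_KEYS, sort=False).head(1)
    if {"cross_x_px", "cross_y_px"}.issubset(t.columns):
        dx = first["x_px"] - first["cross_x_px"]
        dy = first["y_px"] - first["cross_y_px"]
        d2 = dx**2 + dy**2
    else:
        pos = np.asarray(cross.positions)
        d2 = np.min(
            (first["x_px"].to_numpy()[:, None] - pos[None, :, 0]) ** 2
            + (first["y_px"].to_numpy()[:, None] - pos[None, :, 1]) ** 2,
            axis=1)
        d2 = pd.Series(d2, index=first.index)
    drop_idx = first.index[np.asarray(d2) <= cross.overlap_radius_px**2]
    report.cross_dropped = len(drop_idx)
    t = t.drop(index=drop_idx).reset_index(drop=True)

    n_trials_before = table.groupby(_TRIAL_KEYS).ngroups
    n_trials_after = t.groupby(_TRIAL_KEYS).ngroups if len(t) else 0
    report.trials_excluded = n_trials_before - n_trials_after

    t["fix_index"] = t.groupby(_TRIAL_KEYS, sort=False).cumcount() + 1
    report.rows_kept = len(t)
    return t, report


def split_periods(table: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Label fixations ``early`` (index <= 5) / ``late`` (index >= 6).

    Returns the labeled table plus the two sub-tables; the split is a
    partition of the cleaned table.
    """
    t = table.copy()
    t["period"] = np.where(t["fix_index"] <= EARLY_MAX_INDEX, "early", "late")
    return t, t[t["period"] == "early"].copy(), t[t["period"] == "late"].copy()


@dataclass
class OculomotorReport:
    """Per-subject and group-level oculomotor summaries.

    ``per_subject``: subject_id, group, mean_fix_count_per_image,
    mean_fix_duration_ms, sdd_px (pooled over all the subject's fixations).
    ``group_stats``: group means/SDs of the per-subject values.
    ``duration_by_index``: group x fixation index mean durations with SE
    over subjects.  ``reach_fractions``: fraction of trials reaching
    fixation index k.
    """

    per_subject: pd.DataFrame
    group_stats: pd.DataFrame
    duration_by_index: pd.DataFrame
    reach_fractions: pd.DataFrame


def summarize_oculomotor(table: pd.DataFrame,
                         reach_indices: tuple[int, ...] = (5, 10, 15)
                         ) -> OculomotorReport:
    """Oculomotor summaries of a cleaned fixation table."""
    t = table
    if "is_start_cross" in t.columns:
        t = t[~t["is_start_cross"].astype(bool)]

    counts = (t.groupby(["subject_id", "group"] + ["stimulus_id"], observed=True)
              .size().rename("n_fix").reset_index())
    per_subj = (counts.groupby(["subject_id", "group"], observed=True)["n_fix"]
                .mean().rename("mean_fix_count_per_image").reset_index())
    dur = (t.groupby(["subject_id"], observed=True)["duration_ms"]
           .mean().rename("mean_fix_duration_ms"))
    spread = (t.groupby("subject_id", observed=True)
              .apply(lambda g: sdd(g["x_px"].to_numpy(), g["y_px"].to_numpy()),
                     include_groups=False)
              .rename("sdd_px"))
    per_subject = per_subj.merge(dur, on="subject_id").merge(spread, on="subject_id")

    group_stats = (per_subject.groupby("group", observed=True)
                   .agg(n_subjects=("subject_id", "nunique"),
                        mean_fix_count=("mean_fix_count_per_image", "mean"),
                        sd_fix_count=("mean_fix_count_per_image", "std"),
                        mean_duration_ms=("mean_fix_duration_ms", "mean"),
                        sd_duration_ms=("mean_fix_duration_ms", "std"),
                        mean_sdd_px=("sdd_px", "mean"),
                        sd_sdd_px=("sdd_px", "std"))
                   .reset_index())

    subj_idx = subject_index_means(t)
    dbi = (subj_idx.groupby(["group", "fix_index"], observed=True)["mean_duration_ms"]
           .agg(mean_duration_ms="mean",
                se_ms=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                n_subjects="size")
           .reset_index())

    return OculomotorReport(per_subject, group_stats, dbi,
                            _reach_fractions(t, reach_indices))


def _reach_fractions(t: pd.DataFrame, reach_indices) -> pd.DataFrame:
    trial = (t.groupby(_TRIAL_KEYS, observed=True)
             .agg(group=("group", "first"), max_index=("fix_index", "max"))
             .reset_index())
    rows = []
    for g, sub in trial.groupby("group", observed=True):
        for k in reach_indices:
            rows.append({"group": g, "k": int(k),
                         "fraction": float((sub["max_index"] >= k).mean())})
    return pd.DataFrame(rows)


def subject_index_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean fixation duration at each fixation index.

    These are the test units of the sequential duration comparison: one
    value per subject per index, averaged over that subject's trials that
    reach the index.
    """
    t = table
    if "is_start_cross" in t.columns:
        t = t[~t["is_start_cross"].astype(bool)]
    out = (t.groupby(["group", "subject_id", "fix_index"], observed=True)["duration_ms"]
           .agg(mean_duration_ms="mean", n_trials="size").reset_index())
    return out
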