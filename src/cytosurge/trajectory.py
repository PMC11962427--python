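"""Loess trajectories of the composite against time relative to diagnosis.

Locally weighted linear regression (tricube weights, degree 1) is evaluated
on a uniform grid of relative times, with a 95% percentile bootstrap CI that
resamples subjects (not samples) to respect within-subject correlation.
Surge onset is the earliest pre-diagnosis time from which the CI's lower
bound stays detached above the baseline mean all the way to diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import PanelTable

logger = logging.getLogger("cytosurge")


@dataclass
class TrajectoryFit:
    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    baseline_mean: float
    group_label: str = ""
    n_samples: int = 0
    n_subjects: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")


def _loess(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    return sm.nonparametric.lowess(y, x, frac=span, it=0, xvals=grid)


def fit_trajectory(
    rel_times,
    values,
    subjects,
    span: float = 0.4,
    bootstrap_reps: int = 200,
    seed: int = 0,
    grid_step: float = 0.25,
    baseline_values=None,
    group_label: str = "",
) -> TrajectoryFit:
    """Loess fit of ``values`` over ``rel_times`` with a subject bootstrap CI.

    ``baseline_values`` supplies the reference level (e.g. samples collected
    five or more years before diagnosis plus never-diagnosed subjects); when
    omitted, samples at rel_time <= -5 are used. The grid runs in
    ``grid_step`` steps over the observed relative-time range.
    """
    x = np.asarray(rel_times, dtype=float)
    y = np.asarray(values, dtype=float)
    subj = np.asarray(subjects)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, subj = x[keep], y[keep], subj[keep]
    if len(x) < 10 or len(np.unique(x)) < 3:
        raise ValueError("need >=10 points spanning >=3 distinct relative times")
    if span * len(x) < 3:
        raise ValueError(f"span too small for local windows; minimum span = {3 / len(x):.3f}")

    grid = np.arange(np.floor(x.min() / grid_step), np.ceil(x.max() / grid_step) + 1) * grid_step
    fitted = _loess(x, y, grid, span)

    if baseline_values is not None:
        baseline = float(np.nanmean(np.asarray(baseline_values, dtype=float)))
    else:
        pre = y[x <= -5.0]
        baseline = float(np.mean(pre)) if len(pre) else float("nan")

    rng = np.random.default_rng(seed)
    unique_subjects = np.unique(subj)
    by_subject = {s: np.flatnonzero(subj == s) for s in unique_subjects}
    boots = np.full((bootstrap_reps, len(grid)), np.nan)
    for b in range(bootstrap_reps):
        draw = rng.choice(unique_subjects, size=len(unique_subjects), replace=True)
        idx = np.concatenate([by_subject[s] for s in draw])
        xb, yb = x[idx], y[idx]
        if len(np.unique(xb)) < 3:
            continue
        boots[b] = _loess(xb, yb, grid, span)
    ci_low = np.nanpercentile(boots, 2.5, axis=0)
    ci_high = np.nanpercentile(boots, 97.5, axis=0)
    # percentile intervals can exclude the point fit on skewed resamples;
    # widen to preserve ci_low <= fitted <= ci_high
    ci_low = np.minimum(ci_low, fitted)
    ci_high = np.maximum(ci_high, fitted)
    return TrajectoryFit(
        grid=grid, fitted=fitted, ci_low=ci_low, ci_high=ci_high,
        baseline_mean=baseline, group_label=group_label,
        n_samples=len(x), n_subjects=len(unique_subjects),
    )


def detect_onset(fit: TrajectoryFit) -> float | None:
    """Earliest pre-diagnosis grid time from which the CI stays detached.

    Returns the smallest t* < 0 such that ci_low > baseline_mean at every
    grid point in [t*, 0]; None when the detachment does not persist up to
    diagnosis (or the baseline is undefined).
    """
    if not np.isfinite(fit.baseline_mean):
        return None
    mask = fit.grid <= 0
    if not mask.any():
        return None
    grid = fit.grid[mask]
    detached = fit.ci_low[mask] > fit.baseline_mean
    if not detached[-1]:
        return None
    i = len(detached) - 1
    while i > 0 and detached[i - 1]:
        i -= 1
    onset = float(grid[i])
    return onset if onset < 0 else None


def covariate_trajectory(
    rel_times, covariate_values, subjects, **kwargs
) -> TrajectoryFit:
    """Loess trajectory of a covariate (BMI, systolic BP, or one cytokine)."""
    return fit_trajectory(rel_times, covariate_values, subjects, **kwargs)


def cancer_trajectory_inputs(
    panel: PanelTable,
    scores: pd.DataFrame,
    events: pd.DataFrame,
    age_range: tuple[float, float] = (80.0, 200.0),
    values: pd.Series | None = None,
) -> dict:
    """Assemble trajectory inputs for the cancer-aligned age group.

    Samples of cancer-diagnosed subjects inside the age range are aligned to
    the subject's nearest cancer diagnosis; the baseline pool is samples at
    rel_time <= -5 plus samples of never-diagnosed subjects in the same age
    range. ``values`` defaults to the standardized composite.
    """
    from .events import align_to_events

    if values is None:
        values = scores.set_index("sample_id")["standardized"]
    aligned = align_to_events(panel, events, "cancer").set_index("sample_id")
    meta = panel.data.set_index("sample_id")
    in_age = (meta["age_at_sampling"] >= age_range[0]) & (meta["age_at_sampling"] < age_range[1])

    has_event = aligned["rel_time_years"].notna()
    traj_ids = meta.index[in_age & has_event & meta.index.isin(values.index)]
    rel = aligned.loc[traj_ids, "rel_time_years"]
    naive_ids = meta.index[in_age & ~has_event & meta.index.isin(values.index)]
    early_ids = traj_ids[rel <= -5.0]
    baseline_ids = naive_ids.union(early_ids)
    return dict(
        rel_times=rel.to_numpy(),
        values=values.loc[traj_ids].to_numpy(),
        subjects=meta.loc[traj_ids, "subject_id"].to_numpy(),
        baseline_values=values.loc[baseline_ids].to_numpy(),
        sample_ids=list(traj_ids),
    )


def subject_trajectory(
    panel: PanelTable,
    scores: pd.DataFrame,
    events: pd.DataFrame,
    subject_id: str,
    average_same_year: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordered (age, composite) series for one subject plus its event markers.

    With ``average_same_year`` duplicate same-year samples are averaged;
    otherwise both are kept (replicate verification).
    """
    meta = panel.data[panel.data["subject_id"] == subject_id]
    if not len(meta):
        raise KeyError(f"unknown subject {subject_id!r}")
    df = meta.merge(scores[["sample_id", "standardized"]], on="sample_id")
    df = df[["sample_id", "visit_date", "age_at_sampling", "standardized"]].sort_values(
        "age_at_sampling"
    )
    if average_same_year:
        df["year"] = pd.to_datetime(df["visit_date"]).dt.year
        df = (
            df.groupby("year", as_index=False)
            .agg(
                sample_id=("sample_id", "first"),
                visit_date=("visit_date", "first"),
                age_at_sampling=("age_at_sampling", "mean"),
                standardized=("standardized", "mean"),
            )
            .drop(columns=[], errors="ignore")
            .sort_values("age_at_sampling")
        )
    subject_events = events[events["subject_id"] == subject_id].copy()
    return df.reset_index(drop=True), subject_events.reset_index(drop=True)
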