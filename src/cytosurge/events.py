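"""Event-time alignment, diagnosis-window association, and variance attribution.

Samples are aligned to each subject's nearest same-category diagnosis and
flagged when they fall within the +/-2-year diagnosis window. Per-category
association compares the composite inside vs outside the window; variance
attribution quantifies how much of the old-age variability disappears when
cancer-window samples are removed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .composite import AgeBins, DEFAULT_AGE_BINS, variability_by_group
from .io import CANCER_CATEGORIES, DAYS_PER_YEAR, PanelTable

logger = logging.getLogger("cytosurge")


def _category_mask(categories: pd.Series, category: str) -> pd.Series:
    """Match an exact category, or the 'cancer' group covering all cancer_* codes."""
    if category == "cancer":
        return categories.isin(CANCER_CATEGORIES)
    return categories == category


def align_to_events(
    panel: PanelTable,
    events: pd.DataFrame,
    category: str,
    window_half_width: float = 2.0,
) -> pd.DataFrame:
    """Relative time of every sample to its subject's nearest event of a category.

    ``rel_time_years`` is (sample date - diagnosis date) / 365.25, negative
    before diagnosis. Ties between two equidistant events break toward the
    earlier event. Samples of subjects with no event in the category keep
    rel_time missing and in_window False.
    """
    ev = events[_category_mask(events["category"], category)]
    by_subject = {
        sid: np.sort(pd.to_datetime(g["diagnosis_date"]).to_numpy())
        for sid, g in ev.groupby("subject_id")
    }
    rel, nearest = [], []
    for sid, date in zip(panel.data["subject_id"], pd.to_datetime(panel.data["visit_date"])):
        dates = by_subject.get(sid)
        if dates is None or len(dates) == 0:
            rel.append(np.nan)
            nearest.append(pd.NaT)
            continue
        deltas = (date.to_datetime64() - dates) / np.timedelta64(1, "D") / DAYS_PER_YEAR
        order = np.lexsort((dates, np.abs(deltas)))  # nearest first, earlier wins ties
        best = order[0]
        rel.append(deltas[best])
        nearest.append(pd.Timestamp(dates[best]))
    out = pd.DataFrame(
        {
            "sample_id": panel.data["sample_id"],
            "category": category,
            "rel_time_years": rel,
            "nearest_event_date": nearest,
        }
    )
    out["in_window"] = out["rel_time_years"].abs() <= window_half_width
    out["in_window"] = out["in_window"].fillna(False)
    return out


def category_association(
    scores: pd.DataFrame,
    aligned: pd.DataFrame,
    min_in_window: int = 3,
    units: str = "subject",
    panel: PanelTable | None = None,
) -> dict:
    """Wilcoxon rank-sum of the composite: in-window vs out-of-window samples.

    The out-of-window pool is every sample not in-window for this category,
    including samples of never-diagnosed subjects. Repeated samples of one
    subject are correlated, so with ``units='subject'`` (default) the test
    runs on per-(subject, window-status) mean composites, which keeps the
    test calibrated under within-subject correlation; ``units='sample'``
    ranks raw samples. Reported n's are sample counts either way.
    """
    df = scores.merge(aligned[["sample_id", "in_window"]], on="sample_id")
    n_in = int(df["in_window"].sum())
    n_out = int((~df["in_window"]).sum())
    if n_in < min_in_window:
        raise ValueError(f"only {n_in} in-window samples; need >={min_in_window}")
    if units == "subject":
        if panel is None:
            raise ValueError("units='subject' requires the panel for subject IDs")
        df = df.merge(panel.data[["sample_id", "subject_id"]], on="sample_id")
        df = (
            df.groupby(["subject_id", "in_window"], as_index=False)["standardized"].mean()
        )
    elif units != "sample":
        raise ValueError(f"unknown units {units!r}")
    inside = df.loc[df["in_window"], "standardized"]
    outside = df.loc[~df["in_window"], "standardized"]
    if len(inside) < 2 or len(outside) < 2 or inside.nunique() + outside.nunique() < 2:
        raise ValueError("degenerate groups for the rank-sum test")
    stat, p = stats.mannwhitneyu(inside, outside, alternative="two-sided")
    return dict(
        category=str(aligned["category"].iloc[0]),
        n_in_window=n_in,
        n_out_window=n_out,
        median_difference=float(inside.median() - outside.median()),
        statistic=float(stat),
        p_value=float(p),
    )


def categories_association(
    scores: pd.DataFrame,
    panel: PanelTable,
    events: pd.DataFrame,
    categories=("cancer", "cardiovascular", "inflammatory", "other"),
    window_half_width: float = 2.0,
    min_in_window: int = 3,
    units: str = "subject",
) -> pd.DataFrame:
    """Run `category_association` across categories; skips underpowered ones."""
    rows = []
    for cat in categories:
        aligned = align_to_events(panel, events, cat, window_half_width)
        try:
            rows.append(category_association(scores, aligned, min_in_window, units, panel))
        except ValueError as exc:
            logger.info("skipping category %s: %s", cat, exc)
    return pd.DataFrame(rows)


def variance_attribution(
    scores: pd.DataFrame,
    panel: PanelTable,
    aligned_cancer: pd.DataFrame,
    age_bins: AgeBins = (("young", 0.0, 60.0), ("old", 60.0, 200.0)),
) -> dict:
    """Variance of the composite in the old bin, with vs without cancer-window samples.

    Recomputes the per-year variability records excluding in-window cancer
    samples and reports per-year SD deltas plus the composite attribution
    share (V_old_all - V_old_excluded) / (V_old_all - V_young_all), clipped
    to [0, 1]; NaN when the denominator is nonpositive.
    """
    young_label, old_label = age_bins[0][0], age_bins[-1][0]
    exclude = aligned_cancer.set_index("sample_id")["in_window"]

    from .composite import assign_age_bins

    merged = scores.merge(panel.data[["sample_id", "age_at_sampling"]], on="sample_id")
    merged["age_group"] = assign_age_bins(merged["age_at_sampling"], age_bins)
    keep = ~merged["sample_id"].map(exclude).fillna(False).astype(bool)
    old_all = merged.loc[merged["age_group"] == old_label, "standardized"]
    old_excl = merged.loc[(merged["age_group"] == old_label) & keep, "standardized"]
    young_all = merged.loc[merged["age_group"] == young_label, "standardized"]
    if len(old_excl) < 2:
        raise ValueError("all old-group samples fall in the cancer window")
    if len(old_all) < 2 or len(young_all) < 2:
        raise ValueError("both old and young bins must have >=2 samples")

    records_all = variability_by_group(scores, panel, age_bins)
    records_excluded = variability_by_group(scores, panel, age_bins, exclude=exclude)
    deltas = (
        records_all[records_all["age_group"] == old_label]
        .merge(
            records_excluded[records_excluded["age_group"] == old_label],
            on=["sampling_year", "age_group"],
            suffixes=("_all", "_excluded"),
        )
        .assign(sd_delta=lambda d: d["sd_all"] - d["sd_excluded"])
    )

    v_old, v_old_ex, v_young = old_all.var(ddof=1), old_excl.var(ddof=1), young_all.var(ddof=1)
    denom = v_old - v_young
    share = float(np.clip((v_old - v_old_ex) / denom, 0.0, 1.0)) if denom > 0 else np.nan
    return dict(
        records_all=records_all,
        records_excluded=records_excluded,
        per_year_deltas=deltas,
        variance_old_all=float(v_old),
        variance_old_excluded=float(v_old_ex),
        variance_young_all=float(v_young),
        attribution_share=share,
    )


def event_age_summary(events: pd.DataFrame, age_cutoff: float = 60.0) -> dict:
    """Share of recorded clinical events occurring in subjects above an age cutoff."""
    if "age_at_diagnosis" not in events.columns or not len(events):
        raise ValueError("event table needs age_at_diagnosis and at least one event")
    n_total = int(len(events))
    n_older = int((events["age_at_diagnosis"] > age_cutoff).sum())
    return dict(
        n_events=n_total,
        n_events_older=n_older,
        pct_older=100.0 * n_older / n_total,
    )
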