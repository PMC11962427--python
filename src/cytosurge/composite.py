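"""Composite serum cytokine abundance, outlier calling, and age-group variability.

The composite ("serum cytokine abundance") is the standardized geometric mean
of the panel's concentrations, computed per sample on the log scale. Outliers
are samples deviating from the robust population center at a configured FDR.
Variability summaries (SD and CV per sampling year and age group) quantify the
age-dependent spread of the composite and support the re-analysis that
excludes samples near a cancer diagnosis.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import PanelTable

logger = logging.getLogger("cytosurge")

#: (label, age_lo, age_hi) half-open bins. The default mirrors a two-arm
#: aging cohort: young adults, 60-79, and 80+.
AgeBins = Sequence[tuple[str, float, float]]
DEFAULT_AGE_BINS: AgeBins = (("young", 0.0, 40.0), ("old60", 60.0, 80.0), ("old80", 80.0, 200.0))


def assign_age_bins(ages: pd.Series, age_bins: AgeBins = DEFAULT_AGE_BINS) -> pd.Series:
    """Label ages by the first matching half-open [lo, hi) bin; others -> NaN."""
    out = pd.Series(pd.NA, index=ages.index, dtype=object)
    for label, lo, hi in age_bins:
        mask = (ages >= lo) & (ages < hi) & out.isna()
        out[mask] = label
    return out


def composite_score(
    panel: PanelTable,
    variant: str = "geomean_then_standardize",
    min_frac_observed: float = 0.5,
) -> pd.DataFrame:
    """Per-sample composite cytokine score.

    ``geomean_then_standardize`` (default): raw_geomean = exp(mean of log
    concentrations over observed cytokines); ``standardized`` is the z-score
    of log(raw_geomean) across all scored samples.

    ``per_cytokine_z_mean``: z-score each cytokine's log concentration across
    samples, average the z's per sample, and re-standardize.

    Samples with fewer than ``min_frac_observed`` of their cytokines observed
    and positive are excluded with a warning. Returns a frame with columns
    sample_id, raw_geomean, standardized, outlier_q, is_outlier.
    """
    conc = panel.concentrations()
    logs = np.log(conc.where(conc > 0))
    observed = logs.notna().sum(axis=1)
    ok = observed >= min_frac_observed * len(panel.cytokines)
    if (~ok).any():
        logger.warning("excluding %d samples with <%.0f%% observed cytokines",
                       int((~ok).sum()), 100 * min_frac_observed)
    logs = logs.loc[ok]

    raw_geomean = np.exp(logs.mean(axis=1, skipna=True))
    if variant == "geomean_then_standardize":
        base = np.log(raw_geomean)
    elif variant == "per_cytokine_z_mean":
        z = (logs - logs.mean(axis=0)) / logs.std(axis=0, ddof=1)
        base = z.mean(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown composite variant {variant!r}")
    standardized = (base - base.mean()) / base.std(ddof=1)

    return pd.DataFrame(
        {
            "sample_id": logs.index,
            "raw_geomean": raw_geomean.to_numpy(),
            "standardized": standardized.to_numpy(),
            "outlier_q": np.nan,
            "is_outlier": False,
        }
    ).reset_index(drop=True)


def detect_outliers(scores: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Flag composite outliers against a robust normal null at the given FDR.

    Center/scale come from the median and the normal-consistent MAD of the
    standardized composite; two-sided normal p-values are Benjamini-Hochberg
    corrected across samples. MAD = 0 falls back to the SD; both zero means
    no outliers (with a warning).
    """
    if len(scores) < 10:
        raise ValueError("outlier detection needs at least 10 samples")
    x = scores["standardized"].to_numpy(dtype=float)
    center = np.median(x)
    scale = stats.median_abs_deviation(x, scale="normal")
    if scale == 0:
        scale = np.std(x, ddof=1)
    out = scores.copy()
    if scale == 0:
        logger.warning("degenerate composite distribution; no outliers called")
        out["outlier_q"] = 1.0
        out["is_outlier"] = False
        return out
    p = 2.0 * stats.norm.sf(np.abs(x - center) / scale)
    out["outlier_q"] = bh_adjust(p)
    out["is_outlier"] = out["outlier_q"] < fdr
    return out


def variability_by_group(
    scores: pd.DataFrame,
    panel: PanelTable,
    age_bins: AgeBins = DEFAULT_AGE_BINS,
    exclude: pd.Series | None = None,
) -> pd.DataFrame:
    """SD and CV of the composite per (sampling year, age group).

    SD is taken on the standardized composite; CV on the raw geometric-mean
    scale (SD/mean). ``exclude`` is an optional boolean mask indexed by
    sample_id (True = drop), supporting the cancer-window exclusion
    re-analysis. Cells with fewer than two samples are omitted.
    """
    df = scores.merge(
        panel.data[["sample_id", "visit_date", "age_at_sampling"]], on="sample_id"
    )
    if exclude is not None:
        drop = df["sample_id"].map(exclude).fillna(False).astype(bool)
        df = df[~drop]
    df["sampling_year"] = pd.to_datetime(df["visit_date"]).dt.year
    df["age_group"] = assign_age_bins(df["age_at_sampling"], age_bins)
    df = df.dropna(subset=["age_group"])
    records = []
    for (year, group), g in df.groupby(["sampling_year", "age_group"], sort=True):
        if len(g) < 2:
            continue
        records.append(
            dict(
                sampling_year=int(year),
                age_group=group,
                sd=g["standardized"].std(ddof=1),
                cv=g["raw_geomean"].std(ddof=1) / g["raw_geomean"].mean(),
                n=len(g),
            )
        )
    return pd.DataFrame(records, columns=["sampling_year", "age_group", "sd", "cv", "n"])


def compare_group_variability(records_a: pd.DataFrame, records_b: pd.DataFrame) -> dict:
    """Paired Wilcoxon signed-rank test on per-year SDs of two age groups.

    Pairs on sampling_year; requires at least three shared years. Zeros are
    handled by the Pratt method; identical paired SDs give p = 1.
    """
    merged = records_a.merge(records_b, on="sampling_year", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} shared sampling years; need >=3 for the paired test"
        )
    diff = merged["sd_a"] - merged["sd_b"]
    if (diff == 0).all():
        return dict(statistic=np.nan, p_value=1.0, n_years=len(merged))
    res = stats.wilcoxon(merged["sd_a"], merged["sd_b"], zero_method="pratt", method="auto")
    return dict(statistic=float(res.statistic), p_value=float(res.pvalue), n_years=len(merged))


def per_cytokine_variance_trend(
    panel: PanelTable,
    age_bins: AgeBins = DEFAULT_AGE_BINS,
    exclude: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-cytokine test of variance increase with age plus a cancer-attribution share.

    For each cytokine the oldest and youngest bins are compared with a
    Levene-type rank test on absolute deviations from the bin medians of log
    concentration, BH-corrected across the panel. Because repeated samples
    of one subject share a baseline, deviations are averaged per subject
    first and the rank-sum runs on subject-level units, which keeps the
    null calibrated under within-subject correlation.
    ``attribution_share`` = (V_old_all - V_old_excluded) / (V_old_all -
    V_young_all), clipped to [0, 1], where V is the variance of log
    concentration and "excluded" drops the samples masked by ``exclude``
    (typically the cancer diagnosis window); undefined shares are NaN.
    """
    conc = panel.concentrations()
    logs = np.log(conc.where(conc > 0))
    meta = panel.data.set_index("sample_id")
    groups = assign_age_bins(meta["age_at_sampling"], age_bins)
    subjects = meta["subject_id"]
    young_label, old_label = age_bins[0][0], age_bins[-1][0]
    young_ids = groups.index[groups == young_label]
    old_ids = groups.index[groups == old_label]
    if exclude is not None:
        excl = exclude.reindex(logs.index).fillna(False).astype(bool)
    else:
        excl = pd.Series(False, index=logs.index)

    rows = []
    for cyt in panel.cytokines:
        y = logs.loc[young_ids, cyt].dropna()
        o = logs.loc[old_ids, cyt].dropna()
        o_ex = logs.loc[[i for i in old_ids if not excl[i]], cyt].dropna()
        if len(y) < 3 or len(o) < 3:
            continue
        dev_y = np.abs(y - y.median()).groupby(subjects).mean().dropna()
        dev_o = np.abs(o - o.median()).groupby(subjects).mean().dropna()
        stat, p = stats.mannwhitneyu(dev_o, dev_y, alternative="two-sided")
        v_y, v_o = y.var(ddof=1), o.var(ddof=1)
        v_o_ex = o_ex.var(ddof=1) if len(o_ex) >= 2 else np.nan
        denom = v_o - v_y
        share = np.nan
        if np.isfinite(v_o_ex) and denom > 0:
            share = float(np.clip((v_o - v_o_ex) / denom, 0.0, 1.0))
        rows.append(
            dict(cytokine=cyt, variance_young=v_y, variance_old=v_o,
                 variance_increase=v_o - v_y, p_value=p, attribution_share=share)
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] < fdr
    return out
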