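"""Lead-time binning and AUROC-based cancer prediction in the 80+ group.

Samples of the aged group are binned by sampling time relative to the next
cancer diagnosis; negatives are samples from cancer-naive subjects plus
samples drawn five or more years before a diagnosis, and post-diagnostic
samples are excluded. Each pre-diagnosis bin is compared to the negatives by
rank-sum test, and the composite score's discrimination is summarized as an
AUROC with a stratified percentile-bootstrap CI.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import CANCER_CATEGORIES, DAYS_PER_YEAR, PanelTable

logger = logging.getLogger("cytosurge")

#: pre-diagnosis bins, half-open toward diagnosis: (lo, hi] except the last,
#: (-1, 0), which is open at 0 because a same-day sample is post-diagnostic.
LEAD_TIME_BINS = [(-5.0, -4.0), (-4.0, -3.0), (-3.0, -2.0), (-2.0, -1.0), (-1.0, 0.0)]


def _bin_label(lo: float, hi: float) -> str:
    return f"({lo:g},{hi:g}]" if hi < 0 else f"({lo:g},{hi:g})"


def assign_lead_time(
    panel: PanelTable, events: pd.DataFrame, age_threshold: float = 80.0
) -> pd.DataFrame:
    """Label 80+ samples by lead time to the subject's first subsequent cancer diagnosis.

    Returns rows (sample_id, rel_time_years, bin, label) restricted to samples
    with age_at_sampling >= threshold. Labels: 'negative' (naive subjects, or
    rel_time <= -5), 'positive' (a pre-diagnosis bin), 'excluded'
    (post-diagnostic, rel_time >= 0).
    """
    cancers = events[events["category"].isin(CANCER_CATEGORIES)]
    dx_dates = {
        sid: np.sort(pd.to_datetime(g["diagnosis_date"]).to_numpy())
        for sid, g in cancers.groupby("subject_id")
    }
    meta = panel.data[panel.data["age_at_sampling"] >= age_threshold]
    rows = []
    for _, row in meta.iterrows():
        dates = dx_dates.get(row["subject_id"])
        if dates is None:
            rows.append(dict(sample_id=row["sample_id"], rel_time_years=np.nan,
                             bin="negative", label="negative"))
            continue
        sample_date = pd.to_datetime(row["visit_date"]).to_datetime64()
        first_dx = dates[0]
        rel = (sample_date - first_dx) / np.timedelta64(1, "D") / DAYS_PER_YEAR
        if rel >= 0:
            rows.append(dict(sample_id=row["sample_id"], rel_time_years=rel,
                             bin="post_dx", label="excluded"))
            continue
        if rel <= -5.0:
            rows.append(dict(sample_id=row["sample_id"], rel_time_years=rel,
                             bin="negative", label="negative"))
            continue
        for lo, hi in LEAD_TIME_BINS:
            if (lo < rel <= hi) or (hi == 0.0 and lo < rel < 0.0):
                rows.append(dict(sample_id=row["sample_id"], rel_time_years=rel,
                                 bin=_bin_label(lo, hi), label="positive"))
                break
    return pd.DataFrame(rows, columns=["sample_id", "rel_time_years", "bin", "label"])


def group_tests(scores: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of each pre-diagnosis bin vs the negative pool."""
    df = scores.merge(labels, on="sample_id")
    neg = df.loc[df["label"] == "negative", "standardized"]
    if not len(neg):
        raise ValueError("negative pool is empty")
    rows = []
    for lo, hi in LEAD_TIME_BINS:
        label = _bin_label(lo, hi)
        pos = df.loc[df["bin"] == label, "standardized"]
        if len(pos) < 2:
            logger.info("bin %s omitted (n=%d < 2)", label, len(pos))
            continue
        stat, p = stats.mannwhitneyu(pos, neg, alternative="two-sided")
        rows.append(dict(bin=label, n=len(pos), n_negative=len(neg),
                         median_difference=float(pos.median() - neg.median()),
                         statistic=float(stat), p_value=float(p)))
    return pd.DataFrame(rows)


def auroc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUROC with ties counted one half."""
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auroc_ci(
    scores,
    labels,
    reps: int = 1000,
    seed: int = 0,
) -> dict:
    """AUROC with a 95% percentile bootstrap CI stratified by label.

    ``labels`` is a boolean/int array (1 = positive). Bootstrap resamples
    positives and negatives separately so both classes survive every
    replicate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    point = auroc(s, y)
    pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for b in range(reps):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        vals[b] = roc_auc_score(y[idx], s[idx])
    return dict(
        auroc=point,
        ci_low=float(np.percentile(vals, 2.5)),
        ci_high=float(np.percentile(vals, 97.5)),
        n_positive=int(len(pos_idx)),
        n_negative=int(len(neg_idx)),
        reps=reps,
    )


def bin_auroc(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    bins: list[str] | None = None,
    reps: int = 1000,
    seed: int = 0,
    subject_level: bool = False,
    panel: PanelTable | None = None,
) -> dict:
    """AUROC of chosen positive bin(s) against the negative pool.

    ``bins`` defaults to every pre-diagnosis bin. ``subject_level`` collapses
    to one unit per subject (max composite), for the sensitivity check that
    one subject contributes several samples; it requires ``panel``.
    """
    df = scores.merge(labels, on="sample_id")
    if bins is None:
        pos_mask = df["label"] == "positive"
    else:
        pos_mask = df["bin"].isin(bins)
    neg_mask = df["label"] == "negative"
    sub = df[pos_mask | neg_mask].copy()
    sub["y"] = pos_mask[pos_mask | neg_mask].astype(int)
    if subject_level:
        if panel is None:
            raise ValueError("subject_level AUROC requires the panel for subject IDs")
        subj = panel.data.set_index("sample_id")["subject_id"]
        sub["subject_id"] = sub["sample_id"].map(subj)
        sub = (
            sub.groupby(["subject_id", "y"], as_index=False)["standardized"].max()
        )
    return auroc_ci(sub["standardized"].to_numpy(), sub["y"].to_numpy(), reps, seed)
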