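"""Pre-diagnostic inflamed/non-inflamed states and their age association.

Samples drawn in the window before a cancer diagnosis (post-diagnostic
samples excluded) are clustered on their per-cytokine profiles into two
states; the state with the higher mean composite is the inflamed one. The
age dependence of the inflamed state is quantified subject-wise as an odds
ratio with Fisher's exact test, and matched per-cytokine tests identify
which analytes rise before diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._stats import bh_adjust
from .io import CANCER_CATEGORIES, DAYS_PER_YEAR, PanelTable

logger = logging.getLogger("cytosurge")


def select_prediagnostic(
    panel: PanelTable, events: pd.DataFrame, window: float = 2.0
) -> pd.DataFrame:
    """Samples collected within ``window`` years strictly before a subject's
    first subsequent cancer diagnosis.

    A sample is kept when -window <= rel_time < 0 (closed at -window, open at
    0: a same-day sample is post-diagnostic). Samples at or after a subject's
    first cancer diagnosis are excluded. Returns the panel rows plus a
    ``rel_time_years`` column.
    """
    cancers = events[events["category"].isin(CANCER_CATEGORIES)]
    first_dx = cancers.groupby("subject_id")["diagnosis_date"].min()
    dx_dates = {
        sid: np.sort(pd.to_datetime(g["diagnosis_date"]).to_numpy())
        for sid, g in cancers.groupby("subject_id")
    }
    rows = []
    for idx, row in panel.data.iterrows():
        dates = dx_dates.get(row["subject_id"])
        if dates is None:
            continue
        sample_date = pd.to_datetime(row["visit_date"]).to_datetime64()
        if sample_date >= first_dx[row["subject_id"]].to_datetime64():
            continue
        upcoming = dates[dates > sample_date]
        if len(upcoming) == 0:
            continue
        rel = (sample_date - upcoming[0]) / np.timedelta64(1, "D") / DAYS_PER_YEAR
        if -window <= rel < 0:
            rows.append({**row.to_dict(), "rel_time_years": rel})
    return pd.DataFrame(rows, columns=[*panel.data.columns, "rel_time_years"])


def cluster_states(
    samples: pd.DataFrame,
    cytokines: list[str],
    linkage_method: str = "complete",
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Two-state agglomerative clustering of per-cytokine standardized profiles.

    Log concentrations are z-scored per cytokine across the given samples,
    clustered with Euclidean distance and the chosen linkage (complete by
    default; 'ward' available), and cut at k = 2. The cluster with the higher
    mean profile (mean of z's, the subset composite) is labelled inflamed.
    Cytokines are clustered the same way for the heatmap layout.

    Returns (assignments, sample_order, cytokine_order).
    """
    if len(samples) < 4:
        raise ValueError("state clustering needs at least 4 samples")
    conc = samples.set_index("sample_id")[cytokines].astype(float)
    logs = np.log(conc.where(conc > 0))
    z = (logs - logs.mean(axis=0)) / logs.std(axis=0, ddof=1)
    z = z.fillna(0.0)
    if np.allclose(pdist(z.to_numpy()), 0.0):
        raise ValueError("all samples identical; cannot define two states")

    link = hierarchy.linkage(z.to_numpy(), method=linkage_method, metric="euclidean")
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    composite = z.mean(axis=1)
    means = {lab: composite[labels == lab].mean() for lab in np.unique(labels)}
    inflamed_label = max(means, key=means.get)
    state = np.where(labels == inflamed_label, "inflamed", "noninflamed")

    # distance of each sample to its cluster centroid, for reporting
    dist = np.full(len(z), np.nan)
    for lab in np.unique(labels):
        mask = labels == lab
        centroid = z.to_numpy()[mask].mean(axis=0)
        dist[mask] = np.linalg.norm(z.to_numpy()[mask] - centroid, axis=1)

    assignments = pd.DataFrame(
        {
            "sample_id": z.index,
            "subject_id": samples.set_index("sample_id").loc[z.index, "subject_id"].to_numpy(),
            "state": state,
            "cluster_distance": dist,
        }
    ).reset_index(drop=True)
    sample_order = [z.index[i] for i in hierarchy.leaves_list(link)]
    cyt_link = hierarchy.linkage(z.to_numpy().T, method=linkage_method, metric="euclidean")
    cytokine_order = [cytokines[i] for i in hierarchy.leaves_list(cyt_link)]
    return assignments, sample_order, cytokine_order


@dataclass
class ContingencyResult:
    """2x2 age-by-state table: rows (80+, <80), columns (inflamed, noninflamed)."""

    table: np.ndarray
    odds_ratio: float
    fisher_p: float


def odds_ratio(table) -> float:
    """Cross-product odds ratio (a*d)/(b*c); infinite when b*c = 0."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def state_age_contingency(
    assignments: pd.DataFrame, ages: pd.Series, threshold: float = 80.0
) -> ContingencyResult:
    """Subject-level association between age group and the inflamed state.

    A subject is inflamed if any of its pre-diagnostic samples is inflamed;
    its age is the maximum sampling age over those samples. The table rows
    are (age >= threshold, age < threshold) and columns (inflamed,
    noninflamed); the odds ratio is the cross-product and p comes from
    Fisher's exact two-sided test.
    """
    df = assignments.copy()
    df["age"] = df["sample_id"].map(ages)
    subj = df.groupby("subject_id").agg(
        inflamed=("state", lambda s: (s == "inflamed").any()),
        age=("age", "max"),
    )
    old = subj["age"] >= threshold
    table = np.array(
        [
            [int((old & subj["inflamed"]).sum()), int((old & ~subj["inflamed"]).sum())],
            [int((~old & subj["inflamed"]).sum()), int((~old & ~subj["inflamed"]).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("contingency table has an empty margin; odds ratio undefined")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(table=table, odds_ratio=odds_ratio(table), fisher_p=float(p))


def age_correlation(
    values: pd.Series,
    ages: pd.Series,
    method: str = "spearman",
    exclude: pd.Series | None = None,
) -> dict:
    """Correlation between the composite and age within a sample group.

    Spearman by default (Pearson by flag). ``exclude`` optionally drops
    flagged outlier samples to check robustness of the correlation.
    """
    df = pd.DataFrame({"value": values, "age": ages}).dropna()
    if exclude is not None:
        df = df[~exclude.reindex(df.index).fillna(False).astype(bool)]
    if len(df) < 5:
        raise ValueError("need at least 5 points for the age correlation")
    if df["value"].nunique() < 2 or df["age"].nunique() < 2:
        return dict(rho=np.nan, p_value=np.nan, n=len(df), method=method)
    if method == "spearman":
        rho, p = stats.spearmanr(df["age"], df["value"])
    elif method == "pearson":
        rho, p = stats.pearsonr(df["age"], df["value"])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return dict(rho=float(rho), p_value=float(p), n=len(df), method=method)


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    age_tolerance: float = 5.0,
    k: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy 1:k nearest-age matching within (sex, sampling year) strata.

    Cases are visited in seeded-shuffle order; each claims its nearest-age
    unused controls from the naive pool within the same sex and calendar year
    and within ``age_tolerance`` years. Unmatched cases are dropped with a
    logged count. Returns rows (case_id, control_id).
    """
    rng = np.random.default_rng(seed)

    def keyed(df):
        out = df[["sample_id", "sex", "age_at_sampling"]].copy()
        out["year"] = pd.to_datetime(df["visit_date"]).dt.year
        return out

    cases_k, pool_k = keyed(cases), keyed(pool)
    order = rng.permutation(len(cases_k))
    used: set[str] = set()
    pairs = []
    n_unmatched = 0
    for i in order:
        case = cases_k.iloc[i]
        cand = pool_k[
            (pool_k["sex"] == case["sex"])
            & (pool_k["year"] == case["year"])
            & (~pool_k["sample_id"].isin(used))
            & ((pool_k["age_at_sampling"] - case["age_at_sampling"]).abs() <= age_tolerance)
        ]
        if len(cand) == 0:
            n_unmatched += 1
            continue
        chosen = cand.iloc[
            (cand["age_at_sampling"] - case["age_at_sampling"]).abs().argsort()[:k]
        ]
        for _, ctrl in chosen.iterrows():
            pairs.append(dict(case_id=case["sample_id"], control_id=ctrl["sample_id"]))
            used.add(ctrl["sample_id"])
    if n_unmatched:
        logger.info("dropped %d unmatched cases", n_unmatched)
    return pd.DataFrame(pairs, columns=["case_id", "control_id"])


def matched_cytokine_tests(
    panel: PanelTable,
    case_ids,
    naive_pool_ids,
    age_tolerance: float = 5.0,
    k: int = 1,
    seed: int = 0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-cytokine paired tests of pre-diagnostic cases vs matched naive controls.

    Matching is greedy nearest-age within sex and sampling-year strata. Each
    cytokine gets a Wilcoxon signed-rank test (Pratt zero handling) on the
    paired log-concentration differences, BH-corrected across the panel.
    """
    data = panel.data.set_index("sample_id")
    cases = data.loc[list(case_ids)].reset_index()
    pool = data.loc[list(naive_pool_ids)].reset_index()
    pairs = match_controls(cases, pool, age_tolerance, k, seed)
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched pairs; need >=3")
    case_logs = np.log(data.loc[pairs["case_id"], panel.cytokines].to_numpy(dtype=float))
    ctrl_logs = np.log(data.loc[pairs["control_id"], panel.cytokines].to_numpy(dtype=float))
    diffs = case_logs - ctrl_logs
    rows = []
    for j, cyt in enumerate(panel.cytokines):
        d = diffs[:, j]
        d = d[np.isfinite(d)]
        if len(d) < 3:
            continue
        if np.all(d == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(d, zero_method="pratt", method="auto").pvalue)
        rows.append(dict(cytokine=cyt, n_pairs=len(d), median_log_diff=float(np.median(d)), p_value=p))
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < fdr
    return out


def prediagnostic_naive_pool(panel: PanelTable, events: pd.DataFrame) -> pd.DataFrame:
    """Samples of subjects with no cancer event on record (cancer-naive pool)."""
    cancer_subjects = set(
        events.loc[events["category"].isin(CANCER_CATEGORIES), "subject_id"]
    )
    return panel.data[~panel.data["subject_id"].isin(cancer_subjects)].copy()
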