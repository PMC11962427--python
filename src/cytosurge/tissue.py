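"""Tissue-expression arm: cytokine gene-set scoring and age meta-analysis.

Per-sample tissue cytokine abundance is the mean log2(TPM + 1) over the
cytokine gene set. Within each cancer type, the 80+ vs <80 contrast is a
regression-adjusted standardized difference (age-group coefficient divided
by the residual SD; reduces to Cohen's d without confounders), pooled across
types by fixed-effect inverse-variance weighting. The CDKN1A association is
meta-analysed on the Fisher-z scale; gene-set enrichment is a competitive
rank test on per-gene standardized differences; the 5-year age-bin analysis
contrasts each bin with the under-60 reference to expose the nonlinear age
dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import bh_adjust
from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger("cytosurge")


@dataclass
class EffectEstimate:
    """Standardized difference for one stratum, with its 95% normal CI."""

    stratum: str
    estimate: float
    se: float
    n_old: int
    n_young: int

    @property
    def ci_low(self) -> float:
        return self.estimate - 1.96 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + 1.96 * self.se


@dataclass
class MetaResult:
    """Inverse-variance pooled effect with heterogeneity."""

    pooled: float
    se: float
    p: float
    heterogeneity_q: float
    n_strata: int

    @property
    def ci_low(self) -> float:
        return self.pooled - 1.96 * self.se

    @property
    def ci_high(self) -> float:
        return self.pooled + 1.96 * self.se


def log2_tpm(expr: ExpressionMatrix) -> pd.DataFrame:
    """log2(abundance + 1), genes x samples."""
    return np.log2(expr.values.astype(float) + 1.0)


def tissue_abundance(expr: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Per-sample mean of log2(TPM + 1) over the set genes present in the matrix.

    Genes missing from the matrix are dropped with a logged list; an entirely
    absent set is an error.
    """
    present = [g for g in gene_set.genes if g in expr.values.index]
    missing = [g for g in gene_set.genes if g not in expr.values.index]
    if missing:
        logger.info("gene set %s: %d genes absent from matrix: %s",
                    gene_set.name, len(missing), missing[:10])
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    score = log2_tpm(expr).loc[present].mean(axis=0)
    score.name = f"{gene_set.name}_abundance"
    return score


def stage_filter(expr: ExpressionMatrix, stages=(1, 2)) -> ExpressionMatrix:
    """Keep early-stage (default stage 1-2, local disease) samples."""
    if "stage" not in expr.annotations.columns:
        raise ValueError("annotations lack a 'stage' column")
    keep = expr.annotations.index[expr.annotations["stage"].isin(stages)]
    if not len(keep):
        logger.warning("stage filter removed every sample")
    return ExpressionMatrix(expr.values[list(keep)], expr.annotations.loc[list(keep)])


def type_inclusion(expr: ExpressionMatrix, min_old: int = 10, age_threshold: float = 80.0) -> list[str]:
    """Cancer types with strictly more than ``min_old`` samples at age >= threshold."""
    ann = expr.annotations
    counts = ann[ann["age"] >= age_threshold].groupby("cancer_type").size()
    return sorted(t for t, n in counts.items() if n > min_old)


def adjusted_effect(
    scores: pd.Series,
    annotations: pd.DataFrame,
    stratum: str,
    confounders: tuple[str, ...] = ("sex",),
    age_threshold: float = 80.0,
    group_mask: pd.Series | None = None,
) -> EffectEstimate:
    """Regression-adjusted standardized difference within one cancer type.

    Fits score ~ group + confounders by OLS; the estimate is the group
    coefficient divided by the residual SD, with the SE propagated on the
    same scale. ``group_mask`` overrides the default 80+ vs <80 contrast
    (True = comparison group). Confounders collinear with the group or
    constant are dropped with a warning.
    """
    ann = annotations[annotations["cancer_type"] == stratum]
    y = scores.reindex(ann.index).astype(float)
    group = (
        group_mask.reindex(ann.index).astype(float)
        if group_mask is not None
        else (ann["age"] >= age_threshold).astype(float)
    )
    keep = y.notna() & group.notna()
    y, group, ann = y[keep], group[keep], ann[keep]
    n_old, n_young = int(group.sum()), int((1 - group).sum())
    if n_old == 0 or n_young == 0:
        raise ValueError(f"stratum {stratum!r}: both groups must be nonempty")

    X = pd.DataFrame({"group": group})
    for conf in confounders:
        dummies = pd.get_dummies(ann[conf], prefix=conf, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X)
    # drop collinear / constant columns (keep const and group)
    keep_cols = ["const", "group"]
    for col in X.columns:
        if col in keep_cols:
            continue
        trial = X[keep_cols + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) == trial.shape[1] and X[col].nunique() > 1:
            keep_cols.append(col)
        else:
            logger.warning("dropping collinear/constant confounder column %r in %s", col, stratum)
    fit = sm.OLS(y.to_numpy(), X[keep_cols].to_numpy()).fit()
    resid_sd = float(np.sqrt(fit.mse_resid))
    if resid_sd == 0:
        raise ValueError(f"stratum {stratum!r}: zero residual variance")
    j = keep_cols.index("group")
    return EffectEstimate(
        stratum=stratum,
        estimate=float(fit.params[j] / resid_sd),
        se=float(fit.bse[j] / resid_sd),
        n_old=n_old,
        n_young=n_young,
    )


def pool_effects(effects: list[EffectEstimate], random_effects: bool = False) -> MetaResult:
    """Inverse-variance pooled standardized difference across strata.

    Fixed-effect by default; ``random_effects`` switches to
    DerSimonian-Laird. Reports Cochran's Q and a two-sided normal p.
    """
    if not effects:
        raise ValueError("need at least one stratum to pool")
    est = np.array([e.estimate for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("every stratum SE must be positive")
    w = 1.0 / se**2
    pooled_fe = float(np.sum(w * est) / np.sum(w))
    q = float(np.sum(w * (est - pooled_fe) ** 2))
    k = len(effects)
    if random_effects and k > 1:
        tau2 = max(0.0, (q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        w = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(w * est) / np.sum(w))
    else:
        pooled = pooled_fe
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult(pooled=pooled, se=pooled_se, p=p, heterogeneity_q=q, n_strata=k)


def correlation_meta(
    expr: ExpressionMatrix,
    gene: str,
    scores: pd.Series,
    max_age: float | None = None,
) -> MetaResult:
    """Pooled per-type Spearman correlation between one gene and the tissue score.

    Correlations are computed on log2(TPM + 1) within each cancer type,
    Fisher-z transformed (SE = 1/sqrt(n - 3)), inverse-variance pooled, and
    reported back on the correlation scale. ``max_age`` optionally restricts
    to younger patients (e.g. < 80) to check age independence. Strata with
    n < 4 are dropped with a warning.
    """
    if gene not in expr.values.index:
        raise ValueError(f"gene {gene!r} not present in the matrix")
    gene_vals = log2_tpm(expr).loc[gene]
    ann = expr.annotations
    effects = []
    for ctype, g in ann.groupby("cancer_type"):
        idx = g.index
        if max_age is not None:
            idx = idx[g["age"] < max_age]
        x = gene_vals.reindex(idx).astype(float)
        y = scores.reindex(idx).astype(float)
        keep = x.notna() & y.notna()
        n = int(keep.sum())
        if n < 4:
            logger.warning("dropping stratum %s with n=%d < 4", ctype, n)
            continue
        r, _ = stats.spearmanr(x[keep], y[keep])
        r = float(np.clip(r, -0.999999, 0.999999))
        effects.append(EffectEstimate(ctype, float(np.arctanh(r)), 1.0 / np.sqrt(n - 3), n, n))
    meta_z = pool_effects(effects)
    return MetaResult(
        pooled=float(np.tanh(meta_z.pooled)),
        se=meta_z.se,  # on the Fisher-z scale
        p=meta_z.p,
        heterogeneity_q=meta_z.heterogeneity_q,
        n_strata=meta_z.n_strata,
    )


def correlation_meta_ci(meta: MetaResult) -> tuple[float, float]:
    """Back-transformed 95% CI of a Fisher-z pooled correlation, within (-1, 1)."""
    z = np.arctanh(meta.pooled)
    return float(np.tanh(z - 1.96 * meta.se)), float(np.tanh(z + 1.96 * meta.se))


def per_gene_effects(
    expr: ExpressionMatrix,
    genes: list[str],
    confounders: tuple[str, ...] = ("sex",),
    age_threshold: float = 80.0,
) -> pd.DataFrame:
    """Adjusted 80+ vs <80 effect, pooled across cancer types, per gene.

    Returns one row per requested gene present in the matrix with the pooled
    standardized difference, CI, and p.
    """
    logs = log2_tpm(expr)
    ann = expr.annotations
    rows = []
    for gene in genes:
        if gene not in logs.index:
            continue
        effects = []
        for ctype in sorted(ann["cancer_type"].unique()):
            try:
                effects.append(
                    adjusted_effect(logs.loc[gene], ann, ctype, confounders, age_threshold)
                )
            except ValueError:
                continue
        if not effects:
            continue
        meta = pool_effects(effects)
        rows.append(
            dict(gene=gene, pooled=meta.pooled, se=meta.se, ci_low=meta.ci_low,
                 ci_high=meta.ci_high, p_value=meta.p, n_strata=meta.n_strata)
        )
    return pd.DataFrame(rows)


def gene_set_enrichment(gene_stats: pd.Series, sets: list[GeneSet], fdr: float = 0.05) -> pd.DataFrame:
    """Competitive enrichment of gene sets over per-gene standardized differences.

    Each set with >=3 present genes gets a two-sided Wilcoxon rank-sum test of
    in-set vs out-of-set statistics, signed by the median difference, with BH
    correction across sets.
    """
    stats_clean = gene_stats.dropna()
    rows = []
    for gs in sets:
        in_set = stats_clean[stats_clean.index.isin(gs.genes)]
        out_set = stats_clean[~stats_clean.index.isin(gs.genes)]
        if len(in_set) < 3:
            logger.warning("skipping set %s with %d present genes", gs.name, len(in_set))
            continue
        stat, p = stats.mannwhitneyu(in_set, out_set, alternative="two-sided")
        rows.append(
            dict(
                set_name=gs.name,
                n_genes=len(in_set),
                direction=float(np.sign(in_set.median() - out_set.median())),
                statistic=float(stat),
                p_value=float(p),
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] < fdr
    return out


def age_bin_analysis(
    scores: pd.Series,
    annotations: pd.DataFrame,
    bin_width: float = 5.0,
    age_min: float = 60.0,
    age_max: float = 85.0,
    reference_max: float = 60.0,
    confounders: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Each 5-year age bin vs the under-60 reference, pooled across cancer types.

    Bins run [60,65), [65,70), ... with a final open-ended [age_max, inf) bin.
    Returns one row per populated bin with the pooled standardized difference
    and CI; a nonlinear (threshold) age dependence appears as CIs excluding
    zero only in the oldest bins.
    """
    ann = annotations
    ref_mask = ann["age"] < reference_max
    if not ref_mask.any():
        raise ValueError("reference bin (age < reference_max) is empty")
    edges = list(np.arange(age_min, age_max + 1e-9, bin_width)) + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"{lo:.0f}-{hi:.0f}" if np.isfinite(hi) else f"{lo:.0f}+"
        bin_mask = (ann["age"] >= lo) & (ann["age"] < hi)
        if not bin_mask.any():
            continue
        effects = []
        for ctype in sorted(ann["cancer_type"].unique()):
            sub_mask = (bin_mask | ref_mask) & (ann["cancer_type"] == ctype)
            if bin_mask[sub_mask].sum() == 0 or ref_mask[sub_mask].sum() == 0:
                continue
            sub_ann = ann[sub_mask]
            try:
                effects.append(
                    adjusted_effect(
                        scores.reindex(sub_ann.index),
                        sub_ann,
                        ctype,
                        confounders,
                        group_mask=bin_mask[sub_mask],
                    )
                )
            except ValueError:
                continue
        if not effects:
            continue
        meta = pool_effects(effects)
        rows.append(
            dict(age_bin=label, bin_low=lo, pooled=meta.pooled, se=meta.se,
                 ci_low=meta.ci_low, ci_high=meta.ci_high, p_value=meta.p,
                 n_strata=meta.n_strata,
                 n_bin=int(bin_mask.sum()))
        )
    return pd.DataFrame(rows)
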