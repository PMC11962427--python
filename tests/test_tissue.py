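"""Tissue scoring, adjusted effects, meta-pooling, enrichment, age bins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytosurge as cs
from cytosurge.io import ExpressionMatrix, GeneSet
from cytosurge.tissue import EffectEstimate, correlation_meta_ci, log2_tpm, stage_filter


def _toy_expr(seed=0, n=40):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(10)]
    vals = pd.DataFrame(
        rng.uniform(0, 100, (10, n)), index=genes, columns=[f"t{i}" for i in range(n)]
    )
    ann = pd.DataFrame(
        {
            "age": rng.uniform(50, 90, n),
            "sex": rng.choice(["F", "M"], n),
            "cancer_type": rng.choice(["A", "B"], n),
            "stage": rng.choice([1, 2, 3], n),
        },
        index=vals.columns,
    )
    return ExpressionMatrix(vals, ann)


class TestAbundance:
    def test_single_gene_set(self):
        expr = _toy_expr()
        score = cs.tissue_abundance(expr, GeneSet("one", "", ("G3",)))
        assert np.allclose(score, np.log2(expr.values.loc["G3"] + 1.0))

    def test_equal_genes_score_is_common_value(self):
        vals = pd.DataFrame(
            [[7.0, 15.0]] * 3, index=["A", "B", "C"], columns=["s1", "s2"]
        )
        ann = pd.DataFrame(
            {"age": [70, 85], "sex": ["F", "M"], "cancer_type": ["X", "X"], "stage": [1, 1]},
            index=["s1", "s2"],
        )
        score = cs.tissue_abundance(ExpressionMatrix(vals, ann), GeneSet("s", "", ("A", "B", "C")))
        assert score["s1"] == pytest.approx(np.log2(8.0))
        assert score["s2"] == pytest.approx(np.log2(16.0))

    def test_matches_bruteforce_mean_of_logs(self):
        expr = _toy_expr(seed=3)
        gs = GeneSet("ten", "", tuple(expr.values.index))
        score = cs.tissue_abundance(expr, gs)
        oracle = np.log2(expr.values + 1.0).mean(axis=0)
        assert np.allclose(score, oracle, atol=1e-12)

    def test_gene_order_and_absent_gene_invariance(self):
        expr = _toy_expr(seed=4)
        a = cs.tissue_abundance(expr, GeneSet("s", "", ("G1", "G2", "G3")))
        b = cs.tissue_abundance(expr, GeneSet("s", "", ("G3", "G1", "G2", "NOT_THERE")))
        assert np.allclose(a, b)

    def test_fully_absent_set_errors(self):
        with pytest.raises(ValueError, match="no gene"):
            cs.tissue_abundance(_toy_expr(), GeneSet("s", "", ("ZZZ",)))


class TestStageAndInclusion:
    def test_stage_filter_counts_and_idempotence(self):
        expr = _toy_expr(seed=5, n=100)
        early = stage_filter(expr)
        assert early.n_samples == int(expr.annotations["stage"].isin([1, 2]).sum())
        twice = stage_filter(early)
        assert list(twice.values.columns) == list(early.values.columns)

    def test_all_late_empty(self):
        expr = _toy_expr(seed=6)
        expr.annotations["stage"] = 4
        assert stage_filter(expr).n_samples == 0

    @pytest.mark.parametrize("n_old,kept", [(11, True), (10, False)])
    def test_inclusion_boundary_strictly_greater(self, n_old, kept):
        n = n_old + 5
        vals = pd.DataFrame(
            np.ones((2, n)), index=["G0", "G1"], columns=[f"s{i}" for i in range(n)]
        )
        ann = pd.DataFrame(
            {
                "age": [85.0] * n_old + [50.0] * 5,
                "sex": "F",
                "cancer_type": "T1",
                "stage": 1,
            },
            index=vals.columns,
        )
        types = cs.type_inclusion(ExpressionMatrix(vals, ann))
        assert ("T1" in types) is kept

    def test_default_scenario_all_types_kept(self, default_tissue):
        expr, _, _ = default_tissue
        assert cs.type_inclusion(expr) == sorted(expr.annotations["cancer_type"].unique())


class TestAdjustedEffect:
    def test_reduces_to_cohens_d_without_confounders(self):
        rng = np.random.default_rng(7)
        n1, n2 = 30, 50
        score = pd.Series(
            np.r_[rng.normal(1.0, 1.0, n1), rng.normal(0.0, 1.0, n2)],
            index=[f"s{i}" for i in range(n1 + n2)],
        )
        ann = pd.DataFrame(
            {
                "age": [85.0] * n1 + [60.0] * n2,
                "sex": "F",
                "cancer_type": "T",
                "stage": 1,
            },
            index=score.index,
        )
        est = cs.adjusted_effect(score, ann, "T", confounders=())
        m1, m2 = score[:n1].mean(), score[n1:].mean()
        sp = np.sqrt(
            ((n1 - 1) * score[:n1].var(ddof=1) + (n2 - 1) * score[n1:].var(ddof=1))
            / (n1 + n2 - 2)
        )
        assert est.estimate == pytest.approx((m1 - m2) / sp, abs=1e-6)

    def test_injected_effect_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            score = pd.Series(
                np.r_[rng.normal(0.5, 1.0, 200), rng.normal(0.0, 1.0, 200)],
                index=[f"s{i}" for i in range(400)],
            )
            ann = pd.DataFrame(
                {"age": [85.0] * 200 + [60.0] * 200, "sex": rng.choice(["F", "M"], 400),
                 "cancer_type": "T", "stage": 1},
                index=score.index,
            )
            est = cs.adjusted_effect(score, ann, "T")
            hits += abs(est.estimate - 0.5) <= 0.2
        assert hits >= 9

    def test_collinear_confounder_dropped(self):
        score = pd.Series(np.r_[np.random.default_rng(0).normal(size=20)],
                          index=[f"s{i}" for i in range(20)])
        ann = pd.DataFrame(
            {"age": [85.0] * 10 + [60.0] * 10,
             "sex": ["F"] * 10 + ["M"] * 10,  # perfectly aligned with group
             "cancer_type": "T", "stage": 1},
            index=score.index,
        )
        est = cs.adjusted_effect(score, ann, "T")  # must not raise
        assert est.se > 0

    def test_empty_group_refused(self):
        score = pd.Series(np.ones(5), index=[f"s{i}" for i in range(5)])
        ann = pd.DataFrame(
            {"age": 60.0, "sex": "F", "cancer_type": "T", "stage": 1}, index=score.index
        )
        with pytest.raises(ValueError, match="nonempty"):
            cs.adjusted_effect(score, ann, "T")


class TestPooling:
    def test_single_stratum_identity(self):
        e = EffectEstimate("A", 0.4, 0.1, 10, 10)
        meta = cs.pool_effects([e])
        assert meta.pooled == pytest.approx(0.4)
        assert meta.se == pytest.approx(0.1)

    def test_equal_se_gives_arithmetic_mean(self):
        effs = [EffectEstimate(s, v, 0.2, 5, 5) for s, v in [("A", 0.1), ("B", 0.5)]]
        assert cs.pool_effects(effs).pooled == pytest.approx(0.3)

    def test_matches_bruteforce_weights(self):
        rng = np.random.default_rng(8)
        effs = [
            EffectEstimate(f"S{i}", rng.normal(), rng.uniform(0.05, 0.5), 5, 5)
            for i in range(7)
        ]
        meta = cs.pool_effects(effs)
        w = np.array([1 / e.se**2 for e in effs])
        e = np.array([e.estimate for e in effs])
        assert meta.pooled == pytest.approx(np.sum(w * e) / np.sum(w), abs=1e-12)
        assert meta.se == pytest.approx(np.sqrt(1 / np.sum(w)), abs=1e-12)
        assert min(e) <= meta.pooled <= max(e)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cs.pool_effects([EffectEstimate("A", 0.1, 0.0, 5, 5)])

    def test_random_effects_widens_under_heterogeneity(self):
        effs = [EffectEstimate(s, v, 0.1, 5, 5) for s, v in [("A", -0.6), ("B", 0.9)]]
        fe = cs.pool_effects(effs)
        re = cs.pool_effects(effs, random_effects=True)
        assert re.se > fe.se


class TestCorrelationMeta:
    def test_single_stratum_equals_spearman(self):
        expr, sets, _ = cs.simulate_tissue(
            n_per_type={"A": {"<60": 60}, "B": {"<60": 3}}, seed=1, cdkn1a_coupling=0.4
        )
        score = cs.tissue_abundance(expr, sets[0])
        meta = cs.correlation_meta(expr, "CDKN1A", score)  # B dropped (n=3)
        assert meta.n_strata == 1
        idx = expr.annotations.index[expr.annotations["cancer_type"] == "A"]
        r, _ = stats.spearmanr(log2_tpm(expr).loc["CDKN1A", idx], score[idx])
        assert meta.pooled == pytest.approx(r, abs=1e-9)

    def test_null_coupling_ci_covers_zero(self):
        covered = 0
        for seed in range(15):
            expr, sets, _ = cs.simulate_tissue(seed=seed, cdkn1a_coupling=0.0,
                                               effect_80plus=0.0)
            score = cs.tissue_abundance(expr, sets[0])
            meta = cs.correlation_meta(expr, "CDKN1A", score)
            lo, hi = correlation_meta_ci(meta)
            covered += lo <= 0.0 <= hi
        assert covered >= 12

    def test_backtransform_stays_in_unit_interval(self):
        expr, sets, _ = cs.simulate_tissue(seed=2, cdkn1a_coupling=0.9)
        score = cs.tissue_abundance(expr, sets[0])
        meta = cs.correlation_meta(expr, "CDKN1A", score)
        lo, hi = correlation_meta_ci(meta)
        assert -1.0 < lo < hi < 1.0

    def test_under80_restriction_preserves_coupling(self):
        expr, sets, _ = cs.simulate_tissue(seed=3, cdkn1a_coupling=0.5)
        score = cs.tissue_abundance(expr, sets[0])
        meta = cs.correlation_meta(expr, "CDKN1A", score, max_age=80.0)
        assert meta.pooled > 0.3


class TestPerGeneAndEnrichment:
    def test_per_gene_effects_structure_and_recovery(self, default_tissue):
        expr, sets, truth = default_tissue
        genes = list(sets[0].genes)[:5] + ["DECOY001", "DECOY002", "ABSENT"]
        res = cs.per_gene_effects(expr, genes)
        assert len(res) == 7  # one row per present requested gene
        injected = res[res["gene"].isin(sets[0].genes)]
        assert (injected["pooled"] > 0).mean() >= 0.8

    def test_decoy_gene_ci_covers_zero(self):
        covered = 0
        for seed in range(10):
            expr, sets, _ = cs.simulate_tissue(seed=seed)
            res = cs.per_gene_effects(expr, ["DECOY001"]).iloc[0]
            covered += res["ci_low"] <= 0.0 <= res["ci_high"]
        assert covered >= 8

    def test_enrichment_statistic_matches_bruteforce(self):
        stats_in = pd.Series(
            {**{f"A{i}": v for i, v in enumerate([2.0, 1.5, 1.8])},
             **{f"B{i}": v for i, v in enumerate([0.1, -0.2, 0.05, 0.3, -0.1, 0.2, 0.0])}}
        )
        sets = [GeneSet("hot", "", ("A0", "A1", "A2"))]
        res = cs.gene_set_enrichment(stats_in, sets)
        u, p = stats.mannwhitneyu(
            stats_in[["A0", "A1", "A2"]],
            stats_in[[f"B{i}" for i in range(7)]],
            alternative="two-sided",
        )
        assert res["statistic"].iloc[0] == pytest.approx(u)
        assert res["p_value"].iloc[0] == pytest.approx(p, abs=1e-12)
        assert res["direction"].iloc[0] == 1.0

    def test_planted_set_enriched_decoys_not(self, default_tissue):
        expr, sets, _ = default_tissue
        res = cs.per_gene_effects(expr, list(expr.values.index))
        gene_stats = res.set_index("gene")["pooled"]
        enr = cs.gene_set_enrichment(gene_stats, sets).set_index("set_name")
        assert enr.loc["CYTOKINE_SURGE", "q_value"] < 0.05
        assert enr.loc["CYTOKINE_SURGE", "direction"] == 1.0
        # decoys cannot be positively enriched; in a competitive test they may
        # rank significantly below a background that contains the planted genes
        decoys = enr.drop(index="CYTOKINE_SURGE")
        assert not ((decoys["direction"] == 1.0) & (decoys["q_value"] < 0.05)).any()

    def test_small_set_skipped(self):
        gene_stats = pd.Series({"X": 0.1, "Y": 0.2, "Z": 0.3, "W": 0.4})
        res = cs.gene_set_enrichment(gene_stats, [GeneSet("tiny", "", ("X",))])
        assert len(res) == 0

    def test_permuted_labels_uniform_p(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(40):
            gene_stats = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
            chosen = tuple(rng.choice(gene_stats.index, 10, replace=False))
            ps.append(
                cs.gene_set_enrichment(gene_stats, [GeneSet("r", "", chosen)])["p_value"].iloc[0]
            )
        # Kolmogorov-Smirnov against uniform
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestAgeBins:
    def test_reference_vs_itself_zero(self):
        rng = np.random.default_rng(10)
        n = 120
        score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        ann = pd.DataFrame(
            {"age": rng.uniform(40, 59, n), "sex": "F", "cancer_type": "T", "stage": 1},
            index=score.index,
        )
        res = cs.age_bin_analysis(score, ann)
        assert len(res) == 0  # no samples above 60: no bins to contrast

    def test_threshold_scenario_bins(self, default_tissue):
        expr, sets, _ = default_tissue
        score = cs.tissue_abundance(expr, sets[0])
        res = cs.age_bin_analysis(score, expr.annotations).set_index("age_bin")
        assert res.loc["80-85", "ci_low"] > 0
        assert res.loc["85+", "ci_low"] > 0

    def test_linear_scenario_mean_estimates_monotone(self):
        mats = []
        for seed in range(8):
            expr, sets, _ = cs.simulate_tissue(seed=seed, age_effect_shape="linear")
            score = cs.tissue_abundance(expr, sets[0])
            mats.append(cs.age_bin_analysis(score, expr.annotations)["pooled"].to_numpy())
        mean_est = np.mean(mats, axis=0)
        assert (np.diff(mean_est) > 0).all()
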