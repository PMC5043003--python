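"""Decision-tree classical testing: assumption gates, ANOVA/Dunnett,
nonparametric branch, and the single-method batteries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cagestat.classical_analysis import (
    F_CAP,
    anova_from_summary,
    classical_batch,
    classical_flags,
    decision_tree_analyze,
    dunnett_max_t_cdf,
    dunnett_test,
    kruskal_wallis,
    levene_test,
    lilliefors_normality,
    lilliefors_statistic,
    one_way_anova,
    posthoc_t,
    run_single_method,
    wilcoxon_ranksum,
)
from cagestat.errors import DomainError
from cagestat.trial_model import TrialDesign


def _cell(groups: dict[str, list[float]], kind: str = "quantitative") -> pd.DataFrame:
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append(("male", g, f"{g}-{i}", "endpoint", 12, v, kind))
    return pd.DataFrame(
        rows, columns=["gender", "group", "cage_id", "endpoint", "time", "value", "kind"]
    )


class TestLilliefors:
    def test_statistic_affine_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 2, 30)
        assert lilliefors_statistic(x) == pytest.approx(
            lilliefors_statistic(5 * x - 11), abs=1e-12
        )

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        rej = np.mean(
            [lilliefors_normality(rng.standard_normal(20)).p_value < 0.05
             for _ in range(1000)]
        )
        assert rej == pytest.approx(0.05, abs=0.02)

    def test_rejects_uniform(self):
        # normal fit to uniform data is asymptotically inconsistent
        rng = np.random.default_rng(1)
        assert lilliefors_normality(rng.uniform(0, 1, 500)).p_value < 0.01
        ps200 = [lilliefors_normality(rng.uniform(0, 1, 200)).p_value for _ in range(50)]
        assert np.median(ps200) < 0.05

    def test_agrees_with_table_based_implementation(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        rng = np.random.default_rng(2)
        for n in (20, 50):
            x = rng.normal(0, 1, n) + rng.uniform(0, 0.5, n)
            d_sm, p_sm = sm_lilliefors(x, dist="norm")
            res = lilliefors_normality(x)
            assert res.statistic == pytest.approx(d_sm, abs=1e-12)
            if 0.01 < p_sm < 0.5:
                assert res.p_value == pytest.approx(p_sm, abs=0.03)

    def test_too_few_values(self):
        with pytest.raises(DomainError):
            lilliefors_normality([1.0, 2.0, 3.0, 4.0])


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        r = levene_test([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_degenerate_spreads_capped(self):
        # deviations {1,1} vs {5,5}: zero within-group variance, unequal means
        r = levene_test([[0, 2], [-5, 5]])
        assert r.degenerate and r.statistic == F_CAP and r.p_value == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, s, 12) for s in (1.0, 1.5, 2.0)]
        for center in ("mean", "median"):
            mine = levene_test(groups, center=center)
            ref_s, ref_p = stats.levene(*groups, center=center)
            assert mine.statistic == pytest.approx(ref_s, rel=1e-9)
            assert mine.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_scaling_one_group_raises_statistic(self):
        rng = np.random.default_rng(4)
        base = [rng.normal(0, 1, 15) for _ in range(3)]
        stats_seq = []
        for c in (1.0, 2.0, 4.0):
            scaled = [base[0] * c] + [b.copy() for b in base[1:]]
            stats_seq.append(levene_test(scaled).statistic)
        assert stats_seq == sorted(stats_seq)


class TestANOVA:
    def test_hand_decomposition(self):
        r = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert r.statistic == pytest.approx(13.5)
        assert r.df == (1, 4)

    def test_identical_groups_null(self):
        r = one_way_anova([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_equals_summary_recomputation(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 8), (0.5, 10), (1, 12))]
        raw = one_way_anova(groups)
        summ = anova_from_summary(
            [len(g) for g in groups],
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
        )
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)

    @given(data=st.data())
    @settings(max_examples=30)
    def test_two_group_f_is_t_squared(self, data):
        a = data.draw(st.lists(st.floats(-10, 10), min_size=3, max_size=8))
        b = data.draw(st.lists(st.floats(-10, 10), min_size=3, max_size=8))
        if np.std(a + b) == 0:
            return
        f = one_way_anova([a, b])
        t, p = stats.ttest_ind(a, b)
        if not f.degenerate:
            assert f.statistic == pytest.approx(t**2, rel=1e-6, abs=1e-9)
            assert f.p_value == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_zero_within_variance_unequal_means_capped(self):
        r = one_way_anova([[1, 1], [2, 2]])
        assert r.degenerate and r.p_value == 0.0


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self):
        rng = np.random.default_rng(6)
        ctrl, trt = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        [res] = dunnett_test(ctrl, [trt])
        _, p_ref = stats.ttest_ind(trt, ctrl)
        assert res.p_value == pytest.approx(p_ref, abs=2e-5)

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(0, 1, 10)
        trts = [rng.normal(m, 1, 10) for m in (0.0, 0.5, 1.0)]
        dn = dunnett_test(ctrl, trts)
        tt = posthoc_t(ctrl, trts)
        for d, t in zip(dn, tt):
            assert d.p_value >= t.p_value - 1e-12

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(8)
        ctrl = rng.normal(0, 1, 10)
        trts = [rng.normal(m, 1, n) for m, n in ((0.4, 10), (0.0, 8), (1.2, 6))]
        mine = [r.p_value for r in dunnett_test(ctrl, trts)]
        ref = stats.dunnett(*trts, control=ctrl, random_state=1).pvalue
        assert np.allclose(mine, ref, atol=5e-4)

    def test_cdf_k1_equals_t_distribution(self):
        for t, df in ((1.0, 4), (2.0, 18), (3.0, 36)):
            mine = dunnett_max_t_cdf(t, [10], 10, df)
            ref = 1 - 2 * stats.t.sf(t, df)
            assert mine == pytest.approx(ref, abs=1e-8)

    def test_degenerate_zero_variance(self):
        [res] = dunnett_test([1.0, 1.0], [[2.0, 2.0]])
        assert res.degenerate and res.p_value == 0.0


class TestPosthocT:
    def test_two_groups_equals_classic_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        [res] = posthoc_t(a, [b])
        t_ref, p_ref = stats.ttest_ind(b, a)
        assert res.statistic == pytest.approx(t_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_hand_t_from_f(self):
        [res] = posthoc_t([1, 2, 3], [[4, 5, 6]])
        assert abs(res.statistic) == pytest.approx(math.sqrt(13.5), rel=1e-12)


class TestKruskalWallis:
    def test_hand_ranking(self):
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.statistic == pytest.approx(7.2)

    def test_all_ties(self):
        r = kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_two_groups_equals_squared_ranksum_z(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 11)
        h = kruskal_wallis([a, b]).statistic
        n, m = len(a), len(b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        w = ranks[:n].sum()
        z = (w - n * (n + m + 1) / 2) / math.sqrt(n * m * (n + m + 1) / 12.0)
        assert h == pytest.approx(z**2, rel=1e-9)


from helpers import exact_ranksum_p  # noqa: E402


class TestWilcoxon:
    def test_separated_samples_exact_p(self):
        r = wilcoxon_ranksum([1, 2, 3], [10, 11, 12])
        assert r.exact and r.p_value == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        r = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0

    def test_label_symmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
        assert wilcoxon_ranksum(a, b).p_value == pytest.approx(
            wilcoxon_ranksum(b, a).p_value
        )

    def test_exact_matches_enumeration_spot(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 5), rng.normal(0.8, 1, 6)
        r = wilcoxon_ranksum(a, b)
        assert r.exact
        assert r.p_value == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)

    def test_large_or_tied_uses_asymptotic(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        assert not wilcoxon_ranksum(a, b).exact
        r = wilcoxon_ranksum([1, 1, 2], [2, 3, 3])
        assert not r.exact and 0 <= r.p_value <= 1

    def test_empty_sample(self):
        with pytest.raises(DomainError):
            wilcoxon_ranksum([], [1.0])


class TestDecisionTree:
    DESIGN = TrialDesign(
        groups=("control", "treated"),
        genders=("male",),
        cages_per_group_per_gender=10,
    )

    def test_normal_shift_takes_parametric_path_and_flags(self):
        rng = np.random.default_rng(14)
        hits = paths = 0
        n_rep = 200
        for _ in range(n_rep):
            cell = _cell(
                {
                    "control": list(rng.normal(0, 1, 10)),
                    "treated": list(rng.normal(2.0, 1, 10)),
                }
            )
            res = decision_tree_analyze(cell, self.DESIGN)
            paths += res.path == "parametric"
            hits += res.significant("treated")
        assert hits / n_rep >= 0.95
        assert paths / n_rep >= 0.8

    def test_heavy_tail_takes_nonparametric_path(self):
        rng = np.random.default_rng(15)
        design = TrialDesign(
            groups=("control", "treated"), genders=("male",),
            cages_per_group_per_gender=25,
        )
        nonpar = 0
        n_rep = 200
        for _ in range(n_rep):
            cell = _cell(
                {
                    "control": list(np.exp(rng.normal(0, 1.2, 25))),
                    "treated": list(np.exp(rng.normal(0, 1.2, 25))),
                }
            )
            nonpar += decision_tree_analyze(cell, design).path == "nonparametric"
        assert nonpar / n_rep >= 0.9

    def test_ordinal_endpoint_forced_nonparametric(self):
        rng = np.random.default_rng(16)
        cell = _cell(
            {
                "control": list(rng.integers(0, 3, 10).astype(float)),
                "treated": list(rng.integers(0, 3, 10).astype(float)),
            },
            kind="qualitative-ordinal",
        )
        res = decision_tree_analyze(cell, self.DESIGN)
        assert res.path == "nonparametric"
        assert res.normality is None and res.homogeneity is None

    def test_constant_cell_degenerate_nonparametric(self):
        cell = _cell({"control": [5.0] * 10, "treated": [5.0] * 10})
        res = decision_tree_analyze(cell, self.DESIGN)
        assert res.path == "nonparametric"
        assert not res.significant("treated")

    def test_null_parametric_path_rate(self):
        # both gates at alpha=0.05: parametric in ~(1-a)^2 ~ 90 % of cells
        rng = np.random.default_rng(17)
        n_rep = 500
        par = 0
        for _ in range(n_rep):
            cell = _cell(
                {
                    "control": list(rng.normal(0, 1, 10)),
                    "treated": list(rng.normal(0, 1, 10)),
                }
            )
            par += decision_tree_analyze(cell, self.DESIGN).path == "parametric"
        assert par / n_rep == pytest.approx((1 - 0.05) ** 2, abs=0.05)


class TestSingleMethods:
    def test_t_flags_dominate_dunnett_flags(self, design, panel_cage_table):
        t_flags = run_single_method(panel_cage_table, "anova_t", design)
        d_flags = run_single_method(panel_cage_table, "anova_dunnett", design)
        assert (t_flags | d_flags).equals(t_flags)  # d_flags subset of t_flags
        assert int(t_flags.sum()) >= int(d_flags.sum())

    def test_three_matrices_share_index(self, design, panel_cage_table):
        flags = {
            m: run_single_method(panel_cage_table, m, design)
            for m in ("anova_t", "anova_dunnett", "kw_wilcoxon")
        }
        idx = flags["anova_t"].index
        assert flags["anova_dunnett"].index.equals(idx)
        assert flags["kw_wilcoxon"].index.equals(idx)

    def test_null_flag_rate_near_nominal(self, design, panel_cage_table):
        flags = run_single_method(panel_cage_table, "anova_t", design)
        assert flags.mean() == pytest.approx(0.05, abs=0.03)

    def test_unknown_method_rejected(self, design, panel_cage_table):
        with pytest.raises(DomainError):
            run_single_method(panel_cage_table, "bonferroni", design)


class TestClassicalBatch:
    def test_flags_cover_all_comparisons(self, design, panel_cage_table):
        results = classical_batch(panel_cage_table, design)
        flags = classical_flags(results, design)
        cells = panel_cage_table.groupby(["gender", "endpoint", "time"]).ngroups
        assert len(flags) == cells * len(design.treatment_groups)

    def test_parametric_results_carry_assumption_tests(self, design, panel_cage_table):
        results = classical_batch(panel_cage_table, design)
        for r in results:
            if r.path == "parametric":
                assert r.normality is not None and r.normality.p_value >= 0.05
                assert r.homogeneity is not None and r.homogeneity.p_value >= 0.05
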