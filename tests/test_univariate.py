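from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabrisk.datasets import reference_panel_tables
from metabrisk.profiles import exclude_metabolites, normalize_total_area
from metabrisk.synthetic import CohortConfig, generate_cohort
from metabrisk.univariate import (
    UnivariateTable,
    bh_adjust,
    compare_groups,
    fold_change,
    panel_overlap,
    stage_trend_screen,
    wilcoxon_rank_sum,
)


def exact_wilcoxon_oracle(a, b):
    """Two-sided exact Mann-Whitney P by full enumeration of rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_hi = max(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        count += (u >= u_hi) or (u <= n1 * n2 - u_hi)
        total += 1
    return count / total


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        # 2 of the 20 equally likely orderings are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact") == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=15)
        b = rng.normal(loc=0.8, size=15)
        p_exact = wilcoxon_rank_sum(a, b, mode="exact")
        p_approx = wilcoxon_rank_sum(a, b, mode="approx")
        assert abs(p_exact - p_approx) < 0.02

    def test_exact_mode_refuses_ties(self):
        with pytest.raises(ValueError, match="ties"):
            wilcoxon_rank_sum([1.0, 2.0], [2.0, 3.0], mode="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 9)
                                       for n2 in range(n1, 9)])
    def test_exact_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        a = rng.normal(size=n1)
        b = rng.normal(loc=0.5, size=n2)
        assert wilcoxon_rank_sum(a, b, mode="exact") == pytest.approx(
            exact_wilcoxon_oracle(a, b), abs=1e-12
        )


class TestBhAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_dominance_and_order_invariance(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12) and np.all(adj <= 1 + 1e-12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestFoldChange:
    def test_identical_groups_give_one(self):
        assert fold_change([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == pytest.approx(1.0)

    def test_doubling(self):
        a = [1.0, 2.0, 4.0]
        assert fold_change(a, [2 * v for v in a]) == pytest.approx(2.0)

    def test_log_ratio_sign_matches_mean_difference(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.uniform(0.5, 2.0, size=10)
            b = rng.uniform(0.5, 2.0, size=12)
            fc = fold_change(a, b)
            assert np.sign(np.log2(fc)) == np.sign(b.mean() - a.mean())

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change([0.0, 0.0], [1.0])


class TestPanelOverlap:
    def test_reference_pvalue_matrix_yields_nine_metabolites(self):
        panel = panel_overlap(reference_panel_tables(), threshold=0.05)
        assert len(panel) == 9
        assert set(panel.metabolites) == {
            "3-hydroxyisovalerate", "creatine", "fumarate", "gluconate", "lysine",
            "mannose", "N-acetylcysteine", "proline", "propionate",
        }

    def test_single_table_returns_own_significant_set(self):
        t = reference_panel_tables()[0]
        panel = panel_overlap([t])
        assert set(panel.metabolites) == t.significant(0.05)

    def test_nonsignificant_anywhere_excluded_and_subset_property(self):
        tables = reference_panel_tables()
        panel = panel_overlap(tables)
        assert "3-hydroxybutyrate" not in panel.metabolites  # P=0.0950 in one comparison
        for t in tables:
            assert set(panel.metabolites) <= t.significant(0.05)

    def test_mismatched_universe_rejected(self):
        t1 = UnivariateTable.from_adjusted_pvalues("c1", {"a": 0.01, "b": 0.5})
        t2 = UnivariateTable.from_adjusted_pvalues("c2", {"a": 0.01, "c": 0.5})
        with pytest.raises(ValueError, match="universe"):
            panel_overlap([t1, t2])


class TestCompareGroups:
    def test_panel_metabolites_significant_on_synthetic_cohort(self, cohort_effect2):
        matrix, _ = cohort_effect2
        table = compare_groups(matrix, "HC", "PC IV")
        sig = table.significant(0.05)
        planted = {"creatine", "lysine", "mannose", "proline", "propionate",
                   "fumarate", "gluconate", "N-acetylcysteine", "3-hydroxyisovalerate"}
        assert planted <= sig
        assert (table.table["p_adj"] >= table.table["p_raw"] - 1e-15).all()


class TestStageTrendScreen:
    def _planted_matrix(self):
        from metabrisk.profiles import ProfileMatrix
        rng = np.random.default_rng(2)
        groups = np.repeat(["s1", "s2", "s3"], 10)
        up = np.concatenate([rng.normal(1.0, 0.01, 10), rng.normal(2.0, 0.01, 10),
                             rng.normal(3.0, 0.01, 10)])
        flat = rng.normal(5.0, 0.01, 30)
        df = pd.DataFrame({"rising": np.abs(up), "flat": np.abs(flat)},
                          index=[f"s{i}" for i in range(30)])
        return ProfileMatrix(df, pd.Series(groups, index=df.index))

    def test_planted_trend_detected_flat_not(self):
        out = stage_trend_screen(self._planted_matrix(), ["s1", "s2", "s3"])
        assert ("rising", "up") in list(out.itertuples(index=False, name=None))
        assert "flat" not in set(out["metabolite"])

    def test_requires_three_stages(self):
        with pytest.raises(ValueError, match="3"):
            stage_trend_screen(self._planted_matrix(), ["s1", "s2"])

    def test_recovers_planted_trends_on_synthetic_cohort(self, cohort_effect2):
        matrix, _ = cohort_effect2
        out = stage_trend_screen(matrix, ["PC I+II", "PC III", "PC IV"])
        found = dict(zip(out["metabolite"], out["direction"]))
        cfg = CohortConfig()
        hits = sum(found.get(m) == "up" for m in cfg.trend_up)
        hits += sum(found.get(m) == "down" for m in cfg.trend_down)
        assert hits >= 9  # of the 11 planted trend metabolites
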