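"""Rank tests, FDR adjustment, fold changes, Fisher, diversity, phylum ratio."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcmeta.diffabund import (
    FUNCTIONAL_RULESET,
    DiffAbundRuleset,
    bh_adjust,
    differential_abundance,
    diversity,
    fisher_exact,
    fold_change_log_median,
    phylum_ratio,
    rank_test,
)
from crcmeta.errors import ContractError, DataError
from crcmeta.synthetic import GeneratorConfig, Marker, generate_cohort

from test_profiles import matrix_from


def permutation_ranksum_p(x, y, sidedness="two-sided"):
    """Brute-force enumeration oracle over all C(n, |x|) group assignments."""
    pooled = np.r_[x, y]
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if sidedness == "two-sided":
            count += abs(w - mean) >= abs(w_obs - mean) - 1e-12
        elif sidedness == "one-sided-greater":
            count += w >= w_obs - 1e-12
        else:
            count += w <= w_obs + 1e-12
    return count / total


class TestRankTest:
    def test_small_two_sided_exact_value(self):
        res = rank_test([[1, 2], [3, 4]])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "wilcoxon-exact"

    def test_identical_groups_give_p_one(self):
        res = rank_test([[5, 5, 5], [5, 5, 5]])
        assert res.p_value == pytest.approx(1.0)

    def test_two_sided_symmetric_under_group_swap(self):
        a, b = [1.2, 3.4, 2.2], [0.5, 4.1, 6.0, 2.0]
        assert rank_test([a, b]).p_value == pytest.approx(rank_test([b, a]).p_value)

    @pytest.mark.parametrize("sidedness", ["two-sided", "one-sided-greater",
                                           "one-sided-less"])
    def test_exact_branch_matches_full_enumeration(self, sidedness):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n1, n2 = rng.integers(2, 6, 2)
            # tie-rich integer draws exercise midrank handling
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            got = rank_test([x, y], sidedness).p_value
            want = permutation_ranksum_p(x, y, sidedness)
            assert got == pytest.approx(want), (x, y, sidedness)

    def test_large_sample_branch_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        got = rank_test([x, y]).p_value
        want = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
        assert got == pytest.approx(want)

    def test_three_groups_kruskal(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 20) for m in (0, 0.5, 1.0)]
        got = rank_test(groups)
        want = stats.kruskal(*groups)
        assert got.statistic == pytest.approx(want.statistic)
        assert got.p_value == pytest.approx(want.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ContractError):
            rank_test([[1.0], []])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_on_equally_spaced_vector(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_step_up(self):
        def hand_bh(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank_i in range(m - 1, -1, -1):
                i = order[rank_i]
                running = min(running, p[i] * m / (rank_i + 1))
                adj[i] = running
            return adj

        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(0, 1, rng.integers(1, 25))
            np.testing.assert_allclose(bh_adjust(p), hand_bh(p), atol=1e-12)

    def test_order_invariance(self):
        p = np.array([0.04, 0.001, 0.3, 0.02, 0.9])
        perm = [2, 0, 4, 1, 3]
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


class TestFoldChange:
    def test_identical_groups_zero(self):
        assert fold_change_log_median([1e-3] * 4, [1e-3] * 4, 1e-6) == 0.0

    def test_antisymmetric(self):
        x, y = [1e-2, 2e-2, 3e-2], [1e-3, 2e-3, 5e-3]
        assert fold_change_log_median(x, y, 1e-6) == pytest.approx(
            -fold_change_log_median(y, x, 1e-6)
        )

    def test_tenfold_difference_is_one(self):
        x = np.array([1e-2, 2e-2, 5e-2])
        assert fold_change_log_median(x, x / 10, 1e-9) == pytest.approx(1.0, abs=1e-6)


class TestDifferentialAbundance:
    def test_planted_marker_flagged_under_functional_ruleset(self):
        cfg = GeneratorConfig(n_cases=100, n_controls=100, n_features=60,
                              markers=(Marker(5, "enriched", 1.0),), seed=31)
        c = generate_cohort(cfg)
        res = differential_abundance(c.matrix, c.labels, FUNCTIONAL_RULESET)
        assert bool(res.loc["sp0005", "significant"])

    def test_permissive_ruleset_flags_everything(self):
        rng = np.random.default_rng(6)
        m = matrix_from(rng.dirichlet(np.ones(10), size=12).T * 0.8)
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        res = differential_abundance(m, labels, DiffAbundRuleset(1.0, 1.0))
        assert res["significant"].all()

    def test_flags_are_pure_function_of_p_and_fc(self):
        cfg = GeneratorConfig(n_cases=40, n_controls=40, n_features=30,
                              markers=(Marker(2, "depleted", 1.0),), seed=32)
        c = generate_cohort(cfg)
        res = differential_abundance(c.matrix, c.labels, FUNCTIONAL_RULESET)
        recomputed = (res["p_adj"] < 0.01) & (
            res["fold_change_log10"].abs() > np.log10(1.33)
        )
        assert (res["significant"] == recomputed).all()


class TestFisher:
    def test_hand_enumeration_value(self):
        assert fisher_exact([[3, 1], [1, 3]]).p_value == pytest.approx(34 / 70)

    def test_identical_row_proportions(self):
        assert fisher_exact([[5, 10], [5, 10]]).p_value == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        assert fisher_exact([[0, 0], [3, 7]]).p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = rng.integers(0, 8, (2, 2))
            got = fisher_exact(t).p_value
            # enumerate tables with the same margins
            r1, r2 = t[0].sum(), t[1].sum()
            c1 = t[:, 0].sum()
            n = r1 + r2
            p_obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
            total = 0.0
            for x in range(max(0, c1 - r2), min(r1, c1) + 1):
                px = stats.hypergeom.pmf(x, n, r1, c1)
                if px <= p_obs * (1 + 1e-9):
                    total += px
            assert got == pytest.approx(min(total, 1.0), rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[1, -2], [3, 4]])


class TestDiversity:
    def test_uniform_four_species(self):
        m = matrix_from(np.array([[0.25], [0.25], [0.25], [0.25]]))
        res = diversity(m)
        assert res["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert res["richness"].iloc[0] == 4

    def test_single_species(self):
        m = matrix_from(np.array([[1.0], [0.0]]))
        res = diversity(m)
        assert res["shannon"].iloc[0] == pytest.approx(0.0)
        assert res["richness"].iloc[0] == 1

    def test_hand_computed_mixture(self):
        m = matrix_from(np.array([[0.5], [0.25], [0.25]]))
        assert diversity(m)["shannon"].iloc[0] == pytest.approx(1.5 * np.log(2))

    def test_all_zero_sample_is_missing_with_warning(self):
        m = matrix_from(np.array([[0.0, 0.5], [0.0, 0.5]]))
        with pytest.warns(UserWarning, match="all-zero"):
            res = diversity(m)
        assert np.isnan(res["shannon"].iloc[0])


class TestPhylumRatio:
    def make(self):
        m = matrix_from(np.array([[0.1, 0.2], [0.1, 0.0], [0.2, 0.4], [0.3, 0.1]]))
        m.feature_meta = pd.DataFrame(
            {"lineage": ["k__B;p__Bacteroidetes", "k__B;p__Bacteroidetes",
                         "k__B;p__Firmicutes", "k__B;p__Firmicutes"]},
            index=pd.Index(m.feature_ids),
        )
        return m

    def test_hand_ratio(self):
        r = phylum_ratio(self.make(), "Bacteroidetes", "Firmicutes")
        assert r["s0"] == pytest.approx(0.2 / 0.5)
        assert r["s1"] == pytest.approx(0.2 / 0.5)

    def test_equal_sums_give_one(self):
        m = self.make()
        m.values[:] = np.array([[0.1, 0.1], [0.1, 0.1], [0.1, 0.1], [0.1, 0.1]])
        assert phylum_ratio(m, "Bacteroidetes", "Firmicutes")["s0"] == pytest.approx(1.0)

    def test_zero_denominator_missing(self):
        m = self.make()
        m.values[2:, 0] = 0.0
        assert np.isnan(phylum_ratio(m, "Bacteroidetes", "Firmicutes")["s0"])

    def test_unknown_phylum_rejected(self):
        with pytest.raises(DataError, match="Proteobacteria"):
            phylum_ratio(self.make(), "Proteobacteria", "Firmicutes")
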