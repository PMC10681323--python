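"""Nonparametric test wrappers against brute-force and frozen oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from reeftrace import load_cayman_summary
from reeftrace.errors import ConfigurationError
from reeftrace.stats import (
    chi_square_gof,
    dunn_posthoc,
    fisher_exact,
    kruskal_wallis,
    mann_whitney_u,
    spearman,
)


class TestChiSquare:
    def test_island_tagging_counts(self):
        out = chi_square_gof([40, 17, 9], [1 / 3, 1 / 3, 1 / 3])
        assert out.statistic == pytest.approx(23.545, abs=5e-4)
        assert out.df == 2
        assert out.p_value < 0.001

    def test_observed_equal_expected(self):
        out = chi_square_gof([25, 25, 50], [0.25, 0.25, 0.5])
        assert out.statistic == 0.0 and out.p_value == pytest.approx(1.0)

    def test_hand_formula(self):
        obs = np.array([12.0, 3.0, 9.0])
        prop = np.array([0.5, 0.2, 0.3])
        exp = obs.sum() * prop
        out = chi_square_gof(obs, prop)
        assert out.statistic == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert out.p_value == pytest.approx(sps.chi2.sf(out.statistic, 2))

    def test_two_cell_tail_close_to_exact_binomial(self):
        # exact null distribution of the statistic by binomial enumeration
        n, p0, k = 20, 0.5, 14
        stat_obs = chi_square_gof([k, n - k], [p0, 1 - p0]).statistic
        exact = sum(
            sps.binom.pmf(j, n, p0)
            for j in range(n + 1)
            if chi_square_gof([j, n - j], [p0, 1 - p0]).statistic >= stat_obs - 1e-12
        )
        approx = chi_square_gof([k, n - k], [p0, 1 - p0]).p_value
        assert approx == pytest.approx(exact, abs=0.06)  # asymptotic vs exact at n=20

    def test_zero_expected_cell_is_error(self):
        with pytest.raises(ConfigurationError):
            chi_square_gof([5, 5], [1.0, 0.0])


class TestSpearman:
    def test_length_vs_displacement_from_study_table(self):
        df = load_cayman_summary()
        out = spearman(df["tl_cm"], df["mld_km"])
        assert out.statistic == pytest.approx(0.318, abs=0.005)
        assert out.p_value == pytest.approx(0.048, abs=0.002)

    def test_perfectly_monotone(self):
        out = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert out.statistic == pytest.approx(1.0)
        assert out.extras["S"] == 0.0

    def test_midrank_tie_handling_matches_hand_computation(self):
        x = [1.0, 2.0, 2.0, 4.0]  # mid-ranks 1, 2.5, 2.5, 4
        y = [10.0, 30.0, 20.0, 40.0]  # ranks 1, 3, 2, 4
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        out = spearman(x, y)
        assert out.statistic == pytest.approx(np.corrcoef(rx, ry)[0, 1])
        assert out.extras["S"] == pytest.approx(((rx - ry) ** 2).sum())

    def test_constant_vector_is_error(self):
        with pytest.raises(ConfigurationError):
            spearman([1, 1, 1], [1, 2, 3])


class TestMannWhitney:
    def test_identical_samples(self):
        out = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert out.p_value == pytest.approx(1.0)

    def test_constant_pooled_values(self):
        out = mann_whitney_u([5, 5], [5, 5, 5])
        assert out.p_value == 1.0

    def test_tiny_sample_exact_enumeration(self):
        out = mann_whitney_u([1, 2], [3, 4])
        assert out.statistic == 0.0  # W (rank-sum convention, first sample)
        # exhaustive: 6 equally likely assignments, 2 as extreme two-sided
        assert out.p_value == pytest.approx(1 / 3)

    def test_statistic_uses_rank_sum_convention(self):
        a, b = [7, 9, 11], [1, 2]
        out = mann_whitney_u(a, b)
        assert out.statistic == 6.0  # all pairs favour a
        assert out.extras["U"] == 0.0

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(17)
        rejections = []
        for shift in (0.0, 1.0, 2.0):
            hits = 0
            for _ in range(200):
                a = rng.normal(0, 1, 12)
                b = rng.normal(shift, 1, 12)
                hits += mann_whitney_u(a, b).p_value < 0.05
            rejections.append(hits)
        assert rejections[0] < rejections[1] < rejections[2]

    def test_adding_shared_tie_keeps_effect_sign(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = rng.normal(0.6, 1, 8)
            b = rng.normal(0.0, 1, 9)
            eff = mann_whitney_u(a, b).statistic - len(a) * len(b) / 2
            a2, b2 = np.append(a, 0.31), np.append(b, 0.31)
            eff2 = mann_whitney_u(a2, b2).statistic - len(a2) * len(b2) / 2
            assert eff == 0 or np.sign(eff) == np.sign(eff2) or eff2 == 0


class TestKruskalWallis:
    def test_identical_groups_have_zero_statistic(self):
        out = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert out.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_tied(self):
        out = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert out.statistic == 0.0 and out.p_value == 1.0

    def test_df_convention(self):
        groups = [[i + j / 10 for j in range(3)] for i in range(20)]
        assert kruskal_wallis(groups).df == 19

    def test_tail_close_to_exhaustive_permutation_null(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        obs = kruskal_wallis(groups).statistic
        values = [v for g in groups for v in g]
        stats = []
        for perm in itertools.permutations(values):
            g = [list(perm[0:2]), list(perm[2:4]), list(perm[4:6])]
            stats.append(kruskal_wallis(g).statistic)
        exact_p = np.mean([s >= obs - 1e-12 for s in stats])
        # asymptotic chi-squared tail vs the exact permutation null at n=6
        assert kruskal_wallis(groups).p_value == pytest.approx(exact_p, abs=0.05)


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        out = dunn_posthoc([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert out.statistic == pytest.approx(0.0, abs=1e-12)

    def test_three_groups_match_hand_formula(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 8.0, 9.0, 10.0], [4.0, 6.0, 7.0]]
        out = dunn_posthoc(groups, labels=["g1", "g2", "g3"])
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        mean_r = [ranks[0:3].mean(), ranks[3:7].mean(), ranks[7:10].mean()]
        sizes = [3, 4, 3]
        for (i, j), key in [((0, 1), ("g1", "g2")), ((0, 2), ("g1", "g3")), ((1, 2), ("g2", "g3"))]:
            se = math.sqrt(n * (n + 1) / 12.0 * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_r[i] - mean_r[j]) / se
            assert out.extras["pairs"][key]["z"] == pytest.approx(z)
            assert out.extras["pairs"][key]["p"] == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_bonferroni_is_min_one_m_times_p(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 8.0, 9.0], [4.0, 6.0, 7.0]]
        raw = dunn_posthoc(groups)
        adj = dunn_posthoc(groups, adjustment="bonferroni")
        for key, pair in raw.extras["pairs"].items():
            assert adj.extras["pairs"][key]["p"] == pytest.approx(min(1.0, 3 * pair["p"]))

    def test_empty_group_excluded(self):
        out = dunn_posthoc([[1.0, 2.0], [], [3.0, 4.0]], labels=["a", "b", "c"])
        assert set(out.extras["pairs"]) == {("a", "c")}


class TestFisherExact:
    def test_2x2_against_hypergeometric_sum(self):
        out = fisher_exact([[1, 9], [11, 3]])
        assert out.p_value == pytest.approx(0.0027594561852, abs=1e-9)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact([[0, 0], [5, 3]]).p_value == 1.0

    def test_2x3_matches_R_reference(self):
        # rows x cols = [[3, 2, 8], [7, 10, 9]]; fisher.test in R: 0.2368042434
        out = fisher_exact([[3, 2, 8], [7, 10, 9]])
        assert out.p_value == pytest.approx(0.2368042434, abs=1e-8)

    def test_2x3_matches_exhaustive_enumeration(self):
        table = np.array([[4, 6, 3], [2, 1, 8]])
        row, col = table.sum(axis=1), table.sum(axis=0)
        n = table.sum()

        def prob(t):
            num = sum(math.lgamma(x + 1) for x in row) + sum(
                math.lgamma(x + 1) for x in col
            )
            den = math.lgamma(n + 1) + sum(math.lgamma(x + 1) for x in np.ravel(t))
            return math.exp(num - den)

        p_obs = prob(table)
        total = 0.0
        for a in range(min(row[0], col[0]) + 1):
            for b in range(min(row[0] - a, col[1]) + 1):
                c = row[0] - a - b
                if 0 <= c <= col[2]:
                    t = np.array([[a, b, c], [col[0] - a, col[1] - b, col[2] - c]])
                    pr = prob(t)
                    if pr <= p_obs * (1 + 1e-9):
                        total += pr
        assert fisher_exact(table).p_value == pytest.approx(total, rel=1e-9)

    def test_resident_by_island_style_table(self):
        # 13 residents split over three islands vs non-residents
        out = fisher_exact([[1, 10, 2], [9, 26, 7]])
        assert 0.0 < out.p_value <= 1.0

    def test_unsupported_shape(self):
        with pytest.raises(ConfigurationError):
            fisher_exact([[1, 2, 3, 4], [5, 6, 7, 8]])


class TestNullCalibration:
    """Empirical size of the tests at alpha = 0.05 under simulated nulls."""

    @pytest.mark.parametrize(
        "runner",
        [
            lambda rng: mann_whitney_u(rng.normal(size=15), rng.normal(size=15)),
            lambda rng: kruskal_wallis([rng.normal(size=10) for _ in range(3)]),
            lambda rng: spearman(rng.normal(size=20), rng.normal(size=20)),
        ],
        ids=["mann-whitney", "kruskal-wallis", "spearman"],
    )
    def test_type_one_error_close_to_nominal(self, runner):
        rng = np.random.default_rng(99)
        n_rep = 400
        hits = sum(runner(rng).p_value < 0.05 for _ in range(n_rep))
        # binomial 99.9% envelope around 0.05 at 400 replicates
        sd = math.sqrt(n_rep * 0.05 * 0.95)
        assert abs(hits - n_rep * 0.05) < 3.3 * sd
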