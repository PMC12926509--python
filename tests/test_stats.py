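"""Exact Mann-Whitney, Spearman permutation p, Welch t and the comparison driver."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chpsilk.errors import ValidationError
from chpsilk.stats import (
    compare_groups,
    holm_adjust,
    mann_whitney_exact,
    shapiro_wilk,
    spearman_corr,
    u_null_counts,
    welch_t,
)


def brute_force_u_pvalue(x, y):
    """Two-sided exact p by enumerating all group labelings of the pooled data."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(xi < yj for xi in x for yj in y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(xi < yj for xi in xs for yj in ys))
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


class TestMannWhitneyExact:
    def test_complete_separation_8v4(self):
        res = mann_whitney_exact(list(range(8)), [100, 101, 102, 103])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(2 / math.comb(12, 4), abs=1e-15)
        assert res.method == "exact"

    def test_complete_separation_8v5(self):
        res = mann_whitney_exact(list(range(8)), [100, 101, 102, 103, 104])
        assert res.p_value == pytest.approx(2 / math.comb(13, 5), abs=1e-15)

    def test_hand_enumeration_2v2(self):
        res = mann_whitney_exact([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-15)

    def test_u_zero_closed_form_all_small_sizes(self):
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                x = list(range(n1))
                y = [100 + i for i in range(n2)]
                res = mann_whitney_exact(x, y)
                expected = min(1.0, 2 / math.comb(n1 + n2, n1))
                assert res.p_value == pytest.approx(expected, abs=1e-12), (n1, n2)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.normal(), size=n2)
            res = mann_whitney_exact(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_u_pvalue(x, y), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5) + 0.5
        ours = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_null_distribution_properties(self):
        for n1, n2 in [(3, 2), (5, 5), (8, 4), (7, 6)]:
            counts = u_null_counts(n1, n2)
            assert counts.sum() == math.comb(n1 + n2, n1)
            assert np.array_equal(counts, counts[::-1])  # symmetric about n1*n2/2

    def test_ties_fall_back_to_seeded_permutation(self):
        res = mann_whitney_exact([1, 2, 2, 3], [2, 4, 5], seed=1)
        assert res.method == "permutation"
        res2 = mann_whitney_exact([1, 2, 2, 3], [2, 4, 5], seed=1)
        assert res.p_value == res2.p_value  # same seed, same p

    def test_permutation_p_close_to_exact_for_no_ties(self):
        x, y = [1.0, 2.0, 5.0], [3.0, 4.0, 6.0]
        exact = mann_whitney_exact(x, y).p_value
        approx = mann_whitney_exact(x, y, exact_max_n=2, n_permutations=20000, seed=0).p_value
        assert approx == pytest.approx(exact, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_exact([], [1.0])


def brute_force_spearman_p(x, y):
    """Two-sided permutation p with an independent rho computation."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.array(perm))[0, 1]
        hits += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    return hits / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_corr(x, [10, 20, 30, 40, 50]).statistic == pytest.approx(1.0)
        assert spearman_corr(x, [50, 40, 30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_brute_force_n7(self, rng):
        x = rng.normal(size=7)
        y = 0.8 * x + rng.normal(size=7)
        res = spearman_corr(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        base = spearman_corr(x, y)
        transformed = spearman_corr(np.exp(x), y**3)
        assert transformed.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert transformed.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_t_approx_matches_scipy_for_large_n(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert res.method == "t_approx"
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1.0)

    def test_location_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=8)
        assert welch_t(x + 7.5, y + 7.5).statistic == pytest.approx(
            welch_t(x, y).statistic, rel=1e-9
        )

    def test_matches_independent_formula_and_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(2, 11)))
            y = rng.normal(loc=1, size=int(rng.integers(2, 11)))
            res = welch_t(x, y)
            # independent evaluation of the statistic and Welch-Satterthwaite df
            se2 = x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
            t_direct = (x.mean() - y.mean()) / math.sqrt(se2)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert res.statistic == pytest.approx(t_direct, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_df_bounds(self, rng):
        from chpsilk.stats import welch_df

        for _ in range(10):
            x = rng.normal(size=int(rng.integers(2, 9)))
            y = rng.normal(scale=3.0, size=int(rng.integers(2, 9)))
            df = welch_df(x, y)
            assert min(x.size, y.size) - 1 <= df <= x.size + y.size - 2

    def test_degenerate_zero_variance_equal_means(self):
        with pytest.raises(ValidationError):
            welch_t([2.0, 2.0], [2.0, 2.0])


class TestHelpers:
    def test_holm_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=8)
        ours = holm_adjust(p)
        ref = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_shapiro_hook_delegates(self, rng):
        res = shapiro_wilk(rng.normal(size=20))
        assert 0 <= res.p_value <= 1
        assert res.statistic_name == "W"


class TestCompareGroups:
    def make_rates(self):
        rows = []
        for i in range(8):
            rows.append({"subject_id": f"N{i}", "group": "NPH", "peptide_id": "TTHY_TSE",
                         "fsr_pct_per_h": 0.1 + 0.01 * i, "fcr_per_h": 0.002 + 0.0001 * i})
        for i in range(4):
            rows.append({"subject_id": f"C{i}", "group": "control_ventricular",
                         "peptide_id": "TTHY_TSE",
                         "fsr_pct_per_h": 1.0 + 0.1 * i, "fcr_per_h": 0.02 + 0.001 * i})
        return pd.DataFrame(rows)

    def test_separated_groups_give_u_zero_exact_p(self):
        comp, _ = compare_groups(self.make_rates())
        fcr = comp[comp["quantity"] == "fcr_per_h"].iloc[0]
        assert fcr["statistic"] == 0
        assert fcr["p"] == pytest.approx(2 / math.comb(12, 4))
        assert fcr["method"] == "exact"

    def test_undefined_rates_excluded_with_counts(self):
        rates = self.make_rates()
        rates.loc[rates.index[:2], "fcr_per_h"] = np.nan  # FCRs captured in 6/8
        comp, _ = compare_groups(rates)
        fcr = comp[comp["quantity"] == "fcr_per_h"].iloc[0]
        assert fcr["n_a"] == 6 and fcr["n_excluded_a"] == 2

    def test_empty_group_skipped_with_reason(self):
        rates = self.make_rates()
        rates.loc[rates["group"] == "control_ventricular", "fcr_per_h"] = np.nan
        comp, _ = compare_groups(rates)
        fcr = comp[comp["quantity"] == "fcr_per_h"].iloc[0]
        assert fcr["method"] == "skipped_empty_group"

    def test_production_correlation_perfect_at_zero_noise(self):
        rates = self.make_rates()
        nph = rates[rates["group"] == "NPH"]
        production = pd.DataFrame({
            "subject_id": nph["subject_id"],
            # any monotone function of synthesis: Spearman must hit rho = 1
            "production_ml_per_h": np.exp(nph["fsr_pct_per_h"]),
        })
        _, corr = compare_groups(rates, production=production)
        assert corr.iloc[0]["rho"] == pytest.approx(1.0)

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(self.make_rates(), pairs=[("NPH", "nonexistent")])
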