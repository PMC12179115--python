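"""Nonparametric tests with enumeration oracles, Holm-Sidak, and the LME."""

import itertools

import numpy as np
import pandas as pd
import pytest

from petasym.stats import (
    fit_lme_random_intercept,
    holm_sidak_adjust,
    mann_whitney_u,
    pearson_correlation,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_p(diffs: np.ndarray) -> float:
    """Brute force: two-sided p over all 2^n sign assignments of the ranks."""
    n = diffs.size
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = float(ranks[diffs > 0].sum())
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(ranks[np.array(signs, dtype=bool)].sum())
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def mwu_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Brute force: two-sided p over all labelings of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    u_obs = sum(xi > yj for xi in x for yj in y)
    mu = n1 * y.size / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(xi > yj for xi in xs for yj in ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_exact_example(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.exact
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(2 / 8)

    def test_swap_symmetry(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.3, 1, 12)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.statistic + b.statistic == pytest.approx(12 * 13 / 2)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_exact_path_matches_enumeration(self, n, rng):
        """Property sweep: the DP null distribution must equal literal
        enumeration of every sign pattern for tie-free samples."""
        for _ in range(20):
            d = rng.normal(0.2, 1.0, n)
            while np.unique(np.abs(d)).size < n or np.any(d == 0):
                d = rng.normal(0.2, 1.0, n)
            res = wilcoxon_signed_rank(d)
            assert res.exact
            assert res.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self, rng):
        d = rng.normal(0.1, 1.0, 60)
        res = wilcoxon_signed_rank(d)
        assert not res.exact
        assert 0.0 < res.p_value <= 1.0

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 0.0, 0.0], [0.0, 0.0, 0.0])


class TestMannWhitney:
    def test_exact_example(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.exact
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 20)

    def test_identical_multisets(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # n1 n2 / 2
        assert res.p_value == 1.0

    def test_shift_invariance(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 14)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(x + 3.0, y + 3.0)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    @pytest.mark.parametrize("n1, n2", [(3, 3), (4, 4), (3, 6), (5, 4), (2, 8)])
    def test_exact_path_matches_enumeration(self, n1, n2, rng):
        for _ in range(10):
            x = rng.normal(0.5, 1.0, n1)
            y = rng.normal(0.0, 1.0, n2)
            while np.unique(np.concatenate([x, y])).size < n1 + n2:
                x = rng.normal(0.5, 1.0, n1)
            res = mann_whitney_u(x, y)
            assert res.exact
            assert res.p_value == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_sidak_adjust([0.03]), [0.03])

    def test_equal_p_closed_form(self):
        for m in (2, 3, 5, 8):
            p0 = 0.02
            adjusted = holm_sidak_adjust([p0] * m)
            np.testing.assert_allclose(adjusted, 1 - (1 - p0) ** m)

    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(
            holm_sidak_adjust([0.01, 0.04]), [1 - 0.99**2, 0.04], rtol=1e-12
        )

    def test_properties(self, rng):
        p = rng.uniform(0, 1, 12)
        adj = holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.1, 1.2])


class TestShapiro:
    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0] * 10)

    def test_gaussian_samples_look_gaussian(self):
        rng = np.random.default_rng(99)
        good = sum(
            shapiro_wilk(rng.normal(0, 1, 76)).statistic > 0.95 for _ in range(200)
        )
        assert good >= 0.95 * 200

    def test_exponential_samples_rejected(self):
        rng = np.random.default_rng(100)
        hits = sum(
            shapiro_wilk(rng.exponential(1.0, 76)).p_value < 0.05 for _ in range(200)
        )
        assert hits >= 0.95 * 200


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson_correlation([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert res.statistic == pytest.approx(1.0)

    def test_hand_computed_half(self):
        res = pearson_correlation([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert res.statistic == pytest.approx(0.5)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _balanced_table(rng, n=30, delta=0.02, handed=True):
    rows = []
    for i in range(n):
        bilat = 1.08 + rng.normal(0, 0.04)
        pair = rng.normal(0, 0.015)
        hand = "right" if (not handed or i % 5 != 0) else "left"
        for hemi, dvr in (("left", bilat - delta / 2 - pair / 2),
                          ("right", bilat + delta / 2 + pair / 2)):
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "centre": "Manchester" if i % 2 else "Turku",
                    "age": 30.0 + i,
                    "sex": "male" if i % 3 else "female",
                    "handedness": hand,
                    "hemisphere": hemi,
                    "DVR": dvr,
                }
            )
    return pd.DataFrame(rows)


class TestLME:
    def test_balanced_hemisphere_estimate_equals_mean_paired_difference(self, rng):
        data = _balanced_table(rng)
        res = fit_lme_random_intercept(data, covariates=(), interaction=False)
        wide = data.pivot_table(index="subject_id", columns="hemisphere", values="DVR")
        expected = float((wide.right - wide.left).mean())
        assert res.effect("hemisphere_right").estimate == pytest.approx(
            expected, abs=1e-8
        )

    def test_noise_free_data_reduces_to_ols(self, rng):
        """With zero residual and zero intercept variance the REML fixed
        effects coincide with the ordinary least-squares solution."""
        n = 24
        rows = []
        for i in range(n):
            age = 30.0 + i
            for hemi in ("left", "right"):
                dvr = 1.0 + 0.02 * (hemi == "right") + 0.001 * age
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "hemisphere": hemi,
                        "age": age,
                        "DVR": dvr,
                    }
                )
        data = pd.DataFrame(rows)
        res = fit_lme_random_intercept(data, covariates=("age",), interaction=False)
        assert res.effect("hemisphere_right").estimate == pytest.approx(0.02, abs=1e-6)
        assert res.effect("age").estimate == pytest.approx(0.001, abs=1e-6)

    def test_unknown_handedness_excluded(self, rng):
        data = _balanced_table(rng)
        data.loc[data.subject_id.isin(["S0", "S1"]), "handedness"] = "unknown"
        res = fit_lme_random_intercept(
            data, covariates=("age", "sex", "handedness"), interaction=False
        )
        assert res.n_subjects == 28
        assert res.n_rows == 56

    def test_singular_design_names_term(self, rng):
        data = _balanced_table(rng)
        data["centre"] = "Manchester"  # one centre only
        with pytest.raises(ValueError, match="centre"):
            fit_lme_random_intercept(
                data, covariates=("age", "centre"), interaction=True
            )

    def test_uneven_rows_rejected(self, rng):
        data = _balanced_table(rng).iloc[:-1]
        with pytest.raises(ValueError):
            fit_lme_random_intercept(data, covariates=(), interaction=False)

    def test_ci_brackets_estimate_and_variances_nonnegative(self, rng):
        res = fit_lme_random_intercept(_balanced_table(rng))
        for _, row in res.table.iterrows():
            assert row.ci_low <= row.estimate <= row.ci_high
        assert res.var_subject >= 0 and res.var_residual >= 0
        assert res.df_method == "wald_z"
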