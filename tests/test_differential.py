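"""Negative-binomial Wald engine: size factors, dispersion, tests, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from atacreg.differential import (
    DesignInfo,
    adjust_bh,
    call_differential,
    estimate_dispersion,
    estimate_size_factors,
    nb_wald_table,
    nb_wald_test,
    run_differential,
)
from atacreg.peaks import CountsMatrix


def _cm(values, lib_sizes=None):
    values = np.asarray(values)
    return CountsMatrix(
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        lib_sizes,
    )


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        cm = _cm(np.tile([[10], [20], [30]], (1, 4)))
        np.testing.assert_allclose(estimate_size_factors(cm), 1.0)

    def test_doubled_column_ratio(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 100, size=(50, 1))
        cm = _cm(np.hstack([base, 2 * base, base]))
        sf = estimate_size_factors(cm)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_single_sample_is_one(self):
        cm = _cm([[5], [9]])
        np.testing.assert_allclose(estimate_size_factors(cm), 1.0)

    def test_fallback_warns_without_positive_feature(self):
        cm = _cm([[0, 5], [3, 0]])
        with pytest.warns(UserWarning, match="library-size ratio"):
            sf = estimate_size_factors(cm)
        assert np.all(sf > 0)


class TestDispersion:
    def test_constant_feature_hits_floor(self, balanced_sheet):
        cm = _cm(np.full((1, 12), 50))
        d = DesignInfo.from_sample_sheet(balanced_sheet)
        alpha = estimate_dispersion(cm, np.ones(12), d)
        assert alpha[0] == pytest.approx(1e-8)

    def test_poisson_data_near_floor(self):
        rng = np.random.default_rng(1)
        n, F = 100, 500
        mean = rng.lognormal(np.log(100), 0.5, size=F)
        Y = rng.poisson(mean[:, None], (F, n))
        samp = [f"s{i}" for i in range(n)]
        d = DesignInfo(
            samp, ["control", "centenarian"] * (n // 2), ["F", "M"] * (n // 2)
        )
        alpha = estimate_dispersion(_cm(Y), np.ones(n), d)
        assert np.median(alpha) <= 0.01

    def test_nb_alpha_recovery(self):
        rng = np.random.default_rng(2)
        n, F, alpha = 50, 400, 0.5
        mean = rng.lognormal(np.log(100), 0.5, size=F)
        lam = rng.gamma(1 / alpha, alpha * mean[:, None], (F, 2 * n))
        Y = rng.poisson(lam)
        samp = [f"s{i}" for i in range(2 * n)]
        d = DesignInfo(
            samp, ["control"] * n + ["centenarian"] * n, ["F", "M"] * n,
            include_sex=False,
        )
        est = estimate_dispersion(_cm(Y), np.ones(2 * n), d)
        assert np.mean((est >= 0.3) & (est <= 0.7)) >= 0.80


class TestNbWald:
    def test_symmetric_groups_null_lfc(self):
        d = DesignInfo(
            [f"s{i}" for i in range(8)],
            ["control"] * 4 + ["centenarian"] * 4,
            ["F", "F", "M", "M"] * 2,
        )
        row = nb_wald_test([12, 15, 9, 20, 12, 15, 9, 20], d, np.ones(8), 0.1)
        assert abs(row["log2fc"]) < 1e-6

    def test_worked_example_group_means(self):
        """With a group-wise-constant predictor, fitted group means equal sample
        means, so log2fc = log2((91/3)/(33/3)) for any fixed alpha."""
        d = DesignInfo(
            list("abcdef"), ["control"] * 3 + ["centenarian"] * 3,
            ["F", "M", "F", "M", "F", "M"], include_sex=False,
        )
        expected = np.log2((91 / 3) / (33 / 3))
        for alpha in (0.01, 0.2, 1.0):
            row = nb_wald_test([10, 12, 11, 30, 28, 33], d, np.ones(6), alpha)
            assert row["log2fc"] == pytest.approx(expected, abs=1e-6)

    def test_matches_brute_force_likelihood(self):
        """IRLS estimate maximizes the fixed-alpha NB likelihood (numeric oracle)."""
        y = np.array([10, 12, 11, 30, 28, 33], dtype=float)
        g = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        alpha = 0.3

        def negll(beta):
            mu = np.exp(beta[0] + beta[1] * g)
            r = 1.0 / alpha
            return -np.sum(
                gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
            )

        opt = minimize(negll, [2.0, 0.5], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        d = DesignInfo(
            list("abcdef"), ["control"] * 3 + ["centenarian"] * 3,
            ["F"] * 6, include_sex=False,
        )
        row = nb_wald_test(y, d, np.ones(6), alpha)
        assert row["log2fc"] == pytest.approx(opt.x[1] / np.log(2), abs=1e-5)

    def test_matches_statsmodels_glm(self):
        """Independent cross-check of coefficients and SEs against statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 20
        groups = ["control"] * 10 + ["centenarian"] * 10
        sexes = list(np.where(rng.random(n) < 0.5, "F", "M"))
        if len(set(sexes)) < 2:
            sexes[0] = "F" if sexes[0] == "M" else "M"
        d = DesignInfo([f"s{i}" for i in range(n)], groups, sexes)
        sf = np.exp(rng.normal(0, 0.2, n))
        alpha = 0.25
        X = d.matrix()
        for _ in range(5):
            mu = 50 * sf * np.exp(0.6 * X[:, 1])
            y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
            if y.sum() == 0:
                continue
            row = nb_wald_test(y, d, sf, alpha)
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf),
            ).fit()
            assert row["log2fc"] == pytest.approx(fit.params[1] / np.log(2), abs=1e-4)
            assert row["se"] == pytest.approx(fit.bse[1] / np.log(2), rel=0.02)

    def test_all_zero_feature_is_na(self, balanced_sheet):
        d = DesignInfo.from_sample_sheet(balanced_sheet)
        cm = _cm(np.zeros((1, 12), dtype=int))
        table = nb_wald_table(cm, d, np.ones(12), np.array([0.1]))
        assert np.isnan(table["wald_p"].iloc[0])

    def test_invariant_to_sample_order_and_scaling(self, balanced_sheet):
        rng = np.random.default_rng(4)
        Y = rng.integers(5, 200, size=(30, 12))
        sheet = balanced_sheet
        cm = CountsMatrix(
            [f"f{i}" for i in range(30)], list(sheet["sample_id"]), Y
        )
        res = run_differential(cm, sheet, alpha=0.2)
        # permuted columns
        perm = rng.permutation(12)
        cm_p = CountsMatrix(
            cm.feature_ids, [cm.sample_ids[j] for j in perm], Y[:, perm]
        )
        res_p = run_differential(cm_p, sheet, alpha=0.2)
        np.testing.assert_allclose(res["log2fc"], res_p["log2fc"], atol=1e-8)
        # a constant factor on the size factors is absorbed by the intercept
        from atacreg.differential import estimate_size_factors, nb_wald_table

        d = DesignInfo.from_sample_sheet(sheet)
        sf = estimate_size_factors(cm)
        t1 = nb_wald_table(cm, d, sf, np.full(30, 0.2))
        t3 = nb_wald_table(cm, d, 3.0 * sf, np.full(30, 0.2))
        np.testing.assert_allclose(t1["log2fc"], t3["log2fc"], atol=1e-7)
        # doubling every raw count changes only the NB weighting slightly
        cm2 = CountsMatrix(cm.feature_ids, cm.sample_ids, 2 * Y)
        res2 = run_differential(cm2, sheet, alpha=0.2)
        np.testing.assert_allclose(res["log2fc"], res2["log2fc"], atol=0.05)


class TestAdjustBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_na_propagated_and_excluded(self):
        out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        out = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(5):
            p = rng.random(500)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(adjust_bh(p), ref, atol=1e-12)


class TestCallDifferential:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (1.0, 0.01, "opening"),  # FC 2.0 > 1.5
            (0.5, 0.001, "ns"),  # FC 1.41 < 1.5
            (3.0, 0.06, "ns"),  # fails the padj gate
            (-1.0, 0.01, "closing"),
            (np.log2(1.5), 0.01, "ns"),  # strict inequality at the boundary
        ],
    )
    def test_threshold_arithmetic(self, log2fc, padj, expected):
        df = pd.DataFrame(
            {"feature_id": ["x"], "log2fc": [log2fc], "padj": [padj]}
        )
        assert call_differential(df)["call"].iloc[0] == expected
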