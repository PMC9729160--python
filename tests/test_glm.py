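"""Design encoding, weighted logistic IRLS, Wald tests and fold-change ORs."""

import numpy as np
import pandas as pd
import pytest

import iabrisk as ir
from iabrisk.glm import COVARIATE_SETS, ModelFit


def _instances(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "source": rng.choice(["BABYDIAB", "DAISY", "DEW-IT", "DiPiS", "DIPP"], n),
            "sex": rng.choice(["M", "F"], n),
            "family_history": rng.integers(0, 2, n),
            "hla_group": rng.choice(["A", "B", "C", "D", "missing"], n),
            "age_initial": rng.uniform(0.5, 10, n),
            "age_confirm": rng.uniform(1, 11, n),
            **{f"pos_init_{ab}": rng.integers(0, 2, n) for ab in ir.ANTIBODIES},
            **{f"pos_conf_{ab}": rng.integers(0, 2, n) for ab in ir.ANTIBODIES},
            **{f"lnlvl_init_{ab}": rng.normal(size=n) for ab in ir.ANTIBODIES},
            **{f"lnlvl_conf_{ab}": rng.normal(size=n) for ab in ir.ANTIBODIES},
            **{f"lnlvl_t0_{ab}": rng.normal(size=n) for ab in ir.ANTIBODIES},
        }
    )


class TestEncodeDesign:
    def test_levels_confirmatory_set_has_three_terms(self):
        X, names = ir.encode_design(_instances(), COVARIATE_SETS[6])
        assert names == ["intercept"] + [f"lnlvl_conf_{ab}" for ab in ir.ANTIBODIES]
        assert X.shape[1] == 4

    def test_baseline_set_has_twelve_non_intercept_terms(self):
        # 4 source + 1 sex + 1 family history + 4 HLA (incl. missing) + 2 ages
        X, names = ir.encode_design(_instances(), COVARIATE_SETS[1])
        assert len(names) - 1 == 12
        assert "source_DIPP" not in names and "hla_B" not in names  # references

    def test_constant_column_dropped_with_warning(self):
        inst = _instances()
        inst["sex"] = "F"
        with pytest.warns(UserWarning, match="sex_male"):
            _, names = ir.encode_design(inst, COVARIATE_SETS[1])
        assert "sex_male" not in names

    def test_unknown_category_is_named(self):
        inst = _instances()
        inst.loc[0, "hla_group"] = "Z"
        with pytest.raises(ValueError, match="Z"):
            ir.encode_design(inst, COVARIATE_SETS[1])


class TestFitWeightedLogistic:
    def test_two_by_two_table_matches_closed_form(self):
        # x=1: 20 events / 10 non-events; x=0: 10 events / 20 non-events
        x = np.array([1] * 30 + [0] * 30, dtype=float)
        y = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20, dtype=float)
        X = np.column_stack([np.ones(60), x])
        fit = ir.fit_weighted_logistic(X, y, np.ones(60))
        assert fit.beta[1] == pytest.approx(np.log(4), abs=1e-6)

    def test_constant_weight_rescaling_changes_nothing(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = (rng.random(100) < 0.4).astype(float)
        a = ir.fit_weighted_logistic(X, y, np.ones(100))
        b = ir.fit_weighted_logistic(X, y, np.full(100, 2.7))
        assert np.allclose(a.beta, b.beta, atol=1e-10)

    def test_zero_weight_rows_are_inert(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = (rng.random(80) < 0.5).astype(float)
        w = np.ones(80)
        w[::4] = 0.0
        with_zeros = ir.fit_weighted_logistic(X, y, w)
        removed = ir.fit_weighted_logistic(X[w > 0], y[w > 0], w[w > 0])
        assert np.allclose(with_zeros.beta, removed.beta, atol=1e-10)
        assert np.allclose(with_zeros.se, removed.se, atol=1e-10)

    def test_covariate_rescaling_equivariance(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=150)
        y = (rng.random(150) < 1 / (1 + np.exp(-z))).astype(float)
        w = rng.uniform(0.5, 2, 150)
        c = 3.7
        a = ir.fit_weighted_logistic(np.column_stack([np.ones(150), z]), y, w)
        b = ir.fit_weighted_logistic(np.column_stack([np.ones(150), c * z]), y, w)
        assert b.beta[1] == pytest.approx(a.beta[1] / c, rel=1e-7)
        # a fixed fold-change OR is unchanged by the rescaling
        assert ir.fold_change_or(b.beta[1] * c, 5) == pytest.approx(
            ir.fold_change_or(a.beta[1], 5), rel=1e-7
        )

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(300), rng.normal(size=300), rng.integers(0, 2, 300)])
        eta = 0.3 * X[:, 1] - 0.5 * X[:, 2]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        w = rng.uniform(0.5, 3, 300)
        mine = ir.fit_weighted_logistic(X, y, w)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        assert np.allclose(mine.beta, ref.params, atol=1e-6)
        assert np.allclose(mine.se_info, ref.bse, atol=1e-6)

    def test_complete_separation_is_flagged_not_fatal(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = x.copy()
        fit = ir.fit_weighted_logistic(np.column_stack([np.ones(6), x]), y, np.ones(6))
        assert any("separation" in m for m in fit.messages)

    def test_one_class_data_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(ValueError):
            ir.fit_weighted_logistic(X, np.ones(10), np.ones(10))

    def test_negative_weights_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError):
            ir.fit_weighted_logistic(X, np.array([0, 1, 0, 1.0]), np.array([1, 1, -1, 1.0]))


def _toy_fit(beta, se):
    k = len(beta)
    return ModelFit(
        terms=[f"t{i}" for i in range(k)],
        beta=np.asarray(beta, dtype=float),
        se=np.asarray(se, dtype=float),
        cov=np.diag(np.square(se)),
        se_info=np.asarray(se, dtype=float),
        cov_info=np.diag(np.square(se)),
        loglik=0.0,
        n_obs=10,
        weight_sum=10.0,
        n_iter=1,
        converged=True,
    )


class TestWald:
    def test_zero_coefficient(self):
        z, p = ir.wald_test(_toy_fit([0.0], [0.5]), "t0")
        assert (z, p) == (0.0, 1.0)

    def test_1_96_se_is_p_05(self):
        _, p = ir.wald_test(_toy_fit([1.96 * 0.3], [0.3]), "t0")
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_se_signalled(self):
        with pytest.raises(ZeroDivisionError):
            ir.wald_test(_toy_fit([1.0], [0.0]), "t0")

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            ir.wald_test(_toy_fit([1.0], [1.0]), "nope")


class TestFoldChangeOR:
    def test_onefold_is_null(self):
        assert ir.fold_change_or(2.31, 1) == 1.0

    def test_unit_beta_at_e_fold(self):
        assert ir.fold_change_or(1.0, np.e) == pytest.approx(np.e, rel=1e-12)

    def test_ln4_beta_doubling(self):
        assert ir.fold_change_or(np.log(4), 2) == pytest.approx(
            np.exp(np.log(4) * np.log(2)), rel=1e-12
        )
        assert ir.fold_change_or(np.log(4), 2) == pytest.approx(2.6139, abs=5e-4)

    def test_multiplicative_in_fold(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            beta = rng.normal()
            n1, n2 = rng.uniform(0.1, 10, 2)
            assert ir.fold_change_or(beta, n1 * n2) == pytest.approx(
                ir.fold_change_or(beta, n1) * ir.fold_change_or(beta, n2), rel=1e-12
            )

    def test_invalid_fold(self):
        with pytest.raises(ValueError):
            ir.fold_change_or(1.0, 0.0)


def test_odds_ratio_table_is_consistent():
    fit = _toy_fit([0.5, -0.2], [0.1, 0.4])
    table = fit.odds_ratios()
    assert np.allclose(table["OR"], np.exp(fit.beta))
    assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
    assert (table["OR_lo"] <= table["OR"]).all() and (table["OR"] <= table["OR_hi"]).all()


def test_covariate_set_definitions_match_protocol():
    """The nine sets follow the published enumeration."""
    assert set(COVARIATE_SETS) == set(range(1, 10))
    baseline = COVARIATE_SETS[1].features
    assert baseline == (
        "source", "sex", "family_history", "hla_group", "age_initial", "age_confirm"
    )
    assert COVARIATE_SETS[4].features == COVARIATE_SETS[2].features + COVARIATE_SETS[3].features
    assert COVARIATE_SETS[7].features == COVARIATE_SETS[5].features + COVARIATE_SETS[6].features
    assert COVARIATE_SETS[8].features == baseline + COVARIATE_SETS[4].features
    assert COVARIATE_SETS[9].features == baseline + COVARIATE_SETS[7].features
    assert ir.THIRD_VISIT_SET.features == tuple(f"lnlvl_t0_{ab}" for ab in ir.ANTIBODIES)
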