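"""Proportional-odds fitting: closed-form threshold cases, a brute-force
likelihood oracle, an independent statsmodels cross-check, and the
likelihood-ratio test contract."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ordmi import (InteractionTerm, MaskedTable, ModelTerms, OrdinalRegression,
                   Schema, VariableSpec, fit_ordinal, lr_test)


def _schema(extra_pred=True):
    specs = []
    if extra_pred:
        specs.append(VariableSpec("x", "binary", ("no", "yes"), "no"))
    specs.append(VariableSpec("sev", "ordinal", ("lo", "mid", "hi"),
                              role="outcome"))
    return Schema(specs)


def _table(x_vals, y_vals):
    return MaskedTable(_schema(), pd.DataFrame({"x": x_vals, "sev": y_vals}))


class TestFitOrdinal:
    def test_intercept_only_thresholds_are_cumulative_logits(self):
        y = ["lo"] * 25 + ["mid"] * 50 + ["hi"] * 25
        t = MaskedTable(_schema(False), pd.DataFrame({"sev": y}))
        fit = fit_ordinal(t, ModelTerms([], []))
        assert fit.thresholds == pytest.approx([-1.0986123, 1.0986123],
                                               abs=1e-5)

    def test_balanced_predictor_coefficient_is_zero(self):
        # outcome distribution identical in both x groups
        x, y = [], []
        for g in ("no", "yes"):
            x += [g] * 12
            y += ["lo"] * 4 + ["mid"] * 4 + ["hi"] * 4
        fit = fit_ordinal(_table(x, y), ModelTerms(["x"], []))
        assert abs(fit.params["x=yes"]) < 1e-5

    def test_matches_brute_force_likelihood_maximum(self):
        """Single binary predictor: grid-search the 3-parameter likelihood
        on the 2x3 contingency table and compare."""
        counts = {("no", "lo"): 20, ("no", "mid"): 30, ("no", "hi"): 10,
                  ("yes", "lo"): 8, ("yes", "mid"): 22, ("yes", "hi"): 25}
        x = [g for (g, lev), c in counts.items() for _ in range(c)]
        y = [lev for (g, lev), c in counts.items() for _ in range(c)]
        fit = fit_ordinal(_table(x, y), ModelTerms(["x"], []))

        def nll(params):
            beta, t1, gap = params
            theta = np.array([t1, t1 + abs(gap)])
            ll = 0.0
            for (g, lev), c in counts.items():
                eta = beta * (g == "yes")
                cum = 1 / (1 + np.exp(-(theta - eta)))
                probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
                ll += c * np.log(probs[["lo", "mid", "hi"].index(lev)])
            return -ll

        res = optimize.minimize(nll, [0.0, -0.5, 1.0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert fit.params["x=yes"] == pytest.approx(res.x[0], abs=1e-4)
        assert fit.llf == pytest.approx(-res.fun, abs=1e-6)

    def test_against_statsmodels_ordered_model(self, rng):
        """Independent cross-check of estimates, SEs and thresholds."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        n = 400
        X = rng.normal(size=(n, 3))
        lp = X @ np.array([0.8, -0.5, 0.0])
        y = np.digitize(lp + rng.logistic(size=n), [-0.7, 0.9])
        est = OrdinalRegression().fit(X, y)
        sm_model = OrderedModel(y, X, distr="logit")
        sm_res = sm_model.fit(method="bfgs", maxiter=500, disp=False)
        assert np.allclose(est.coef_, np.asarray(sm_res.params[:3]), atol=1e-4)
        assert np.allclose(est.se_, np.asarray(sm_res.bse[:3]), atol=1e-4)
        assert np.allclose(
            est.thresholds_,
            np.asarray(sm_model.transform_threshold_params(sm_res.params))[1:-1],
            atol=1e-4)
        assert est.llf_ == pytest.approx(float(sm_res.llf), abs=1e-5)

    def test_coefficient_recovery_on_generated_data(self, rng):
        n = 2000
        x = rng.normal(size=n)
        beta = 0.9
        y = np.digitize(beta * x + rng.logistic(size=n), [-1.0, 1.0])
        est = OrdinalRegression().fit(pd.DataFrame({"x": x}), y)
        assert est.converged_
        assert abs(est.coef_[0] - beta) < 3 * est.se_[0]
        probs = est.predict_proba(pd.DataFrame({"x": x}))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_interaction_design_from_joint_variable_matches_products(self):
        """A carried joint interaction variable yields the same design as
        recomputing products from the factors (consistent data)."""
        from ordmi import code_for_fcs
        from ordmi.ordinal import build_design

        schema = Schema([
            VariableSpec("a", "binary", ("no", "yes"), "no"),
            VariableSpec("b", "binary", ("no", "yes"), "no"),
            VariableSpec("sev", "ordinal", ("1", "2", "3"), role="outcome"),
        ])
        combos = list(itertools.product(("no", "yes"), repeat=2)) * 3
        df = pd.DataFrame({"a": [c[0] for c in combos],
                           "b": [c[1] for c in combos],
                           "sev": np.resize(["1", "2", "3"], len(combos))})
        t = MaskedTable(schema, df)
        term = InteractionTerm(("a", "b"))
        terms = ModelTerms(["a", "b"], [term])
        X_plain, _ = build_design(t, terms)
        coded, _ = code_for_fcs(t, [term])
        X_joint, _ = build_design(coded, terms)
        pd.testing.assert_frame_equal(X_plain, X_joint)


class TestLrTest:
    @pytest.fixture()
    def fits(self, rng):
        n = 300
        x = rng.choice(["no", "yes"], n)
        z = rng.choice(["no", "yes"], n)
        eta = 0.8 * (x == "yes")
        y = np.array(["lo", "mid", "hi"])[
            np.digitize(eta + rng.logistic(size=n), [-0.5, 1.0])]
        schema = Schema([
            VariableSpec("x", "binary", ("no", "yes"), "no"),
            VariableSpec("z", "binary", ("no", "yes"), "no"),
            VariableSpec("sev", "ordinal", ("lo", "mid", "hi"),
                         role="outcome"),
        ])
        t = MaskedTable(schema, pd.DataFrame({"x": x, "z": z, "sev": y}))
        full = fit_ordinal(t, ModelTerms(["x", "z"], []))
        reduced = fit_ordinal(t, ModelTerms(["x"], []))
        return full, reduced

    def test_identical_models_give_zero_statistic(self, fits):
        full, _ = fits
        stat, df, p = lr_test(full, full)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 0 and p == 1.0

    def test_statistic_is_twice_the_loglik_difference(self, fits):
        full, reduced = fits
        stat, df, p = lr_test(full, reduced)
        assert stat == pytest.approx(2 * (full.llf - reduced.llf))
        assert df == 1

    def test_nested_loglik_never_exceeds_full(self, fits):
        full, reduced = fits
        assert reduced.llf <= full.llf + 1e-8

    def test_multi_category_term_df_equals_dummy_count(self, rng):
        n = 200
        schema = Schema([
            VariableSpec("inc", "nominal", ("a", "b", "c", "d"), "a"),
            VariableSpec("sev", "ordinal", ("lo", "mid", "hi"),
                         role="outcome"),
        ])
        df = pd.DataFrame({"inc": rng.choice(list("abcd"), n),
                           "sev": rng.choice(["lo", "mid", "hi"], n)})
        t = MaskedTable(schema, df)
        full = fit_ordinal(t, ModelTerms(["inc"], []))
        reduced = fit_ordinal(t, ModelTerms([], []))
        _, df_, _ = lr_test(full, reduced)
        assert df_ == 3

    def test_non_nested_fits_rejected(self, fits, rng):
        full, reduced = fits
        with pytest.raises(ValueError, match="nested"):
            lr_test(reduced, full)
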