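"""Rubin's rules against brute-force recomputation, the hand-worked pooling
case, KS diagnostics against an ECDF oracle, and the df-stability and
recommended-m lookups."""

import numpy as np
import pandas as pd
import pytest

from ordmi import (DAConfig, MaskedTable, ModelTerms, OrdinalFit, df_stability,
                   impute_mvni, ks_compare, recommended_m, rubin_pool, simulate)
from ordmi.synthetic import compact_design


def _fake_fit(estimates, ses, names=None):
    names = names or [f"c{i}" for i in range(len(estimates))]
    est = pd.Series(np.asarray(estimates, dtype=float), index=names)
    se = pd.Series(np.asarray(ses, dtype=float), index=names)
    return OrdinalFit(est, se, pd.DataFrame(), np.array([0.0, 1.0]), -1.0,
                      True, 100, ModelTerms(), {})


class TestRubinPool:
    def test_hand_computed_case(self):
        """Estimates (1,2,3) with unit variances: Qbar=2, W=1, B=1,
        T = 1 + (4/3)*1 = 2.3333, df = 2*(1 + 1/(4/3))^2 = 6.125."""
        fits = [_fake_fit([e], [1.0]) for e in (1.0, 2.0, 3.0)]
        pooled = rubin_pool(fits)
        row = pooled["c0"]
        assert row["estimate"] == pytest.approx(2.0)
        assert row["W"] == pytest.approx(1.0)
        assert row["B"] == pytest.approx(1.0)
        assert row["T"] == pytest.approx(2.0 + 1.0 / 3.0)
        assert row["df"] == pytest.approx(6.125)

    def test_zero_between_variance_gives_infinite_df(self):
        fits = [_fake_fit([1.0], [0.2]) for _ in range(3)]
        pooled = rubin_pool(fits)
        assert pooled["c0"]["B"] == 0.0
        assert pooled["c0"]["T"] == pytest.approx(0.04)
        assert np.isinf(pooled["c0"]["df"])

    def test_matches_brute_force_on_random_fit_lists(self, rng):
        for _ in range(1000):
            m = int(rng.integers(2, 8))
            k = int(rng.integers(1, 5))
            est = rng.normal(size=(m, k))
            ses = rng.uniform(0.1, 2.0, size=(m, k))
            pooled = rubin_pool([_fake_fit(est[i], ses[i]) for i in range(m)])
            for j in range(k):
                q = sum(est[i, j] for i in range(m)) / m
                w = sum(ses[i, j] ** 2 for i in range(m)) / m
                b = sum((est[i, j] - q) ** 2 for i in range(m)) / (m - 1)
                t_ = w + (1 + 1 / m) * b
                df = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
                row = pooled[f"c{j}"]
                assert abs(row["estimate"] - q) < 1e-12
                assert abs(row["W"] - w) < 1e-12
                assert abs(row["B"] - b) < 1e-12
                assert abs(row["T"] - t_) < 1e-12
                assert abs(row["df"] - df) < 1e-9 * max(df, 1.0)

    def test_pooled_se_at_least_within_se(self, rng):
        est = rng.normal(size=(5, 3))
        ses = rng.uniform(0.1, 1.0, size=(5, 3))
        pooled = rubin_pool([_fake_fit(est[i], ses[i]) for i in range(5)])
        assert np.all(pooled.table["se"] ** 2 >= pooled.table["W"] - 1e-12)

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            rubin_pool([_fake_fit([1.0], [1.0])])

    def test_mismatched_terms_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            rubin_pool([_fake_fit([1.0], [1.0], ["a"]),
                        _fake_fit([1.0], [1.0], ["b"])])


def _ks_fixture(observed, imputed_per_set):
    """A one-variable table with missing cells plus a handmade stack."""
    from ordmi import ImputedStack, Schema, VariableSpec

    schema = Schema([
        VariableSpec("v", "continuous"),
        VariableSpec("out", "ordinal", ("a", "b", "c"), role="outcome"),
    ])
    n_miss = len(imputed_per_set[0])
    n = len(observed) + n_miss
    v = np.concatenate([observed, np.full(n_miss, np.nan)])
    out = np.resize(["a", "b", "c"], n)
    t = MaskedTable(schema, pd.DataFrame({"v": v, "out": out}))
    datasets = []
    for imp in imputed_per_set:
        d = t.copy()
        d.data.loc[len(observed):, "v"] = np.asarray(imp, dtype=float)
        datasets.append(d)
    return t, ImputedStack(datasets, "mvni")


class TestKsCompare:
    def test_d_matches_brute_force_ecdf_gap(self, rng):
        for _ in range(20):
            obs = rng.normal(size=30)
            imp = rng.normal(0.5, 1.2, size=20)
            t, stack = _ks_fixture(obs, [imp])
            report = ks_compare(t, stack, min_missing_pct=8.0)
            d = report.rows[0]["D"]
            pooled = imp
            grid = np.sort(np.concatenate([obs, pooled]))
            ecdf_o = np.searchsorted(np.sort(obs), grid, side="right") / len(obs)
            ecdf_i = np.searchsorted(np.sort(pooled), grid,
                                     side="right") / len(pooled)
            assert d == pytest.approx(np.max(np.abs(ecdf_o - ecdf_i)))

    def test_identical_samples_give_zero_d(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        t, stack = _ks_fixture(obs, [obs.copy(), obs.copy()])
        report = ks_compare(t, stack, min_missing_pct=8.0)
        assert report.rows[0]["D"] == 0.0

    def test_disjoint_supports_give_d_one(self):
        t, stack = _ks_fixture(np.array([0.0, 0.1, 0.2]), [[5.0, 5.1]])
        report = ks_compare(t, stack, min_missing_pct=8.0)
        assert report.rows[0]["D"] == 1.0

    def test_only_heavily_missing_variables_examined(self):
        t = simulate(compact_design(n=250), seed=13)
        stack = impute_mvni(t, [], DAConfig(m=3, k=3, seed=7))
        report = ks_compare(t, stack, min_missing_pct=8.0)
        examined = {r["variable"] for r in report.rows}
        pct = 100.0 * t.mask.mean(axis=0)
        assert examined == set(pct[pct > 8.0].index)


class TestDfStability:
    def test_large_df_is_stable(self):
        fits = [_fake_fit([1.0, 2.0], [1.0, 1.0]) for _ in range(3)]
        pooled = rubin_pool(fits)
        pooled.table.loc[:, "df"] = [130.54, 25.0]
        flags = df_stability(pooled, m=20, c=3.0)
        assert bool(flags.iloc[0]) is True     # 130.54 >= 60
        assert bool(flags.iloc[1]) is False    # 25 < 60

    def test_infinite_df_is_stable(self):
        fits = [_fake_fit([1.0], [0.5]) for _ in range(4)]
        pooled = rubin_pool(fits)
        assert bool(df_stability(pooled, m=20).iloc[0]) is True


class TestRecommendedM:
    @pytest.mark.parametrize("frac,expected", [
        (0.0, 20), (0.053, 20), (0.1, 20), (0.2, 20), (0.3, 20),
        (0.4, 40), (0.5, 40), (0.6, 100), (0.7, 100),
    ])
    def test_band_lookup(self, frac, expected):
        m = recommended_m(frac)
        assert int(m) == expected
        assert m.open_ended is False

    def test_top_band_open_ended(self):
        m = recommended_m(0.9)
        assert int(m) == 100 and m.open_ended is True

    @pytest.mark.parametrize("frac", [-0.1, 1.0, 1.5])
    def test_out_of_range_rejected(self, frac):
        with pytest.raises(ValueError):
            recommended_m(frac)
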