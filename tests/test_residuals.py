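"""Martingale, deviance, OTE and OLRR residuals and their invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teres import (
    SurvivalResidualizer,
    WeibullFit,
    compute_residuals,
    deviance,
    g_function,
    martingale,
    modified_martingale,
    olrr,
    ote,
    simulate_study,
    standardize,
)

LN2 = math.log(2.0)


class TestScalarResiduals:
    def test_martingale_examples(self):
        assert martingale(1, 1.0) == 0.0
        assert martingale(0, 0.3859) == pytest.approx(-0.3859)
        with pytest.raises(ValueError):
            martingale(1, -0.1)

    def test_censored_vs_uncensored_gap_is_exactly_one(self, example_fit):
        """Same time, same survival model: MR differs by exactly 1."""
        for t in (2.0, 10.0, 15.0, 25.0):
            chf = example_fit.chf(t)
            assert martingale(1, chf) - martingale(0, chf) == pytest.approx(1.0, abs=1e-15)

    def test_deviance_examples(self):
        assert deviance(0.0, 1) == 0.0
        assert deviance(-0.3859, 0) == pytest.approx(-0.8785, abs=1e-4)
        assert deviance(0.5, 1) == pytest.approx(0.6215, abs=1e-4)

    def test_deviance_domain(self):
        with pytest.raises(ValueError):
            deviance(1.0, 1)  # uncensored MR must stay below 1
        with pytest.raises(ValueError):
            deviance(0.2, 0)  # censored MR cannot be positive

    def test_modified_martingale_examples(self):
        assert modified_martingale(LN2) == 0.0
        assert modified_martingale(0.0) == pytest.approx(0.6931, abs=1e-4)
        assert modified_martingale(1.0791) == pytest.approx(-0.3859, abs=1e-4)

    def test_ote_examples(self):
        assert ote(0.0) == 0.0
        # evaluation time 13.15 under Weibull(12.89, 3.75)
        assert ote(LN2 - 1.0791154) == pytest.approx(-0.3978, abs=1e-4)
        with pytest.raises(ValueError):
            ote(LN2)  # CHF = 0, i.e. evaluation time 0, is out of domain

    def test_olrr_examples(self):
        assert olrr(11.69, 11.69) == 0.0
        assert olrr(11.69, 13.15) == pytest.approx(-1.46)
        assert olrr(11.69, 10.0) == pytest.approx(1.69)
        with pytest.raises(ValueError):
            olrr(11.69, 0.0)


class TestGFunction:
    @settings(max_examples=100, deadline=None)
    @given(x=st.floats(1e-6, 50.0), b=st.floats(0.05, 5.0))
    def test_nonpositive_with_max_at_b(self, x, b):
        assert g_function(x, b) <= 1e-12
        assert g_function(b, b) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(x=st.floats(1e-3, 20.0))
    def test_deviance_is_g_at_b_equal_one(self, x):
        """For uncensored individuals (b = 1, so b log b = 0), the deviance
        residual equals sign(1 - x) * sqrt(-2 g(x))."""
        mr = 1.0 - x
        via_g = np.sign(1.0 - x) * math.sqrt(max(-2.0 * g_function(x, b=1.0), 0.0))
        assert deviance(mr, 1) == pytest.approx(via_g, abs=1e-12)

    def test_ote_is_g_at_b_ln2(self):
        x = np.linspace(0.05, 5.0, 50)
        via_g = np.sign(LN2 - x) * np.sqrt(-2.0 * g_function(x))
        np.testing.assert_allclose(ote(LN2 - x), via_g, atol=1e-12)


class TestComputeResiduals:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["time", "status", "covariate"])

    def test_worked_three_individual_scenario(self, example_fit):
        """Censored at 10 and uncensored at t_pred(10) share the same OTE;
        the uncensored individual whose DR matches sits at a later time and
        gets the most negative OTE."""
        t_pred = example_fit.predicted_median(10.0)
        t_match = 15.8142  # uncensored time with the same DR as censored@10
        data = self._table([[10.0, 0, 1], [t_match, 1, 1], [t_pred, 1, 1]])
        res = compute_residuals(data, {1: example_fit})
        assert res.loc[0, "ote"] == pytest.approx(res.loc[2, "ote"], abs=1e-12)
        assert res.loc[0, "dr"] == pytest.approx(res.loc[1, "dr"], abs=1e-3)
        assert res.loc[1, "ote"] < res.loc[0, "ote"] < 0
        assert res.loc[0, "t_star"] == pytest.approx(t_pred)

    def test_censored_near_zero_gives_near_zero_ote(self, example_fit):
        data = self._table([[1e-6, 0, 1]])
        res = compute_residuals(data, {1: example_fit})
        assert abs(res.loc[0, "ote"]) < 1e-6

    def test_censored_residuals_nonpositive(self, example_fit, rng):
        t = rng.uniform(0.5, 30.0, 500)
        data = self._table(np.column_stack([t, np.zeros(500), np.ones(500)]))
        res = compute_residuals(data, {1: example_fit})
        assert (res["mr"] <= 0).all()
        assert (res["dr"] <= 0).all()
        assert (res["ote"] <= 0).all()

    def test_ote_zero_iff_tstar_at_median(self, example_fit):
        data = self._table(
            [[example_fit.median, 1, 1], [example_fit.median - 1, 1, 1],
             [example_fit.median + 1, 1, 1]]
        )
        res = compute_residuals(data, {1: example_fit})
        assert res.loc[0, "ote"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[1, "ote"] > 0
        assert res.loc[2, "ote"] < 0

    def test_ote_sign_tracks_median(self, example_fit, rng):
        t = rng.uniform(0.5, 30.0, 300)
        data = self._table(np.column_stack([t, np.ones(300), np.ones(300)]))
        res = compute_residuals(data, {1: example_fit})
        early = res["t_star"] < example_fit.median
        assert ((res["ote"] > 0) == early).all()
        assert ((res["olrr"] > 0) == early).all()

    def test_rank_order_equivalence_on_mixed_grid(self, example_fit, rng):
        """OTE, OLRR and t* produce identical orderings over a mixed
        censored/uncensored grid of 1,000 evaluation times."""
        t = np.linspace(0.5, 30.0, 1000)
        status = rng.integers(0, 2, 1000)
        data = self._table(np.column_stack([t, status, np.ones(1000)]))
        res = compute_residuals(data, {1: example_fit})
        order_t = np.argsort(-res["t_star"].to_numpy(), kind="stable")
        order_ote = np.argsort(res["ote"].to_numpy(), kind="stable")
        order_olrr = np.argsort(res["olrr"].to_numpy(), kind="stable")
        np.testing.assert_array_equal(order_t, order_ote)
        np.testing.assert_array_equal(order_t, order_olrr)

    def test_dr_monotone_in_mr_within_strata(self, example_fit):
        t = np.linspace(0.5, 30.0, 500)
        for status in (0, 1):
            data = self._table(
                np.column_stack([t, np.full(500, status), np.ones(500)])
            )
            res = compute_residuals(data, {1: example_fit})
            mr_order = np.argsort(res["mr"].to_numpy())
            dr_sorted = res["dr"].to_numpy()[mr_order]
            assert np.all(np.diff(dr_sorted) > 0)

    def test_missing_fit_for_level(self, example_fit):
        data = self._table([[5.0, 1, 1], [6.0, 1, 2]])
        with pytest.raises(KeyError):
            compute_residuals(data, {1: example_fit})

    def test_per_level_quantities_use_own_fit(self):
        fits = {1: WeibullFit(12.89, 3.75, level=1), 2: WeibullFit(15.0, 3.75, level=2)}
        data = self._table([[10.0, 0, 1], [10.0, 0, 2]])
        res = compute_residuals(data, fits)
        assert res.loc[0, "t_star"] == pytest.approx(fits[1].predicted_median(10.0))
        assert res.loc[1, "t_star"] == pytest.approx(fits[2].predicted_median(10.0))
        assert res.loc[0, "ote"] != res.loc[1, "ote"]


class TestStandardize:
    def test_mean_zero_sd_one_within_levels(self, rng):
        data = simulate_study(2, n=400, seed=rng)
        table = SurvivalResidualizer(standardize=False).fit_transform(data)
        std = standardize(table)
        for _, sub in std.groupby("covariate"):
            for kind in ("mr", "dr", "mmr", "ote", "olrr"):
                assert abs(sub[kind + "_std"].mean()) < 1e-10
                assert sub[kind + "_std"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_preserves_within_level_rank_order(self, rng):
        data = simulate_study(2, n=400, seed=rng)
        std = SurvivalResidualizer().fit_transform(data)
        for _, sub in std.groupby("covariate"):
            np.testing.assert_array_equal(
                np.argsort(sub["ote"].to_numpy()), np.argsort(sub["ote_std"].to_numpy())
            )

    def test_zero_variance_names_the_level(self, example_fit):
        table = pd.DataFrame(
            {"time": [5.0, 5.0], "status": [1, 1], "covariate": [1, 1]}
        )
        res = compute_residuals(table, {1: example_fit})
        with pytest.raises(ValueError, match="level 1"):
            standardize(res)

    def test_raw_ote_level_mean_near_zero_on_large_samples(self):
        """Self-fitted OTE residuals centre themselves: the raw within-level
        mean is approximately 0, so standardization is close to a pure
        rescaling."""
        data = simulate_study(1, n=4000, seed=7)
        table = SurvivalResidualizer(standardize=False).fit_transform(data)
        for _, sub in table.groupby("covariate"):
            assert abs(sub["ote"].mean()) < 0.05


class TestSurvivalResidualizer:
    def test_fit_transform_augments_input(self, rng):
        data = simulate_study(1, n=300, seed=rng)
        out = SurvivalResidualizer().fit_transform(data)
        assert set(data.columns) <= set(out.columns)
        for kind in ("mr", "dr", "mmr", "ote", "olrr"):
            assert kind in out.columns and kind + "_std" in out.columns
        assert len(out) == len(data)

    def test_selected_kinds_only(self, rng):
        data = simulate_study(1, n=300, seed=rng)
        out = SurvivalResidualizer(kinds=("ote",), standardize=False).fit_transform(data)
        assert "ote" in out.columns and "mr" not in out.columns

    def test_fits_one_model_per_level(self, rng):
        data = simulate_study(1, n=300, seed=rng)
        est = SurvivalResidualizer().fit(data)
        assert set(est.fits_) == {1, 2}
        assert est.fits_[1].level == 1

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = SurvivalResidualizer(kinds=("ote",), standardize=False)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_transform_before_fit_raises(self, rng):
        data = simulate_study(1, n=300, seed=rng)
        with pytest.raises(RuntimeError):
            SurvivalResidualizer().transform(data)

    def test_unknown_kind_rejected(self, rng):
        data = simulate_study(1, n=300, seed=rng)
        with pytest.raises(ValueError):
            SurvivalResidualizer(kinds=("schoenfeld",)).fit_transform(data)
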