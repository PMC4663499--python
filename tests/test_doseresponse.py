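"""4PL fitting, ICx inversion, relative potency and curve comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamtox import (
    FitError,
    ICxNotReachedError,
    Truth4PL,
    bootstrap_icx,
    compare_ic50_ftest,
    fit_4pl,
    geometric_dose_series,
    goodness_of_fit,
    invert_icx,
    logistic4,
    relative_potency,
    relative_potency_table,
    simulate_single_assay,
)
from pamtox.datasets import inhibition_endpoints
from pamtox.validation import grid_fit_4pl


def exact_dataset(truth: Truth4PL, n_rep: int = 3) -> np.ndarray:
    doses = geometric_dose_series(truth.ic50)
    return np.array(
        [[d, truth.inhibition(d)] for d in doses for _ in range(n_rep)]
    )


class TestFit4PL:
    def test_noiseless_recovery_is_exact(self, noiseless_curve):
        truth, data = noiseless_curve
        fit = fit_4pl(data)
        assert fit.bottom == pytest.approx(truth.bottom, abs=1e-6)
        assert fit.top == pytest.approx(truth.top, abs=1e-6)
        assert fit.hill == pytest.approx(truth.hill, rel=1e-6)
        assert fit.ic50 == pytest.approx(truth.ic50, rel=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("hill", [0.6, 1.0, 2.5])
    @pytest.mark.parametrize("ic50", [0.5, 10.0, 250.0])
    def test_oracle_equivalence_on_noiseless_curves(self, hill, ic50):
        """The LM fitter and the independent grid+bisection SS minimiser agree."""
        truth = Truth4PL(5.0, 95.0, hill, ic50)
        data = exact_dataset(truth)
        fit = fit_4pl(data)
        oracle = grid_fit_4pl(data[:, 0], data[:, 1])
        assert abs(fit.ic50 - oracle.ic50) / oracle.ic50 < 1e-4

    def test_degenerate_flat_data_is_fit_failure(self):
        doses = np.repeat(geometric_dose_series(10.0), 3)
        flat = np.column_stack([doses, np.full(doses.size, 40.0)])
        with pytest.raises(FitError):
            fit_4pl(flat)

    def test_too_few_doses_rejected(self):
        data = np.array([[1.0, 10.0], [10.0, 50.0], [100.0, 90.0]])
        with pytest.raises(FitError):
            fit_4pl(data)

    def test_controls_excluded_from_fit(self, noiseless_curve):
        truth, data = noiseless_curve
        with_controls = np.vstack([data, [[0.0, 0.0], [0.0, 0.0]]])
        fit = fit_4pl(with_controls)
        assert fit.n_obs == len(data)
        assert fit.ic50 == pytest.approx(truth.ic50, rel=1e-8)

    def test_decreasing_data_warns(self):
        truth = Truth4PL(100.0, 0.0, 1.0, 10.0)  # decreasing: 100% down to 0%
        doses = geometric_dose_series(10.0)
        data = np.array([[d, truth.inhibition(d)] for d in doses for _ in range(2)])
        with pytest.warns(UserWarning, match="non-increasing"):
            fit_4pl(data)

    def test_dataframe_metadata_is_carried(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "diuron")
        fit = fit_4pl(df)
        assert fit.treatment_id == "diuron"
        assert fit.duration_h == 24.0
        assert fit.df == fit.n_obs - 4

    def test_constrained_mode_pins_asymptotes(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "diuron")
        fit = fit_4pl(df, constrain=True)
        assert fit.bottom == 0.0 and fit.top == 100.0
        assert fit.df == fit.n_obs - 2


class TestInvertICx:
    def test_ic50_is_fixed_point_when_symmetric(self):
        fit = fit_4pl(exact_dataset(Truth4PL(0.0, 100.0, 1.0, 10.0)))
        est = invert_icx(fit, 50.0)
        assert est.value == pytest.approx(10.0, rel=1e-8)

    def test_ic10_closed_form(self):
        fit = fit_4pl(exact_dataset(Truth4PL(0.0, 100.0, 1.0, 10.0)))
        est = invert_icx(fit, 10.0)
        assert est.value == pytest.approx(10.0 * (10.0 / 90.0), rel=1e-8)

    @pytest.mark.parametrize("level", [10.0, 20.0, 50.0, 80.0])
    def test_round_trip_through_the_curve(self, level, demo_scenario):
        df = simulate_single_assay(demo_scenario, "atrazine")
        fit = fit_4pl(df)
        est = invert_icx(fit, level)
        assert fit.predict(est.value) == pytest.approx(level, abs=1e-9)

    def test_level_outside_span_not_reached(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "diuron")
        fit = fit_4pl(df)
        with pytest.raises(ICxNotReachedError):
            invert_icx(fit, fit.top + 5.0)

    def test_icx_monotone_in_level(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "ametryn")
        fit = fit_4pl(df)
        values = [invert_icx(fit, f).value for f in (10, 25, 50, 75)]
        assert values == sorted(values)
        assert invert_icx(fit, 10.0).value < invert_icx(fit, 50.0).value

    def test_ci_brackets_the_estimate(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "bromacil")
        est = invert_icx(fit_4pl(df), 50.0)
        assert est.ci_low <= est.value <= est.ci_high

    def test_bootstrap_ci_close_to_delta_ci(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "metribuzin")
        delta = invert_icx(fit_4pl(df), 50.0)
        boot = bootstrap_icx(df, 50.0, n_boot=300, seed=7)
        assert boot.value == pytest.approx(delta.value)
        # same order of magnitude of uncertainty, not identical by construction
        assert boot.ci_low < delta.value < boot.ci_high
        assert np.log10(boot.ci_high / boot.ci_low) < 3 * np.log10(
            delta.ci_high / delta.ci_low
        )


class TestRelativePotency:
    def test_published_ratio_examples(self):
        assert relative_potency(4.3, 132.0).rep == pytest.approx(0.033, abs=5e-4)
        assert relative_potency(4.3, 3.5).rep == pytest.approx(1.23, abs=5e-3)
        assert relative_potency(4.3, 4.3).rep == 1.0

    @given(
        a=st.floats(1e-3, 1e3),
        b=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_swap(self, a, b):
        assert relative_potency(a, b).rep * relative_potency(b, a).rep == pytest.approx(
            1.0
        )

    def test_table_uses_24h_reference_for_all_rows(self):
        ep = inhibition_endpoints()
        table = relative_potency_table(ep)
        row = table[(table["herbicide"] == "ametryn") & (table["duration_h"] == 48)]
        assert row["rep"].iloc[0] == pytest.approx(4.3 / 3.5)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            relative_potency(0.0, 1.0)


class TestFTest:
    def test_identical_datasets_give_f_near_zero(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "diuron")
        res = compare_ic50_ftest([df, df.copy()])
        assert res.f_stat == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.99

    def test_separated_noiseless_curves_reject_decisively(self):
        d1 = exact_dataset(Truth4PL(0.0, 100.0, 1.0, 10.0))
        d2 = exact_dataset(Truth4PL(0.0, 100.0, 1.0, 20.0))
        res = compare_ic50_ftest([d1, d2])
        assert res.p_value < 1e-10
        assert res.ss_full < 1e-10 or res.f_stat > 1e6

    def test_posthoc_table_has_all_pairs(self, demo_scenario):
        dfs = [
            simulate_single_assay(demo_scenario.with_seed(s), "atrazine")
            for s in (1, 2, 3, 4)
        ]
        res = compare_ic50_ftest(dfs)
        assert len(res.pairwise) == 6
        assert {"p", "p_holm", "significant"} <= set(res.pairwise.columns)
        assert (res.pairwise["p_holm"] >= res.pairwise["p"] - 1e-15).all()

    def test_separate_all_scheme_runs(self, demo_scenario):
        dfs = [
            simulate_single_assay(demo_scenario.with_seed(s), "diuron")
            for s in (5, 6)
        ]
        res = compare_ic50_ftest(dfs, sharing="separate_all")
        assert res.df1 == 1
        assert res.sharing == "separate_all"

    def test_fewer_than_two_datasets_rejected(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "diuron")
        with pytest.raises(ValueError):
            compare_ic50_ftest([df])


class TestGoodnessOfFit:
    def test_noiseless_r2_is_one(self, noiseless_curve):
        _, data = noiseless_curve
        assert goodness_of_fit(fit_4pl(data)) == pytest.approx(1.0, abs=1e-12)

    def test_noisy_r2_below_one_but_high(self, demo_scenario):
        df = simulate_single_assay(demo_scenario, "tebuthiuron")
        r2 = goodness_of_fit(fit_4pl(df))
        assert 0.9 < r2 < 1.0


def test_logistic4_monotone_increasing_for_positive_hill():
    x = np.geomspace(0.01, 100, 50)
    y = logistic4(x, 0.0, 100.0, 1.3, 5.0)
    assert np.all(np.diff(y) > 0)
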