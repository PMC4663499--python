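"""Toxic-Unit arithmetic, mixture design and the CA additivity decision rule."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamtox import (
    MixtureSpec,
    ToxicUnitTable,
    Truth4PL,
    ca_expected_curve,
    classify_additivity,
    design_mixture_series,
    fit_4pl,
    percent_lower,
    simulate_mixture_assay,
    toxic_units,
    tu_sum,
)


class TestToxicUnits:
    @pytest.mark.parametrize(
        "conc, ic50, expected",
        [(4.3, 4.3, 1.0), (0.0, 4.3, 0.0), (11.0, 22.0, 0.5)],
    )
    def test_definition(self, conc, ic50, expected):
        assert toxic_units(conc, ic50) == pytest.approx(expected)

    def test_missing_herbicide_is_lookup_error(self, tu_table_24h):
        with pytest.raises(KeyError, match="glyphosate"):
            tu_sum([("glyphosate", 1.0)], tu_table_24h)

    def test_tu_sum_of_binary_half_half(self, tu_table_24h):
        # half an IC50 of each component adds to exactly 1 TU
        assert tu_sum(
            [("diuron", 4.3 / 2), ("atrazine", 22.0 / 2)], tu_table_24h
        ) == pytest.approx(1.0)

    def test_tu_sum_ten_components_at_tenth(self, tu_table_24h):
        comps = [(h, ic50 / 10) for h, ic50 in tu_table_24h.entries.items()]
        assert tu_sum(comps, tu_table_24h) == pytest.approx(1.0)

    def test_empty_mixture_is_zero(self, tu_table_24h):
        assert tu_sum([], tu_table_24h) == 0.0

    @given(split=st.integers(0, 10))
    @settings(max_examples=20, deadline=None)
    def test_linear_over_disjoint_partitions(self, split, tu_table_24h):
        comps = [(h, 0.7 * ic50) for h, ic50 in tu_table_24h.entries.items()]
        a, b = comps[:split], comps[split:]
        assert tu_sum(a, tu_table_24h) + tu_sum(b, tu_table_24h) == pytest.approx(
            tu_sum(comps, tu_table_24h)
        )


class TestMixtureDesign:
    def test_equal_binary_doses_at_one_tu(self, tu_table_24h, binary_mixture_spec):
        table = design_mixture_series(binary_mixture_spec, tu_table_24h)
        at1 = table[table["tu_level"] == 1.0].set_index("component")
        assert at1.loc["diuron", "concentration_ugL"] == pytest.approx(4.3 / 2)
        assert at1.loc["atrazine", "concentration_ugL"] == pytest.approx(22.0 / 2)

    def test_ten_way_mix_diuron_dose_at_one_tu(self, tu_table_24h):
        spec = MixtureSpec.equal_proportions(
            "10-mix", sorted(tu_table_24h.entries)
        )
        table = design_mixture_series(spec, tu_table_24h)
        row = table[(table["tu_level"] == 1.0) & (table["component"] == "diuron")]
        assert row["concentration_ugL"].iloc[0] == pytest.approx(0.43)

    def test_zero_level_gives_zero_concentrations(self, tu_table_24h, binary_mixture_spec):
        table = design_mixture_series(binary_mixture_spec, tu_table_24h)
        assert (table.loc[table["tu_level"] == 0.0, "concentration_ugL"] == 0).all()

    def test_design_round_trips_through_tu_sum(self, tu_table_24h):
        """Every designed row set reproduces its nominal TU level exactly."""
        spec = MixtureSpec.equal_proportions(
            "10-mix", sorted(tu_table_24h.entries)
        )
        table = design_mixture_series(spec, tu_table_24h)
        for level, grp in table.groupby("tu_level"):
            comps = list(zip(grp["component"], grp["concentration_ugL"]))
            assert tu_sum(comps, tu_table_24h) == pytest.approx(level, abs=1e-12)

    def test_mismatched_duration_basis_rejected(self, binary_mixture_spec):
        table_48 = ToxicUnitTable(entries={"diuron": 4.3, "atrazine": 22.0}, duration_h=48.0)
        with pytest.raises(ValueError, match="bases must match"):
            design_mixture_series(binary_mixture_spec, table_48)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec("bad", (("diuron", 0.5), ("atrazine", 0.4)))


class TestCAExpectedCurve:
    @pytest.fixture()
    def tu_reference_fit(self):
        truth = Truth4PL(0.0, 100.0, 1.3, 1.0)
        doses = np.geomspace(1 / 30, 30, 7)
        data = pd.DataFrame(
            {
                "dose": np.repeat(doses, 3),
                "inhibition": np.repeat(truth.inhibition(doses), 3),
                "dose_scale": "TU",
            }
        )
        return fit_4pl(data, dose_scale="TU")

    def test_ca_null_is_fifty_percent_at_one_tu(self, tu_reference_fit):
        curve = ca_expected_curve(tu_reference_fit)
        assert curve(1.0) == pytest.approx(50.0, abs=1e-6)

    def test_limits_are_the_asymptotes(self, tu_reference_fit):
        curve = ca_expected_curve(tu_reference_fit)
        assert curve(1e-12) == pytest.approx(tu_reference_fit.bottom, abs=1e-6)
        assert curve(1e12) == pytest.approx(tu_reference_fit.top, abs=1e-6)

    def test_concentration_scale_fit_rejected(self, demo_scenario):
        from pamtox import simulate_single_assay

        fit = fit_4pl(simulate_single_assay(demo_scenario, "diuron"))
        with pytest.raises(ValueError, match="TU"):
            ca_expected_curve(fit)


class TestClassifyAdditivity:
    def refs(self, scenario, table):
        specs = [
            MixtureSpec.equal_proportions("diuron+diuron", ["diuron", "diuron"]),
            MixtureSpec.equal_proportions("atrazine+atrazine", ["atrazine", "atrazine"]),
        ]
        return [simulate_mixture_assay(scenario, s, table) for s in specs]

    def test_ca_null_mixture_classified_additive(
        self, demo_scenario, tu_table_24h, binary_mixture_spec
    ):
        mix = simulate_mixture_assay(demo_scenario, binary_mixture_spec, tu_table_24h)
        res = classify_additivity(
            mix, self.refs(demo_scenario, tu_table_24h), mixture_id="diuron+atrazine"
        )
        assert res.classification == "additive"
        assert res.rule == "reference_ftest"
        assert 0.8 < res.ic50_tu < 1.2

    def test_double_potency_classified_synergistic(
        self, demo_scenario, tu_table_24h, binary_mixture_spec
    ):
        hot = dataclasses.replace(demo_scenario, seed=99, deviation_factor=2.0)
        mix = simulate_mixture_assay(hot, binary_mixture_spec, tu_table_24h)
        res = classify_additivity(mix, self.refs(demo_scenario, tu_table_24h))
        assert res.classification == "synergistic"
        assert res.ic50_tu < 0.7

    def test_half_potency_classified_antagonistic(
        self, demo_scenario, tu_table_24h, binary_mixture_spec
    ):
        cold = dataclasses.replace(demo_scenario, seed=7, deviation_factor=0.5)
        mix = simulate_mixture_assay(cold, binary_mixture_spec, tu_table_24h)
        res = classify_additivity(mix, self.refs(demo_scenario, tu_table_24h))
        assert res.classification == "antagonistic"
        assert res.ic50_tu > 1.4

    @pytest.mark.parametrize(
        "ic50_tu, expected",
        [(1.0, "additive"), (0.5, "synergistic"), (2.0, "antagonistic")],
    )
    def test_no_references_falls_back_to_ci_rule(self, ic50_tu, expected):
        """Without sham references the CI-contains-1 rule decides, flagged as such."""
        truth = Truth4PL(0.0, 100.0, 1.0, ic50_tu)
        doses = np.geomspace(0.25, 4.0, 7)
        mix = pd.DataFrame(
            {
                "dose": np.repeat(doses, 3),
                "inhibition": np.repeat(truth.inhibition(doses), 3),
                "dose_scale": "TU",
            }
        )
        res = classify_additivity(mix, None)
        assert res.rule == "ci_contains_1"
        assert res.classification == expected

    def test_sham_self_mixture_matches_single_compound_scale(
        self, demo_scenario, tu_table_24h
    ):
        """Loewe self-consistency: [X+X] has IC50 ~ 1 TU like X itself."""
        sham = MixtureSpec.equal_proportions("diuron+diuron", ["diuron", "diuron"])
        res = classify_additivity(
            simulate_mixture_assay(demo_scenario, sham, tu_table_24h), None
        )
        assert res.ic50_tu == pytest.approx(1.0, abs=0.15)


def test_percent_lower_matches_published_mixture_comparison():
    # published mixture IC50s: test 0.85 TU vs references 0.90 / 0.95 TU
    assert round(percent_lower(0.85, 0.90)) == 6
    assert round(percent_lower(0.85, 0.95)) == 11
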