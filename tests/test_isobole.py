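"""Loewe-additive predictions, fraction indices, percent changes, isobologram export."""

import math

import pytest
from hypothesis import given, strategies as st

from isobolo.isobole import (
    AdditivityError,
    MixtureComponent,
    MixtureDesign,
    additive_ed50,
    experimental_mixture_ed50,
    fraction_breakdown,
    isobologram_coordinates,
    percent_change,
    round_half_away,
)
from isobolo.probit import PotencyEstimate


def potency(ed50, sem=float("nan"), n=16):
    return PotencyEstimate(
        ed50=ed50, sem=sem, cl95_lower=float("nan"), cl95_upper=float("nan"),
        slope=float("nan"), n_probit=n,
    )


def design(varied_ed50, adjuncts, varied_sem=float("nan"), varied_n=16):
    comps = tuple(
        MixtureComponent(f"A{i}", dose, potency(ed50, sem, n))
        for i, (dose, ed50, sem, n) in enumerate(adjuncts)
    )
    return MixtureDesign("V", potency(varied_ed50, varied_sem, varied_n), comps)


NAN = float("nan")


class TestAdditiveEd50:
    @pytest.mark.parametrize(
        "varied, dose, adjunct_ed50, expected_total",
        [
            (9.52, 25.0, 235.7, 33.51),   # carbamazepine + isopimpinellin 25
            (28.85, 50.0, 235.7, 72.73),  # phenobarbital + isopimpinellin 50
        ],
    )
    def test_published_additive_totals(self, varied, dose, adjunct_ed50, expected_total):
        pred = additive_ed50(design(varied, [(dose, adjunct_ed50, NAN, 28)]))
        assert pred.ed50_add_total == pytest.approx(expected_total, abs=0.01)

    def test_zero_adjunct_dose_reduces_to_drug_alone(self):
        pred = additive_ed50(design(9.52, [(0.0, 235.7, 23.5, 28)]))
        assert pred.ed50_add_total == 9.52
        assert pred.ed50_add_varied == 9.52

    def test_total_decomposes_into_varied_plus_fixed(self):
        pred = additive_ed50(design(28.85, [(25.0, 235.7, NAN, 28), (10.0, 120.0, NAN, 12)]))
        assert pred.ed50_add_total == pytest.approx(pred.ed50_add_varied + 35.0)

    @given(st.floats(min_value=0.0, max_value=100.0))
    def test_linear_in_adjunct_dose(self, dose):
        varied_ed50, adjunct_ed50 = 9.52, 235.7
        pred = additive_ed50(design(varied_ed50, [(dose, adjunct_ed50, NAN, 28)]))
        slope = varied_ed50 / adjunct_ed50
        assert pred.ed50_add_varied == pytest.approx(varied_ed50 - slope * dose, rel=1e-12)

    @given(
        st.floats(min_value=1.0, max_value=400.0),
        st.floats(min_value=0.05, max_value=0.4),
        st.floats(min_value=0.1, max_value=0.9),
    )
    def test_two_adjuncts_equal_one_pooled_adjunct_of_same_fraction(
        self, varied_ed50, total_fraction, split
    ):
        """Splitting the same total Loewe fraction over two adjuncts changes nothing."""
        e1, e2 = 100.0, 300.0
        d1 = split * total_fraction * e1
        d2 = (1 - split) * total_fraction * e2
        two = additive_ed50(design(varied_ed50, [(d1, e1, NAN, 8), (d2, e2, NAN, 8)]))
        pooled_ed50 = (d1 + d2) / total_fraction
        one = additive_ed50(design(varied_ed50, [(d1 + d2, pooled_ed50, NAN, 16)]))
        assert two.ed50_add_varied == pytest.approx(one.ed50_add_varied, rel=1e-12)
        assert two.ed50_add_total == pytest.approx(one.ed50_add_total, rel=1e-12)

    def test_sem_reduces_to_varied_sem_at_zero_adjunct_dose(self):
        pred = additive_ed50(design(9.52, [(0.0, 235.7, 23.5, 28)], varied_sem=1.5))
        assert pred.sem_add == pytest.approx(1.5, rel=1e-12)

    def test_delta_method_propagates_both_variances(self):
        pred = additive_ed50(design(9.52, [(25.0, 235.7, 23.5, 28)], varied_sem=1.5))
        f = 25.0 / 235.7
        expected = math.sqrt(
            (1 - f) ** 2 * 1.5**2 + (9.52 * 25.0 / 235.7**2) ** 2 * 23.5**2
        )
        assert pred.sem_add == pytest.approx(expected, rel=1e-12)

    def test_n_add_sums_component_probit_counts(self):
        pred = additive_ed50(design(292.0, [(50.0, 235.7, 23.5, 28)], varied_n=24))
        assert pred.n_add == 52

    def test_adjuncts_exceeding_additivity_refused(self):
        with pytest.raises(AdditivityError):
            design(9.52, [(300.0, 235.7, NAN, 28)])


class TestExperimentalMixture:
    @pytest.mark.parametrize(
        "ed50, fixed, expected",
        [(26.17, [25.0], 51.17), (8.44, [25.0], 33.44), (7.7, [], 7.7)],
    )
    def test_total_adds_fixed_doses(self, ed50, fixed, expected):
        exp = experimental_mixture_ed50(potency(ed50, 0.9, 24), fixed)
        assert exp.ed50_exp_total == pytest.approx(expected)
        assert exp.ed50_exp_varied == pytest.approx(ed50)

    def test_sem_and_n_carried_from_the_mixture_fit(self):
        exp = experimental_mixture_ed50(potency(26.17, 2.07, 16), [25.0])
        assert exp.sem_exp == 2.07
        assert exp.n_exp == 16


class TestFractionBreakdown:
    def test_published_three_drug_varied_fraction(self):
        # phenobarbital three-drug row: (62.25 - 50) / 28.85 -> 0.42
        d = design(28.85, [(25.0, 235.7, NAN, 28), (25.0, 250.0, NAN, 16)])
        exp = experimental_mixture_ed50(potency(12.25, 2.52, 24), [25.0, 25.0])
        fb = fraction_breakdown(exp, d)
        assert fb.fractions["V"] == pytest.approx(0.42)
        assert fb.fractions["A0"] == pytest.approx(0.11)
        assert fb.fractions["A1"] == pytest.approx(0.10)
        assert fb.fraction_index == pytest.approx(0.63)

    def test_additive_point_sums_to_one_exactly_unrounded(self):
        d = design(9.52, [(25.0, 235.7, NAN, 28)])
        pred = additive_ed50(d)
        exp = experimental_mixture_ed50(
            potency(pred.ed50_add_varied, 1.0, 16), [25.0]
        )
        fb = fraction_breakdown(exp, d)
        assert sum(fb.fractions_exact.values()) == pytest.approx(1.0, abs=1e-12)
        assert fb.fraction_index == pytest.approx(1.0, abs=0.01)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.105, 2) == 0.11
        assert round_half_away(0.115, 2) == 0.12
        assert round_half_away(-0.105, 2) == -0.11
        assert round_half_away(57.445, 2) == 57.45


class TestPercentChange:
    @pytest.mark.parametrize(
        "control, treated, expected",
        [
            (9.52, 7.32, 23),
            (292.0, 169.0, 42),
            (28.85, 12.25, 58),
            (10.0, 10.0, 0),
            (10.0, 12.0, -20),
        ],
    )
    def test_values(self, control, treated, expected):
        assert percent_change(control, treated) == expected

    def test_sign_flips_around_equality(self):
        assert percent_change(10.0, 8.0) == -percent_change(10.0, 12.0)

    def test_nonpositive_control_raises(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)


class TestIsobologramCoordinates:
    def test_two_drug_points_from_published_values(self):
        d = design(9.52, [(25.0, 235.7, NAN, 28)])
        add = additive_ed50(d)
        exp = experimental_mixture_ed50(potency(8.44, 0.84, 16), [25.0])
        coords = isobologram_coordinates(d, add, exp)
        assert coords.point_additive == pytest.approx((25.0, 8.51), abs=0.01)
        assert coords.point_experimental == pytest.approx((25.0, 8.44), abs=1e-9)
        assert coords.pooled_note is None

    def test_additive_point_lies_on_the_additivity_line(self):
        d = design(9.52, [(25.0, 235.7, NAN, 28)])
        add = additive_ed50(d)
        coords = isobologram_coordinates(d, add, experimental_mixture_ed50(potency(8.0), [25.0]))
        x, y = coords.point_additive
        # line from (0, varied ED50) to (adjunct ED50, 0)
        expected_y = coords.varied_intercept * (1 - x / coords.adjunct_intercept)
        assert y == pytest.approx(expected_y, rel=1e-12)

    def test_multi_adjunct_designs_pool_onto_one_axis(self):
        d = design(9.52, [(25.0, 235.7, NAN, 28), (25.0, 250.0, NAN, 16)])
        add = additive_ed50(d)
        coords = isobologram_coordinates(d, add, experimental_mixture_ed50(potency(5.0), [25.0, 25.0]))
        assert coords.pooled_note is not None
        assert coords.fixed_dose == 50.0
        f_sum = 25.0 / 235.7 + 25.0 / 250.0
        assert coords.adjunct_intercept == pytest.approx(50.0 / f_sum, rel=1e-12)
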