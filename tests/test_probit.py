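"""Log-probit fitting: probit scale, ML fit vs closed form, bookkeeping rules."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.optimize import minimize

from isobolo.probit import (
    DoseResponseDataset,
    NonEstimableError,
    QuantalDoseGroup,
    count_probit_window_n,
    fit_log_probit,
    probit_transform,
    sem_from_cl,
)


def dataset(*groups, drug="test"):
    return DoseResponseDataset(drug, [QuantalDoseGroup(*g) for g in groups])


class TestProbitTransform:
    @pytest.mark.parametrize(
        "p, expected, tol",
        [
            (0.5, 5.0, 1e-12),          # median response sits at the 5th probit
            (0.8413, 6.0, 1e-3),        # Phi(1) -> 6th probit
            (0.1587, 4.0, 1e-3),        # Phi(-1) -> 4th probit
        ],
    )
    def test_reference_points(self, p, expected, tol):
        assert probit_transform(p) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.3])
    def test_domain_error_outside_open_interval(self, p):
        with pytest.raises(ValueError):
            probit_transform(p)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_round_trip_through_normal_cdf(self, p):
        assert stats.norm.cdf(probit_transform(p) - 5.0) == pytest.approx(p, abs=1e-9)

    @given(
        st.floats(min_value=0.01, max_value=0.98),
        st.floats(min_value=1e-6, max_value=0.01),
    )
    def test_strictly_increasing(self, p, eps):
        assert probit_transform(p + eps) > probit_transform(p)


def closed_form_two_point(d1, k1, n1, d2, k2, n2):
    """Line through the two empirical probits; returns (log10 ed50, slope)."""
    x1, x2 = math.log10(d1), math.log10(d2)
    z1, z2 = stats.norm.ppf(k1 / n1), stats.norm.ppf(k2 / n2)
    slope = (z2 - z1) / (x2 - x1)
    return x1 - z1 / slope, slope


class TestFitLogProbit:
    def test_two_point_fit_matches_brute_force_likelihood(self):
        """Saturated 2-dose fit: ML solution equals the empirical-probit line,
        confirmed against a direct likelihood maximisation."""
        est = fit_log_probit(dataset((6, 2, 8), (16, 6, 8)))
        assert est.ed50 == pytest.approx(math.sqrt(96), abs=0.01)

        def nll(theta):
            log_ed50, slope = theta
            ll = 0.0
            for d, k, n in [(6, 2, 8), (16, 6, 8)]:
                p = stats.norm.cdf(slope * (math.log10(d) - log_ed50))
                ll += k * math.log(p) + (n - k) * math.log(1 - p)
            return -ll

        opt = minimize(nll, x0=[1.0, 2.0], method="Nelder-Mead", options={"xatol": 1e-10})
        assert math.log10(est.ed50) == pytest.approx(opt.x[0], abs=1e-5)
        assert est.slope == pytest.approx(opt.x[1], rel=1e-4)

    @pytest.mark.parametrize(
        "groups",
        [
            ((6, 2, 8), (16, 6, 8)),
            ((3, 1, 10), (30, 8, 10)),
            ((50, 3, 12), (90, 10, 12)),
        ],
    )
    def test_two_point_fit_equals_closed_form(self, groups):
        est = fit_log_probit(dataset(*groups))
        (d1, k1, n1), (d2, k2, n2) = groups
        log_ed50, slope = closed_form_two_point(d1, k1, n1, d2, k2, n2)
        assert math.log10(est.ed50) == pytest.approx(log_ed50, abs=1e-6)
        assert est.slope == pytest.approx(slope, rel=1e-6)

    def test_symmetric_three_point_crosses_at_middle_dose(self):
        d = 12.0
        est = fit_log_probit(dataset((d / 2, 1, 8), (d, 4, 8), (2 * d, 7, 8)))
        assert est.ed50 == pytest.approx(d, rel=0.01)

    def test_parameter_recovery_on_synthetic_data(self):
        from isobolo.simulate import SimulationConfig, simulate_quantal

        cfg = SimulationConfig(
            ed50_true=250.0,
            slope_true=3.0,
            doses=tuple(np.geomspace(100, 600, 5)),
            n_per_group=100,
            seed=42,
        )
        est = fit_log_probit(simulate_quantal(cfg))
        assert est.ed50 == pytest.approx(250.0, rel=0.10)

    def test_all_zero_and_all_full_raise(self):
        with pytest.raises(NonEstimableError):
            fit_log_probit(dataset((5, 0, 8), (10, 0, 8)))
        with pytest.raises(NonEstimableError):
            fit_log_probit(dataset((5, 8, 8), (10, 8, 8)))

    def test_single_dose_raises(self):
        with pytest.raises(NonEstimableError):
            fit_log_probit(dataset((5, 4, 8)))

    def test_complete_separation_is_flagged_not_silent(self):
        est = fit_log_probit(dataset((5, 0, 8), (20, 8, 8)))
        assert not est.converged
        assert math.isinf(est.slope)
        assert est.ed50 == pytest.approx(10.0)  # geometric midpoint of the gap
        assert math.isnan(est.sem)

    def test_duplicate_doses_are_aggregated(self):
        split = fit_log_probit(dataset((6, 1, 4), (6, 1, 4), (16, 6, 8)))
        pooled = fit_log_probit(dataset((6, 2, 8), (16, 6, 8)))
        assert split.ed50 == pytest.approx(pooled.ed50, rel=1e-9)
        assert split.n_probit == pooled.n_probit

    def test_extreme_groups_are_retained_in_likelihood(self):
        with_tails = fit_log_probit(
            dataset((2, 0, 8), (6, 2, 8), (16, 6, 8), (40, 8, 8))
        )
        without = fit_log_probit(dataset((6, 2, 8), (16, 6, 8)))
        # the 0%/100% groups carry tail information, so the fits differ
        assert with_tails.sem < without.sem

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_dose_scaling_equivariance(self, c):
        base = dataset((6, 2, 8), (10, 4, 8), (16, 6, 8))
        scaled = dataset((6 * c, 2, 8), (10 * c, 4, 8), (16 * c, 6, 8))
        e0, e1 = fit_log_probit(base), fit_log_probit(scaled)
        assert e1.ed50 == pytest.approx(c * e0.ed50, rel=1e-6)
        assert e1.sem == pytest.approx(c * e0.sem, rel=1e-6)
        assert e1.cl95_lower == pytest.approx(c * e0.cl95_lower, rel=1e-6)
        assert e1.cl95_upper == pytest.approx(c * e0.cl95_upper, rel=1e-6)
        assert e1.slope == pytest.approx(e0.slope, rel=1e-6)

    @pytest.mark.parametrize("factor", [2, 5, 10])
    def test_more_animals_never_widen_the_log_se(self, factor):
        base = dataset((6, 2, 8), (10, 4, 8), (16, 6, 8))
        bigger = dataset(
            (6, 2 * factor, 8 * factor),
            (10, 4 * factor, 8 * factor),
            (16, 6 * factor, 8 * factor),
        )
        e0, e1 = fit_log_probit(base), fit_log_probit(bigger)
        # same fractions, more animals: SE on the log scale shrinks, ED50 unchanged
        assert e1.ed50 == pytest.approx(e0.ed50, rel=1e-6)
        assert e1.sem / e1.ed50 <= e0.sem / e0.ed50 + 1e-12


class TestProbitWindowCount:
    @pytest.mark.parametrize(
        "groups, expected",
        [
            (((1, 1, 8), (2, 2, 8), (3, 6, 8), (4, 8, 8)), 16),
            (((5, 4, 8),), 8),
            (((1, 0, 8), (2, 8, 8)), 0),
        ],
    )
    def test_window_membership(self, groups, expected):
        assert count_probit_window_n(dataset(*groups)) == expected

    def test_bounds_are_inclusive(self):
        # fractions within 1e-9 of Phi(+-1) count as inside the window
        n = 10**9
        k_lo = round(stats.norm.cdf(-1) * n)
        k_hi = round(stats.norm.cdf(1) * n)
        assert count_probit_window_n(dataset((1, k_lo, n), (2, k_hi, n))) == 2 * n

    def test_invariant_to_order_and_dose_labels(self):
        a = dataset((1, 2, 8), (2, 6, 8), (3, 8, 8))
        b = dataset((30, 8, 8), (999, 6, 8), (17, 2, 8))
        assert count_probit_window_n(a) == count_probit_window_n(b)


class TestSemFromCl:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [(0.0, 3.92, 1.0), (200.0, 278.4, 20.0), (7.5, 7.5, 0.0)],
    )
    def test_values(self, lo, hi, expected):
        assert sem_from_cl(lo, hi) == pytest.approx(expected, abs=1e-12)

    def test_reversed_limits_raise(self):
        with pytest.raises(ValueError):
            sem_from_cl(10.0, 5.0)
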