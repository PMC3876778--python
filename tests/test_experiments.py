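"""Tests for protocol builders, scans and the LQ reference law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhrsim import (
    LOG10_E,
    LQParams,
    RadiationParams,
    ThermalParams,
    asymptotic_survival,
    cutoff_scan,
    dose_rate_scan,
    fit_exponential_decay,
    fractionation_protocol,
    ht_rt_protocol,
    lq_log_survival,
    run,
)
from mhrsim.kinetics import celsius_to_kelvin
from mhrsim.simulate import BODY_TEMPERATURE_K, Protocol, Segment

RAD = RadiationParams(alpha=1.1, c_r=100.0, c_e=10.0, mu_gamma=0.5, gamma=1.45)


class TestLQ:
    def test_values(self):
        lq = LQParams(0.13, 0.054)
        assert lq_log_survival(lq, 0.0) == 0.0
        assert lq_log_survival(lq, 2.0) == pytest.approx(-0.476)

    def test_pure_linear_reproduces_apoptotic_line(self):
        lq = LQParams(1.1, 0.0)
        D = np.array([1.0, 4.0, 8.0])
        assert np.allclose(lq_log_survival(lq, D) * LOG10_E, -(1.1 * LOG10_E) * D)

    def test_rejects_negative_dose_and_coefficients(self):
        with pytest.raises(ValueError):
            lq_log_survival(LQParams(0.1, 0.0), -1.0)
        with pytest.raises(ValueError):
            LQParams(-0.1, 0.0)


class TestFractionation:
    def test_five_by_two_gray_course(self):
        p = fractionation_protocol(5, 2.0, 60.0, gap=24.0)
        beam = [s for s in p if s.dose_rate > 0]
        assert len(beam) == 5
        assert all(s.duration == pytest.approx(2.0 / 60.0) for s in beam)
        assert p.total_dose == pytest.approx(10.0)

    def test_single_fraction(self):
        p = fractionation_protocol(1, 8.0, 240.0)
        assert len(p) == 1
        assert p.segments[0].duration == pytest.approx(8.0 / 240.0)
        assert p.total_dose == pytest.approx(8.0)

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(1, 6),
        d=st.floats(0.5, 10.0),
        R=st.floats(10.0, 300.0),
        gap=st.floats(0.0, 48.0),
    )
    def test_total_dose_exact(self, n, d, R, gap):
        assert fractionation_protocol(n, d, R, gap).total_dose == pytest.approx(n * d)

    def test_zero_dose_rate_rejected(self):
        with pytest.raises(ValueError):
            fractionation_protocol(1, 2.0, 0.0)


class TestHtRtProtocol:
    HEAT = celsius_to_kelvin(42.5)

    def test_positive_gap_heat_first(self):
        p = ht_rt_protocol(5.0, 60.0, self.HEAT, heat_duration=2.0 / 3.0, time_gap=2.0)
        heat_segs = [s for s in p if s.temperature > BODY_TEMPERATURE_K]
        beam_segs = [s for s in p if s.dose_rate > 0]
        assert len(heat_segs) == 1 and len(beam_segs) == 1
        heat, beam = heat_segs[0], beam_segs[0]
        heat_mid = 0.5 * (heat.t_start + heat.t_end)
        beam_mid = 0.5 * (beam.t_start + beam.t_end)
        assert beam_mid - heat_mid == pytest.approx(2.0)
        assert heat.t_end < beam.t_start

    def test_negative_gap_irradiation_first(self):
        p = ht_rt_protocol(5.0, 60.0, self.HEAT, heat_duration=2.0 / 3.0, time_gap=-7.0)
        beam = next(s for s in p if s.dose_rate > 0)
        heat = next(s for s in p if s.temperature > BODY_TEMPERATURE_K)
        assert beam.t_end < heat.t_start
        assert p.segments[0].t_start == 0.0

    def test_zero_gap_merges_into_simultaneous_segment(self):
        p = ht_rt_protocol(5.0, 60.0, self.HEAT, heat_duration=2.0 / 3.0, time_gap=0.0)
        both = [s for s in p if s.dose_rate > 0 and s.temperature > BODY_TEMPERATURE_K]
        assert both, "overlapping heat and beam must share a segment"
        assert p.total_dose == pytest.approx(5.0)

    def test_contiguity_and_dose_for_any_gap(self):
        for gap in (-3.0, -0.25, 0.1, 4.0):
            p = ht_rt_protocol(5.0, 120.0, self.HEAT, 2.0 / 3.0, gap)
            assert p.total_dose == pytest.approx(5.0)

    def test_heating_alone_never_kills(self):
        # below ~44 degC heat acts only through the repair probability
        rad = RAD
        therm = ThermalParams()
        p = Protocol([Segment(0.0, 1.0, 0.0, self.HEAT)])
        traj = run(p, rad, therm, relax=False)
        assert traj.N[-1] == pytest.approx(1.0, abs=1e-12)
        assert traj.Lambda[-1] > 0.0

    def test_synergy_vanishes_at_large_gap(self):
        # |gap| -> large approaches the radiation-only survival
        rad = RadiationParams(alpha=1.1, c_r=6.1, c_e=2.0, mu_gamma=0.5, gamma=1.45)
        therm = ThermalParams(a=1.0, k2=2.0, mu_lambda=20.0)
        rt_only = asymptotic_survival(
            fractionation_protocol(1, 5.0, 60.0), rad, dt_off=5e-3
        )
        sim = asymptotic_survival(
            ht_rt_protocol(5.0, 60.0, self.HEAT, 2.0 / 3.0, 0.0),
            rad, therm, dt_off=5e-3,
        )
        far = asymptotic_survival(
            ht_rt_protocol(5.0, 60.0, self.HEAT, 2.0 / 3.0, -30.0),
            rad, therm, dt_off=5e-3,
        )
        assert sim < rt_only          # simultaneous heat sensitises
        assert abs(far - rt_only) < abs(sim - rt_only) * 0.2


class TestExponentialFit:
    def test_exact_two_point_recovery(self):
        a, b = 2.0, 1.0
        pts = [(1, a * math.exp(-b)), (2, a * math.exp(-2 * b))]
        a_fit, b_fit = fit_exponential_decay(pts)
        assert a_fit == pytest.approx(a) and b_fit == pytest.approx(b)

    def test_least_squares_recovery_under_noise(self, rng):
        a, b = 1.5, 0.8
        ks = np.arange(1, 9)
        noise = rng.normal(0.0, 0.01, size=ks.size)
        pts = list(zip(ks, a * np.exp(-b * ks) * np.exp(noise)))
        a_fit, b_fit = fit_exponential_decay(pts)
        assert b_fit == pytest.approx(b, abs=0.02)
        assert a_fit == pytest.approx(a, rel=0.05)

    def test_subset_selection(self):
        pts = [(1, 1.0), (2, 0.1), (3, 0.05)]
        _, b12 = fit_exponential_decay(pts, subset={1, 2})
        assert b12 == pytest.approx(math.log(10.0))

    def test_rejects_nonpositive_delta(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([(1, 1.0), (2, 0.0)])


@pytest.fixture(scope="module")
def report():
    return cutoff_scan(RAD, 2, 2.0, 60.0, gap=24.0, k_list=(1, 3, 6), dt_off=5e-3)


class TestCutoffScan:

    def test_reference_row_identities(self, report):
        i6 = list(report.k_values).index(6)
        assert np.all(report.ratio[i6] == 1.0)
        assert np.all(report.delta[i6] == 0.0)

    def test_truncation_costs_survival(self, report):
        # smaller cutoff removes repair opportunities: delta > 0 for k < 6
        for i, k in enumerate(report.k_values):
            if k < 6:
                assert np.all(report.delta[i] > 0.0)

    def test_monotone_in_k(self, report):
        # log S increases (less killing) as the chain deepens
        final = report.log10S[:, -1]
        assert np.all(np.diff(final) > 0.0)

    def test_cumulative_doses(self, report):
        assert list(report.cumulative_doses) == [2.0, 4.0]


class TestDoseRateScan:
    def test_monotone_nonincreasing_in_rate(self, t98g):
        table = dose_rate_scan(t98g, 5.0, [12.0, 60.0, 240.0], dt_off=5e-3)
        vals = table["log10S"].to_numpy()
        assert np.all(np.diff(vals) < 0.0)

    def test_rejects_nonpositive_dose(self, t98g):
        with pytest.raises(ValueError):
            dose_rate_scan(t98g, 0.0, [60.0])
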