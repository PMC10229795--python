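"""Cohort engine: occupancy, conservation, discounting, accrual."""

import dataclasses
import math

import numpy as np
import pytest

import pscea
from pscea.cohort import _mid_discount


def exponential(rate):
    return pscea.WeibullParams.from_shape_rate(1.0, rate)


class TestTrace:
    def test_cycle_zero_everyone_progression_free(self, itt):
        spec, settings = itt
        trace = pscea.run_trace(spec.survival["placebo"].os,
                                spec.survival["placebo"].pfs, settings)
        assert trace.occ_pfs[0] == 1.0
        assert trace.occ_pd[0] == 0.0
        assert trace.occ_dead[0] == 0.0

    def test_identical_curves_empty_pd(self):
        p = exponential(0.05)
        trace = pscea.run_trace(p, p, pscea.ModelSettings())
        assert np.all(trace.occ_pd == 0.0)

    def test_occupancy_conservation_all_packaged_models(self, all_populations):
        for spec, settings in all_populations.values():
            for arm in pscea.ARMS:
                s = spec.survival[arm]
                trace = pscea.run_trace(s.os, s.pfs, settings)
                total = trace.occ_pfs + trace.occ_pd + trace.occ_dead
                assert total == pytest.approx(np.ones_like(total), abs=1e-9)
                assert np.all(np.diff(trace.occ_dead) >= -1e-12)
                for occ in (trace.occ_pfs, trace.occ_pd, trace.occ_dead):
                    assert np.all((occ >= 0) & (occ <= 1))

    def test_crossing_curves_clamped_and_logged(self, caplog):
        # PFS above OS everywhere: PD clamps to zero on every cycle
        os_p = exponential(0.2)
        pfs_p = exponential(0.05)
        with caplog.at_level("WARNING"):
            trace = pscea.run_trace(os_p, pfs_p, pscea.ModelSettings())
        assert np.all(trace.occ_pd == 0.0)
        assert trace.clamped_cycles > 0
        assert any("clamped" in r.message for r in caplog.records)

    def test_pfs_life_years_match_restricted_mean(self, itt):
        """Trapezoid PFS person-time equals the capped mean survival within 1 %."""
        spec, settings = itt
        s = spec.survival["toripalimab"]
        trace = pscea.run_trace(s.os, s.pfs, settings)
        mean_occ = trace.mean_occupancy("PFS")
        person_years = float(np.sum(mean_occ)) * settings.cycle_years
        horizon_months = settings.n_cycles * settings.cycle_days / pscea.MONTH_DAYS
        oracle_years = s.pfs.mean(cap=horizon_months) * pscea.MONTH_DAYS / 365.25
        assert person_years == pytest.approx(oracle_years, rel=0.01)

    def test_to_frame_columns(self, itt):
        spec, settings = itt
        res = pscea.run_arm(spec, "placebo", settings)
        df = res.trace.to_frame()
        assert list(df.columns) == ["cycle", "time_years", "occ_pfs", "occ_pd",
                                    "occ_dead", "disc_factor", "cost_accrued",
                                    "qaly_accrued"]
        assert len(df) == settings.n_cycles + 1


class TestDiscounting:
    def test_factor_at_zero(self):
        assert pscea.discount_factor(0, pscea.ModelSettings()) == 1.0

    def test_one_year_at_three_percent(self):
        settings = pscea.ModelSettings(cycle_days=365.25)
        assert pscea.discount_factor(1, settings) == pytest.approx(1 / 1.03, rel=1e-12)

    def test_final_cycle(self):
        settings = pscea.ModelSettings()
        t174 = 174 * 21 / 365.25
        assert pscea.discount_factor(174, settings) == pytest.approx(
            1.03 ** (-t174), rel=1e-12
        )
        assert t174 == pytest.approx(10.004, abs=0.002)

    def test_factors_non_increasing_in_unit_interval(self, itt):
        _, settings = itt
        f = pscea.discount_factor(np.arange(175), settings)
        assert np.all(np.diff(f) < 0)
        assert np.all((f > 0) & (f <= 1))

    def test_discounted_totals_below_undiscounted(self, all_populations):
        for spec, settings in all_populations.values():
            undisc = dataclasses.replace(settings, discount_annual=0.0)
            for arm in pscea.ARMS:
                disc_res = pscea.run_arm(spec, arm, settings)
                undisc_res = pscea.run_arm(spec, arm, undisc)
                assert disc_res.cost_total <= undisc_res.cost_total
                assert disc_res.qaly_total <= undisc_res.qaly_total


class TestAccrual:
    def test_zero_inputs_zero_result(self, itt):
        spec, settings = itt
        s = spec.survival["placebo"]
        trace = pscea.run_trace(s.os, s.pfs, settings)
        utilities = pscea.UtilitySet(
            pfs=pscea.UtilityParam(0.0, 0.0, 0.0, distribution="fixed"),
            pd=pscea.UtilityParam(0.0, 0.0, 0.0, distribution="fixed"),
        )
        res = pscea.accumulate(trace, (), utilities, settings, "placebo")
        assert res.cost_total == 0.0
        assert res.qaly_total == 0.0

    def test_immortal_cohort_accrues_pfs_utility(self):
        # S_OS = S_PFS ~ 1 over one year, no discounting: QALYs ~ u_pfs
        p = pscea.WeibullParams.from_shape_rate(1.0, 1e-12)
        settings = pscea.ModelSettings(horizon_years=1.0, discount_annual=0.0)
        trace = pscea.run_trace(p, p, settings)
        utilities = pscea.UtilitySet(
            pfs=pscea.UtilityParam(0.673, 0.47, 0.87),
            pd=pscea.UtilityParam(0.473, 0.33, 0.61),
        )
        res = pscea.accumulate(trace, (), utilities, settings, "placebo")
        quantum = 0.673 * settings.cycle_years
        assert abs(res.qaly_total - 0.673) <= quantum + 1e-9

    def test_per_cycle_cost_matches_exponential_mean(self):
        """$100/cycle in PFS, exponential PFS, no discounting:
        total = 100 x (restricted mean PFS time / cycle length)."""
        rate = 0.08  # per month
        pfs = exponential(rate)
        os_p = exponential(rate)  # identical: everyone in PFS until death
        settings = pscea.ModelSettings(discount_annual=0.0, horizon_years=40.0)
        trace = pscea.run_trace(os_p, pfs, settings)
        item = pscea.CostItem(name="c", base_value=100.0, low=100.0, high=100.0,
                              state="PFS", arm="both", interval_days=21.0)
        utilities = pscea.UtilitySet(
            pfs=pscea.UtilityParam(0.0, 0.0, 0.0), pd=pscea.UtilityParam(0.0, 0.0, 0.0)
        )
        res = pscea.accumulate(trace, (item,), utilities, settings, "placebo")
        cycle_months = settings.cycle_days / pscea.MONTH_DAYS
        expected = 100.0 * (1.0 / rate) / cycle_months  # mean 1/rate months
        assert res.cost_total == pytest.approx(expected, rel=0.01)

    def test_interval_days_scales_recurring_costs(self, itt):
        spec, settings = itt
        s = spec.survival["placebo"]
        trace = pscea.run_trace(s.os, s.pfs, settings)
        utilities = spec.utilities
        base = dict(name="c", base_value=100.0, low=100.0, high=100.0,
                    state="PFS", arm="both")
        monthly = pscea.CostItem(interval_days=pscea.MONTH_DAYS, **base)
        per_cycle = pscea.CostItem(interval_days=21.0, **base)
        r_month = pscea.accumulate(trace, (monthly,), utilities, settings, "placebo")
        r_cycle = pscea.accumulate(trace, (per_cycle,), utilities, settings, "placebo")
        assert r_month.cost_total == pytest.approx(
            r_cycle.cost_total * 21.0 / pscea.MONTH_DAYS, rel=1e-12
        )

    def test_one_off_cost_discounted_at_start_cycle(self, itt):
        spec, settings = itt
        s = spec.survival["placebo"]
        trace = pscea.run_trace(s.os, s.pfs, settings)
        utilities = spec.utilities
        item = pscea.CostItem(name="late", base_value=1000.0, low=1000.0, high=1000.0,
                              application="one_off", state="PFS", arm="both",
                              start_cycle=17)
        res = pscea.accumulate(trace, (item,), utilities, settings, "placebo")
        expected = 1000.0 * trace.occ_pfs[17] * pscea.discount_factor(17, settings)
        assert res.cost_total == pytest.approx(expected, rel=1e-12)

    def test_unknown_state_rejected(self, itt):
        spec, settings = itt
        with pytest.raises(pscea.EnumerationError):
            pscea.CostItem(name="x", base_value=1, low=1, high=1, state="CURED")

    def test_pd_uptake_multiplier_scales_pd_costs_only(self, itt):
        spec, settings = itt
        scaled = dataclasses.replace(settings, pd_cost_uptake=0.5)
        base_res = pscea.run_arm(spec, "placebo", settings)
        scaled_res = pscea.run_arm(spec, "placebo", scaled)
        assert scaled_res.cost_by_state["PD"] == pytest.approx(
            0.5 * base_res.cost_by_state["PD"], rel=1e-12
        )
        assert scaled_res.cost_by_state["PFS"] == pytest.approx(
            base_res.cost_by_state["PFS"], rel=1e-12
        )


class TestRunArm:
    def test_splits_sum_to_totals(self, all_populations):
        for spec, settings in all_populations.values():
            for arm in pscea.ARMS:
                res = pscea.run_arm(spec, arm, settings)
                assert sum(res.cost_by_state.values()) == pytest.approx(
                    res.cost_total, abs=1e-6
                )
                assert sum(res.qaly_by_state.values()) == pytest.approx(
                    res.qaly_total, abs=1e-9
                )
                assert res.cost_total > 0 and res.qaly_total > 0

    def test_deterministic(self, itt):
        spec, settings = itt
        a = pscea.run_arm(spec, "toripalimab", settings)
        b = pscea.run_arm(spec, "toripalimab", settings)
        assert a.cost_total == b.cost_total
        assert a.qaly_total == b.qaly_total

    def test_unknown_arm_rejected(self, itt):
        spec, settings = itt
        with pytest.raises(pscea.EnumerationError):
            pscea.run_arm(spec, "nivolumab", settings)

    def test_qalys_bounded_by_horizon_at_full_utility(self, all_populations):
        for spec, settings in all_populations.values():
            for arm in pscea.ARMS:
                res = pscea.run_arm(spec, arm, settings)
                assert res.qaly_total <= settings.horizon_years * spec.utilities.pfs.value

    def test_halving_cycle_length_is_stable(self, itt):
        """Discretization: halving the cycle changes QALYs by < 0.5 %."""
        spec, settings = itt
        fine = dataclasses.replace(settings, cycle_days=10.5)
        for arm in pscea.ARMS:
            coarse_q = pscea.run_arm(spec, arm, settings).qaly_total
            fine_q = pscea.run_arm(spec, arm, fine).qaly_total
            assert abs(fine_q / coarse_q - 1.0) < 0.005

    def test_half_cycle_correction_flag_changes_accrual(self, itt):
        spec, settings = itt
        no_hcc = dataclasses.replace(settings, half_cycle_correction=False)
        with_hcc = pscea.run_arm(spec, "placebo", settings).qaly_total
        without = pscea.run_arm(spec, "placebo", no_hcc).qaly_total
        # start-boundary membership over-counts occupancy relative to trapezoid
        assert without > with_hcc

    def test_mid_cycle_discount_between_boundaries(self, itt):
        _, settings = itt
        mid = _mid_discount(settings)
        bounds = pscea.discount_factor(np.arange(settings.n_cycles + 1), settings)
        assert np.all(mid < bounds[:-1])
        assert np.all(mid > bounds[1:])
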