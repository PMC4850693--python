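"""Planner vs controller delivery-time models and trace bookkeeping."""

import numpy as np
import pytest

import wavearc as w
from wavearc.delivery import controller_gap_times, subarc_mu
from wavearc.errors import InfeasiblePlanError, WaveArcError
from wavearc.fixtures import FixtureSpec, generate_plan

from conftest import make_coplanar_plan, make_plan_from_trajectory

AP = w.AngularPosition


# -------------------------------------------------------- oracles ---------
def oracle_tps_time(plan, mc, v_step=0.001):
    """Exhaustive search over a gantry-speed grid and the dose-rate table."""
    g = np.array([abs(b.gantry - a.gantry) for a, b in plan.trajectory.sub_arcs])
    r = np.array([abs(b.ring - a.ring) for a, b in plan.trajectory.sub_arcs])
    G = g.sum()
    best = np.inf
    for v in np.arange(mc.gantry_speed[0], mc.gantry_speed[1] + v_step / 2, v_step):
        ok = True
        for k in range(g.size):
            if r[k] > 0:
                vr = v * r[k] / g[k]
                if not (mc.ring_speed[0] - 1e-12 <= vr <= mc.ring_speed[1] + 1e-12):
                    ok = False
                    break
        if not ok:
            continue
        T = G / v
        if plan.total_mu > 0:
            needed = plan.total_mu * 60.0 / T
            if not any(dr >= needed - 1e-9 for dr in mc.dose_rate_table):
                continue
        best = min(best, T)
    return best


def oracle_controller_time(plan, mc, v_step=0.001):
    """Per-sub-arc exhaustive search; returns total beam-on time (no stops)."""
    g = np.array([abs(b.gantry - a.gantry) for a, b in plan.trajectory.sub_arcs])
    r = np.array([abs(b.ring - a.ring) for a, b in plan.trajectory.sub_arcs])
    mu = subarc_mu(plan)
    # mirror the MP ramp debit of the simulator
    ramp = mc.mp_ramp_dose_rate * mc.mp_stop_duration / 60.0
    total = 0.0
    for k in range(g.size):
        m = mu[k] - (min(ramp, mu[k]) if k > 0 else 0.0)
        best = np.inf
        for v in np.arange(mc.gantry_speed[0], mc.gantry_speed[1] + v_step / 2,
                           v_step):
            if g[k] <= 0:
                break
            t = g[k] / v
            vr = r[k] / t if r[k] > 0 else 0.0
            if r[k] > 0 and not (mc.ring_speed[0] - 1e-12 <= vr
                                 <= mc.ring_speed[1] + 1e-12):
                continue
            if m > 0:
                needed = m * 60.0 / t
                if not any(dr >= needed - 1e-9 for dr in mc.dose_rate_table):
                    # MU-limited: stretch to the fastest table entry
                    t = m * 60.0 / mc.dose_rate_table[-1]
                    vr = r[k] / t if r[k] > 0 else 0.0
                    vg = g[k] / t
                    if not (mc.gantry_speed[0] - 1e-12 <= vg
                            <= mc.gantry_speed[1] + 1e-12):
                        continue
                    if r[k] > 0 and not (mc.ring_speed[0] - 1e-12 <= vr
                                         <= mc.ring_speed[1] + 1e-12):
                        continue
            best = min(best, t)
        total += best
    return total


# --------------------------------------------------------- planner --------
class TestTpsEstimate:
    def test_coplanar_dose_rate_limited_arc(self, mc):
        """180 deg / 300 MU: motion allows 30 s but DR 400 forces 45 s."""
        plan = make_coplanar_plan(180.0, 300.0)
        est = w.tps_time_estimate(plan, mc)
        assert est.beam_on_time == pytest.approx(45.0)
        assert est.chosen_gantry_speed == pytest.approx(4.0)
        assert est.chosen_dose_rate == 400.0

    def test_ring_ratio_bounds_gantry_speed(self, mc):
        traj = w.WaveArcTrajectory([AP(0, 0), AP(60, 60)])
        plan = make_plan_from_trajectory(traj, total_mu=10.0)
        est = w.tps_time_estimate(plan, mc)
        assert est.beam_on_time == pytest.approx(60 / 2.5)
        assert est.per_subarc_ring_speed[0] == pytest.approx(2.5)

    def test_zero_mu_is_motion_limited(self, mc):
        plan = make_coplanar_plan(180.0, 0.0)
        est = w.tps_time_estimate(plan, mc)
        assert est.beam_on_time == pytest.approx(180 / 6.0)

    def test_matches_exhaustive_search(self, mc):
        for seed in range(8):
            plan = generate_plan(FixtureSpec(seed=seed, n_subarcs=3))
            est = w.tps_time_estimate(plan, mc)
            oracle = oracle_tps_time(plan, mc)
            assert est.beam_on_time <= oracle + 1e-9
            assert oracle - est.beam_on_time <= 0.05

    def test_infeasible_ring_window_raises_named_error(self, mc):
        # tiny ring span with max gantry span: implied ring speed < minimum
        traj = w.WaveArcTrajectory([AP(0, 0), AP(360, 2)])
        plan = make_plan_from_trajectory(traj, total_mu=1.0)
        mc2 = w.MachineConstraints(ring_speed=(2.0, 2.5))
        with pytest.raises(InfeasiblePlanError) as exc:
            w.tps_time_estimate(plan, mc2)
        assert exc.value.binding == "ring_speed"


# ------------------------------------------------------ controller --------
class TestController:
    def test_simultaneous_finish_dose_rate(self, mc):
        """60 deg / 50 MU: 10 s motion, DR 300 finishes MU with motion."""
        plan = make_coplanar_plan(60.0, 50.0)
        trace, total = w.controller_simulate(plan, mc)
        assert total == pytest.approx(10.0)
        on = trace.samples[~trace.samples["in_stop"]]
        assert on["dose_rate"].max() == pytest.approx(300.0)

    def test_mp_stops_count_and_duration(self, mc):
        for seed in (1, 2):
            plan = generate_plan(FixtureSpec(seed=seed, n_subarcs=3))
            n_sub = plan.trajectory.n_subarcs
            _, total = w.controller_simulate(plan, mc)
            stops = total - sum(_subarc_times(plan, mc))
            assert stops == pytest.approx((n_sub - 1) * mc.mp_stop_duration)

    def test_controller_never_slower_than_planner_single_subarc(self, mc):
        rng = np.random.default_rng(11)
        count = 0
        while count < 200:
            g = 4.0 * rng.integers(6, 60)
            r = 4.0 * rng.integers(0, min(int(g // 4), 15) + 1)
            if g > 360:
                continue
            mu = float(rng.uniform(5, 200))
            traj = w.WaveArcTrajectory([AP(0, 0), AP(g, r)])
            plan = make_plan_from_trajectory(traj, total_mu=mu)
            est = w.tps_time_estimate(plan, mc)
            _, total = w.controller_simulate(plan, mc)
            assert total <= est.beam_on_time + 1e-9
            count += 1

    def test_controller_matches_exhaustive_search(self, mc):
        for seed in range(6):
            plan = generate_plan(FixtureSpec(seed=seed, n_subarcs=3))
            n_sub = plan.trajectory.n_subarcs
            _, total = w.controller_simulate(plan, mc)
            beam_on = total - (n_sub - 1) * mc.mp_stop_duration
            oracle = oracle_controller_time(plan, mc)
            assert beam_on <= oracle + 1e-9
            assert oracle - beam_on <= 0.05

    def test_trace_conserves_mu(self, mc):
        for seed in range(5):
            plan = generate_plan(FixtureSpec(seed=seed, n_subarcs=3,
                                             mu_total=250.0))
            trace, _ = w.controller_simulate(plan, mc)
            assert abs(trace.total_mu - plan.total_mu) <= 0.5

    def test_beam_hold_at_mp_delivers_less_mu_never_more(self, mc):
        plan = generate_plan(FixtureSpec(seed=4, n_subarcs=3))
        trace, _ = w.controller_simulate(plan, mc, beam_hold_at_mp=True)
        assert trace.total_mu <= plan.total_mu + 1e-9

    def test_trace_speeds_within_limits_or_zero(self, mc, fixture_plan):
        trace, _ = w.controller_simulate(fixture_plan, mc)
        df = trace.samples
        on = ~df["in_stop"]
        assert (df.loc[on, "gantry_speed"] <= mc.gantry_speed[1] + 1e-9).all()
        assert (df.loc[on, "ring_speed"] <= mc.ring_speed[1] + 1e-9).all()
        stopped = df.loc[~on]
        assert (stopped["gantry_speed"] == 0).all()
        assert (stopped["ring_speed"] == 0).all()

    def test_more_mu_never_faster(self, mc):
        t_prev = 0.0
        for mu in (50.0, 150.0, 400.0, 800.0):
            plan = make_coplanar_plan(120.0, mu)
            _, total = w.controller_simulate(plan, mc)
            assert total >= t_prev - 1e-9
            t_prev = total


def _subarc_times(plan, mc):
    from wavearc.delivery import _subarc_schedule
    _, times = _subarc_schedule(plan, mc, False)
    return times


# --------------------------------------------------------- summary --------
class TestTraceSummary:
    def test_constant_speed_trace_mean(self, mc):
        plan = make_coplanar_plan(180.0, 300.0)
        trace, _ = w.controller_simulate(plan, mc)
        summary = w.summarize_trace(trace)
        assert summary["mean_gantry_speed"] == pytest.approx(4.0, abs=1e-6)
        assert summary["total_time"] == pytest.approx(45.0)

    def test_two_subarc_total_time_closed_form(self, mc):
        traj = w.WaveArcTrajectory([AP(0, 0), AP(60, 0), AP(120, 0)])
        plan = make_plan_from_trajectory(traj, total_mu=100.0)
        trace, total = w.controller_simulate(plan, mc)
        times = _subarc_times(plan, mc)
        assert total == pytest.approx(times.sum() + mc.mp_stop_duration)
        assert w.summarize_trace(trace)["total_time"] == pytest.approx(total)

    def test_empty_trace_errors(self, mc):
        import pandas as pd
        trace = w.DeliveryTrace(100.0, pd.DataFrame(), 0.0, 0.0)
        with pytest.raises(WaveArcError):
            w.summarize_trace(trace)


# --------------------------------------------------- overestimation -------
class TestOverestimation:
    def test_dose_rate_worked_example_rounds_to_26(self):
        mu = 301.0
        t_tps = mu / 180.0 * 60.0
        t_actual = mu / 243.0 * 60.0
        over = w.time_overestimation(t_tps, t_actual)
        assert over == pytest.approx(100.0 * (1 - 180.0 / 243.0))
        assert round(over) == 26

    def test_identical_times_zero(self):
        assert w.time_overestimation(10.0, 10.0) == 0.0

    def test_half_time_is_fifty_percent(self):
        assert w.time_overestimation(10.0, 5.0) == pytest.approx(50.0)


# ------------------------------------------------------- leaf travel ------
class TestLeafTravel:
    def _plan_with_leaf_jump(self, jump_cm):
        plan = generate_plan(FixtureSpec(seed=2, n_subarcs=2, complexity=0.0))
        cps = list(plan.control_points)
        ap = cps[1].mlc
        moved = w.MLCAperture(ap.left + jump_cm, ap.right + jump_cm,
                              ap.leaf_widths)
        cps[1] = w.ControlPoint(cps[1].position, cps[1].mu_weight, moved)
        return w.DeliveryPlan(plan.trajectory, tuple(cps),
                              cp_norms=plan.cp_norms)

    def test_static_aperture_has_no_violations(self, mc, ):
        plan = generate_plan(FixtureSpec(seed=2, n_subarcs=2, complexity=0.0))
        times = controller_gap_times(plan, mc)
        assert w.leaf_travel_feasibility(plan, times, mc) == []

    def test_fast_leaf_flagged(self, mc):
        plan = self._plan_with_leaf_jump(1.0)
        times = np.full(len(plan.control_points) - 1, 0.1)  # 10 cm/s needed
        report = w.leaf_travel_feasibility(plan, times, mc)
        assert report and all(rec["required_speed"] > mc.leaf_speed_max
                              for rec in report)

    def test_zero_time_with_motion_is_infinite_violation(self, mc):
        plan = self._plan_with_leaf_jump(1.0)
        times = np.full(len(plan.control_points) - 1, 1.0)
        times[0] = 0.0
        report = w.leaf_travel_feasibility(plan, times, mc)
        assert any(np.isinf(rec["required_speed"]) for rec in report)

    def test_generated_plans_leaf_feasible(self, mc):
        for seed in range(4):
            plan = generate_plan(FixtureSpec(seed=seed, complexity=0.5))
            times = controller_gap_times(plan, mc)
            assert w.leaf_travel_feasibility(plan, times, mc) == []
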