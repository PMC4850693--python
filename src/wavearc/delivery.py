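"""Machine-constraint delivery model for gantry-ring wave arcs.

Two delivery-time models are provided:

``tps_time_estimate``
    The conservative planner model: one constant gantry speed and one
    constant dose rate for the whole arc (ring speed alone is modulated
    per sub-arc), chosen so that constant MU per control point is
    deliverable.  This is the "feasible delivery time" a planning system
    reports.

``controller_simulate``
    An emulation of the machine controller, which re-selects gantry
    speed, ring speed and dose rate independently at every manipulation
    point so each sub-arc finishes as fast as its own constraints allow,
    with a brief mechanical stop at every MP during which the dose rate
    ramps down.  It emits a log-file-like trace sampled at 100 Hz.

The gap between the two is the planner's delivery-time overestimation.
Dose rates live on a discrete look-up table (the published machine range
is 150-400 MU/min; the exact table entries are configuration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complexity import ArcSequence, MLCAperture
from .errors import InfeasiblePlanError, WaveArcError
from .trajectory import (AngularPosition, WaveArcTrajectory,
                         project_onto_trajectory)

__all__ = [
    "MachineConstraints", "ControlPoint", "DeliveryPlan", "TimeEstimate",
    "DeliveryTrace", "tps_time_estimate", "controller_simulate",
    "summarize_trace", "time_overestimation", "leaf_travel_feasibility",
    "subarc_mu", "controller_gap_times",
]


@dataclass(frozen=True)
class MachineConstraints:
    """O-ring machine axis, dose-rate and MLC limits.

    Speeds in deg/s, dose rates in MU/min, leaf speed in cm/s at
    isocenter, stop duration in s.  The dose-rate table is discrete; the
    default is a 50 MU/min grid spanning the machine's 150-400 MU/min
    range.
    """

    gantry_speed: tuple[float, float] = (0.1, 6.0)
    ring_speed: tuple[float, float] = (0.1, 2.5)
    dose_rate_table: tuple[float, ...] = (150.0, 200.0, 250.0, 300.0, 350.0, 400.0)
    leaf_speed_max: float = 4.0
    mp_stop_duration: float = 0.1
    mp_ramp_dose_rate: float = 100.0

    def __post_init__(self) -> None:
        for name in ("gantry_speed", "ring_speed"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise WaveArcError(f"{name} range must be positive and ordered")
        table = tuple(float(v) for v in self.dose_rate_table)
        if not table or list(table) != sorted(table):
            raise WaveArcError("dose_rate_table must be sorted ascending")
        if any(v <= 0 for v in table):
            raise WaveArcError("dose rates must be positive")
        object.__setattr__(self, "dose_rate_table", table)
        if self.leaf_speed_max <= 0 or self.mp_stop_duration < 0:
            raise WaveArcError("leaf_speed_max must be positive, stop duration >= 0")


@dataclass(frozen=True)
class ControlPoint:
    """One plan sample: machine angles, MLC aperture, MU weight.

    ``mu_weight`` is the MU delivered between the previous CP and this
    one; the first CP of a plan carries weight 0.
    """

    position: AngularPosition
    mu_weight: float
    mlc: MLCAperture | None = None


@dataclass(frozen=True)
class DeliveryPlan:
    """Control-point sequence on a wave trajectory."""

    trajectory: WaveArcTrajectory
    control_points: tuple[ControlPoint, ...]
    cp_norms: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        cps = tuple(self.control_points)
        if len(cps) < 2:
            raise WaveArcError("a plan needs at least 2 control points")
        if any(cp.mu_weight < 0 for cp in cps):
            raise WaveArcError("mu weights must be non-negative")
        if cps[0].mu_weight != 0:
            raise WaveArcError("the first control point must carry mu_weight 0")
        object.__setattr__(self, "control_points", cps)
        if self.cp_norms is None:
            norms = np.array([project_onto_trajectory(self.trajectory, cp.position)
                              for cp in cps])
        else:
            norms = np.asarray(self.cp_norms, dtype=float)
        if not np.all(np.diff(norms) >= 0):
            raise WaveArcError("control points must be ordered along the trajectory")
        object.__setattr__(self, "cp_norms", norms)

    @property
    def total_mu(self) -> float:
        return float(sum(cp.mu_weight for cp in self.control_points))

    @property
    def is_constant_mu(self) -> bool:
        w = [cp.mu_weight for cp in self.control_points[1:]]
        return bool(np.allclose(w, w[0]))

    def arc_sequence(self) -> ArcSequence:
        """View of the plan as an MCS-ready aperture/MU sequence."""
        aps = tuple(cp.mlc for cp in self.control_points)
        if any(ap is None for ap in aps):
            raise WaveArcError("plan has control points without apertures")
        mu = np.array([cp.mu_weight for cp in self.control_points[1:]])
        return ArcSequence(aps, mu)


@dataclass(frozen=True)
class TimeEstimate:
    """Planner-model beam-on time and the constant machine settings."""

    beam_on_time: float
    chosen_gantry_speed: float
    chosen_dose_rate: float
    per_subarc_ring_speed: tuple[float, ...]


@dataclass(frozen=True)
class DeliveryTrace:
    """Log-file-like time series of axis speeds and dose rate."""

    sample_rate: float
    samples: pd.DataFrame = field(repr=False)
    total_time: float
    total_mu: float


def _subarc_spans(traj: WaveArcTrajectory) -> tuple[np.ndarray, np.ndarray]:
    g = np.array([abs(b.gantry - a.gantry) for a, b in traj.sub_arcs])
    r = np.array([abs(b.ring - a.ring) for a, b in traj.sub_arcs])
    return g, r


def subarc_mu(plan: DeliveryPlan) -> np.ndarray:
    """MU delivered within each sub-arc.

    MU between two control points is spread uniformly along the path
    between them, then integrated over each sub-arc's norm interval.
    """
    bounds = plan.trajectory.cumulative_norms()
    out = np.zeros(plan.trajectory.n_subarcs)
    s = plan.cp_norms
    for j in range(1, len(plan.control_points)):
        w = plan.control_points[j].mu_weight
        a, b = s[j - 1], s[j]
        if w == 0:
            continue
        if b - a <= 1e-12:
            # point mass: assign to the sub-arc containing it
            k = min(int(np.searchsorted(bounds, a, side="right") - 1), out.size - 1)
            out[k] += w
            continue
        for k in range(out.size):
            lo, hi = max(a, bounds[k]), min(b, bounds[k + 1])
            if hi > lo:
                out[k] += w * (hi - lo) / (b - a)
    return out


def _smallest_rate_at_least(table: tuple[float, ...], needed: float) -> float | None:
    for dr in table:
        if dr >= needed - 1e-9:
            return dr
    return None


def tps_time_estimate(plan: DeliveryPlan, mc: MachineConstraints) -> TimeEstimate:
    """Conservative planner beam-on time.

    Finds the minimum T such that a single constant gantry speed
    v_g = total_gantry_span / T is within range, every sub-arc's implied
    ring speed v_g * ring_span/gantry_span is within range (or exactly 0),
    and one dose-rate table entry delivers the plan MU within T.  Raises
    :class:`InfeasiblePlanError` naming the binding constraint when no
    such pair exists.
    """
    g, r = _subarc_spans(plan.trajectory)
    if np.any(g <= 0):
        if np.any(r[g <= 0] > 0):
            raise InfeasiblePlanError(
                "pure-ring sub-arc cannot be driven at constant gantry speed",
                binding="gantry_span", subarc=int(np.argmax(g <= 0)))
        raise InfeasiblePlanError("zero gantry span", binding="gantry_span")
    G = float(g.sum())
    g_lo, g_hi = mc.gantry_speed
    r_lo, r_hi = mc.ring_speed
    v_hi, v_lo = g_hi, g_lo
    for k in range(g.size):
        if r[k] > 0:
            v_hi = min(v_hi, r_hi * g[k] / r[k])
            v_lo = max(v_lo, r_lo * g[k] / r[k])
    if v_lo > v_hi + 1e-12:
        raise InfeasiblePlanError(
            "no constant gantry speed keeps every ring speed in range",
            binding="ring_speed")
    t_motion = G / v_hi
    total_mu = plan.total_mu
    table = mc.dose_rate_table
    needed = 0.0 if total_mu == 0 else total_mu * 60.0 / t_motion
    dr = _smallest_rate_at_least(table, needed)
    if dr is not None:
        T = t_motion
    else:
        dr = table[-1]
        T = total_mu * 60.0 / dr
        if G / T < v_lo - 1e-12:
            raise InfeasiblePlanError(
                "dose-rate-limited time pushes gantry speed below its minimum",
                binding="dose_rate")
    v_g = G / T
    ring = tuple(float(v_g * r[k] / g[k]) for k in range(g.size))
    return TimeEstimate(float(T), float(v_g), float(dr), ring)


def _subarc_schedule(plan: DeliveryPlan, mc: MachineConstraints,
                     beam_hold_at_mp: bool):
    """Per-sub-arc controller settings plus MP stop segments.

    Returns a list of segments (duration, gantry_vel, ring_vel,
    dose_rate, in_stop) covering the whole delivery, and the per-sub-arc
    durations (stops excluded).
    """
    traj = plan.trajectory
    g, r = _subarc_spans(traj)
    dg_signed = np.array([b.gantry - a.gantry for a, b in traj.sub_arcs])
    dr_signed = np.array([b.ring - a.ring for a, b in traj.sub_arcs])
    mu = subarc_mu(plan)
    g_lo, g_hi = mc.gantry_speed
    r_lo, r_hi = mc.ring_speed
    table = mc.dose_rate_table

    n = traj.n_subarcs
    ramp_mu_full = mc.mp_ramp_dose_rate * mc.mp_stop_duration / 60.0
    debit = 0.0
    segments: list[tuple[float, float, float, float, bool]] = []
    subarc_times = np.zeros(n)
    for k in range(n):
        m_k = max(mu[k] - debit, 0.0)
        t_motion = 0.0
        if g[k] > 0:
            t_motion = max(t_motion, g[k] / g_hi)
        if r[k] > 0:
            t_motion = max(t_motion, r[k] / r_hi)
        if t_motion <= 0:
            raise InfeasiblePlanError("degenerate sub-arc", binding="span", subarc=k)
        t_max = math.inf
        if g[k] > 0:
            t_max = min(t_max, g[k] / g_lo)
        if r[k] > 0:
            t_max = min(t_max, r[k] / r_lo)
        if t_motion > t_max + 1e-12:
            raise InfeasiblePlanError(
                "axis speed window is empty", binding="axis_speed", subarc=k)
        needed = 0.0 if m_k == 0 else m_k * 60.0 / t_motion
        dr = _smallest_rate_at_least(table, needed)
        if dr is None:
            dr = table[-1]
        t_k = max(t_motion, m_k * 60.0 / dr) if m_k > 0 else t_motion
        if t_k > t_max + 1e-12:
            raise InfeasiblePlanError(
                "MU-limited time pushes an axis below its minimum speed",
                binding="axis_min_speed", subarc=k)
        vg = dg_signed[k] / t_k
        vr = dr_signed[k] / t_k
        if m_k > 0:
            t_beam = m_k * 60.0 / dr
            segments.append((t_beam, vg, vr, dr, False))
            if t_k - t_beam > 1e-12:
                segments.append((t_k - t_beam, vg, vr, 0.0, False))
        else:
            segments.append((t_k, vg, vr, 0.0, False))
        subarc_times[k] = t_k
        debit = 0.0
        if k < n - 1 and mc.mp_stop_duration > 0:
            if beam_hold_at_mp:
                segments.append((mc.mp_stop_duration, 0.0, 0.0, 0.0, True))
            else:
                debit = min(ramp_mu_full, mu[k + 1])
                stop_dr = debit * 60.0 / mc.mp_stop_duration
                segments.append((mc.mp_stop_duration, 0.0, 0.0, stop_dr, True))
    return segments, subarc_times


def controller_simulate(plan: DeliveryPlan, mc: MachineConstraints,
                        *, beam_hold_at_mp: bool = False,
                        sample_rate: float = 100.0
                        ) -> tuple[DeliveryTrace, float]:
    """Emulate the fastest-delivery controller and emit a 100 Hz trace.

    Per sub-arc the controller independently picks gantry speed, ring
    speed and a dose-rate table entry minimising that sub-arc's time
    while delivering its MU; between sub-arcs the axes stop for
    ``mp_stop_duration`` while the dose rate ramps to
    ``mp_ramp_dose_rate`` (the MU delivered during the ramp is debited
    from the following sub-arc, so the trace conserves plan MU).  With
    ``beam_hold_at_mp`` the beam is held (zero dose rate) instead.

    Returns the trace and the total delivery time (stops included).
    """
    segments, _ = _subarc_schedule(plan, mc, beam_hold_at_mp)
    durations = np.array([s[0] for s in segments])
    ends = np.cumsum(durations)
    starts = ends - durations
    total_time = float(ends[-1])

    # angles at segment starts, integrated from the first MP
    g0 = plan.trajectory.manipulation_points[0].gantry
    r0 = plan.trajectory.manipulation_points[0].ring
    seg_g = np.empty(len(segments))
    seg_r = np.empty(len(segments))
    seg_mu0 = np.empty(len(segments))
    gacc, racc, muacc = g0, r0, 0.0
    for i, (dt, vg, vr, dr, _stop) in enumerate(segments):
        seg_g[i], seg_r[i], seg_mu0[i] = gacc, racc, muacc
        gacc += vg * dt
        racc += vr * dt
        muacc += dr * dt / 60.0

    n_samples = int(math.ceil(total_time * sample_rate)) + 1
    t = np.arange(n_samples) / sample_rate
    te = np.minimum(t, total_time)  # clamp the final sample to delivery end
    idx = np.clip(np.searchsorted(ends, te, side="right"), 0, len(segments) - 1)
    dt_in = te - starts[idx]
    vg = np.array([s[1] for s in segments])[idx]
    vr = np.array([s[2] for s in segments])[idx]
    dr_arr = np.array([s[3] for s in segments])[idx]
    stop = np.array([s[4] for s in segments])[idx]
    df = pd.DataFrame({
        "t": t,
        "gantry": seg_g[idx] + vg * dt_in,
        "ring": seg_r[idx] + vr * dt_in,
        "gantry_speed": np.abs(vg),
        "ring_speed": np.abs(vr),
        "dose_rate": dr_arr,
        "cumulative_mu": seg_mu0[idx] + dr_arr * dt_in / 60.0,
        "in_stop": stop,
    })
    trace = DeliveryTrace(sample_rate, df, total_time,
                          float(df["cumulative_mu"].iloc[-1]))
    return trace, total_time


def summarize_trace(trace: DeliveryTrace) -> dict[str, float]:
    """Log-file summary: mean speeds/dose rate over beam-on samples.

    MP stop samples are excluded from the speed and dose-rate means but
    are included in the total time.
    """
    df = trace.samples
    if df.empty:
        raise WaveArcError("empty trace")
    on = ~df["in_stop"].to_numpy(dtype=bool)
    if not on.any():
        raise WaveArcError("trace has no beam-on samples")
    return {
        "mean_gantry_speed": float(df.loc[on, "gantry_speed"].mean()),
        "mean_ring_speed": float(df.loc[on, "ring_speed"].mean()),
        "mean_dose_rate": float(df.loc[on, "dose_rate"].mean()),
        "total_time": trace.total_time,
        "total_mu": trace.total_mu,
    }


def time_overestimation(tps: TimeEstimate | float, actual_time: float) -> float:
    """Planner overestimation in percent: 100 * (T_tps - T_actual) / T_tps."""
    t_tps = tps.beam_on_time if isinstance(tps, TimeEstimate) else float(tps)
    if t_tps <= 0 or actual_time <= 0:
        raise WaveArcError("times must be positive")
    return 100.0 * (t_tps - actual_time) / t_tps


def controller_gap_times(plan: DeliveryPlan, mc: MachineConstraints,
                         *, beam_hold_at_mp: bool = False) -> np.ndarray:
    """Elapsed controller time between consecutive control points.

    MP stops falling inside a gap are included (the MLC may keep moving
    while the axes are stopped).
    """
    _, subarc_times = _subarc_schedule(plan, mc, beam_hold_at_mp)
    bounds = plan.trajectory.cumulative_norms()
    L = np.diff(bounds)
    rate = np.where(L > 0, L / np.maximum(subarc_times, 1e-300), 0.0)
    t_at_mp = np.concatenate(
        [[0.0], np.cumsum(subarc_times + mc.mp_stop_duration)])

    def t_of_norm(s: float) -> float:
        k = min(int(np.searchsorted(bounds, s, side="right") - 1), L.size - 1)
        k = max(k, 0)
        return t_at_mp[k] + (s - bounds[k]) / rate[k] if rate[k] > 0 else t_at_mp[k]

    times = np.array([t_of_norm(s) for s in plan.cp_norms])
    return np.diff(times)


def leaf_travel_feasibility(plan: DeliveryPlan, segment_times: np.ndarray,
                            mc: MachineConstraints) -> list[dict]:
    """Flag leaves whose required speed between CPs exceeds the limit.

    ``segment_times`` holds the elapsed time (s) between consecutive CPs
    (length n_cp - 1).  Returns one record per violating leaf with the
    gap index, bank, leaf index and required speed (cm/s); zero time with
    nonzero motion is reported as an infinite-speed violation.
    """
    times = np.asarray(segment_times, dtype=float)
    cps = plan.control_points
    if times.size != len(cps) - 1:
        raise WaveArcError("segment_times must have length n_cp - 1")
    out: list[dict] = []
    for j in range(times.size):
        a, b = cps[j].mlc, cps[j + 1].mlc
        if a is None or b is None:
            continue
        dt = times[j]
        for bank, pa, pb in (("left", a.left, b.left), ("right", a.right, b.right)):
            delta = np.abs(pb - pa)
            for leaf in np.nonzero(delta > 0)[0] if dt <= 0 else \
                    np.nonzero(delta / dt > mc.leaf_speed_max)[0]:
                speed = math.inf if dt <= 0 else float(delta[leaf] / dt)
                out.append({"gap": j, "bank": bank, "leaf": int(leaf),
                            "required_speed": speed})
    return out
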