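"""Seeded synthetic fixtures: plans, dose grids and pseudo-measurements.

Everything here is a pure function of its parameters and seed, so every
module is testable without external data.  The toy dose engine is
explicitly NOT a clinical dose algorithm: it projects the smoothed MLC
aperture along each control point's beam direction with a simple
exponential depth attenuation, which is enough to give dose grids that
are linear in MU, rotate with the plan angles and have realistic-looking
gradients -- nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .complexity import MLCAperture
from .delivery import (ControlPoint, DeliveryPlan, MachineConstraints)
from .errors import WaveArcError
from .gamma import DiodePlaneSet, DoseGrid3D
from .trajectory import (AngularPosition, TrajectoryRules, WaveArcTrajectory,
                         build_control_points, discretize_beams,
                         validate_trajectory)

__all__ = [
    "FixtureSpec", "generate_trajectory", "generate_plan",
    "toy_dose_engine", "default_diode_planes", "perturb_measurement",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study case.

    ``complexity`` in [0, 1] scales the per-CP MLC modulation: 0 gives an
    identical aperture at every CP (MCS exactly 1).  Defaults emulate a
    mid-size single-arc case: a 3-sub-arc wave, 300 MU, a 10-pair MLC
    with 0.5 cm leaves, and a 21^3 grid at 2 mm spacing.
    """

    seed: int = 0
    n_subarcs: int = 3
    mu_total: float = 300.0
    complexity: float = 0.3
    n_leaf_pairs: int = 10
    leaf_width_cm: float = 0.5
    grid_shape: tuple[int, int, int] = (21, 21, 21)
    grid_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd_pct: float = 0.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale_pct: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.complexity <= 1.0):
            raise WaveArcError("complexity must lie in [0, 1]")
        if self.n_subarcs < 1 or self.mu_total < 0:
            raise WaveArcError("n_subarcs >= 1 and mu_total >= 0 required")


def generate_trajectory(seed: int, n_subarcs: int = 3,
                        rules: TrajectoryRules | None = None) -> WaveArcTrajectory:
    """Random legal wave trajectory with ``n_subarcs`` gantry-dominant arcs.

    Gantry spans are multiples of 4 degrees in [24, 40], monotone
    increasing; ring deltas are multiples of 4 no larger than the gantry
    span, alternating direction at MPs and clamped to the ring range, so
    the result passes :func:`validate_trajectory` by construction.
    """
    rules = rules or TrajectoryRules()
    rng = np.random.default_rng(seed)
    g = 4.0 * rng.integers(0, 6)
    r = 0.0
    mps = [AngularPosition(g, r)]
    sign = 1 if rng.integers(0, 2) else -1
    for _ in range(n_subarcs):
        g_span = 4.0 * rng.integers(6, 11)  # 24..40 deg
        if g + g_span > 360.0:
            break
        max_r = min(g_span, rules.ring_limit - r if sign > 0
                    else rules.ring_limit + r)
        hi = int(max_r // 4)
        r_span = 4.0 * rng.integers(0, hi + 1) if hi >= 0 else 0.0
        g += g_span
        r += sign * r_span
        sign = -sign
        mps.append(AngularPosition(g, r))
    traj = WaveArcTrajectory(mps)
    report = validate_trajectory(traj, rules)
    if report:
        raise WaveArcError(f"generated trajectory is invalid: {report}")
    return traj


def generate_plan(spec: FixtureSpec,
                  rules: TrajectoryRules | None = None,
                  mc: MachineConstraints | None = None) -> DeliveryPlan:
    """Seeded delivery plan with trajectory, CPs, apertures and MU.

    The trajectory is legal under the default rules; control points
    follow the 2-per-beam-angle construction; MU is constant per CP; the
    apertures are a base rectangle modulated by a seeded random walk
    whose step size scales with ``spec.complexity``, kept small enough
    to remain leaf-speed feasible for the controller's segment times.
    """
    rules = rules or TrajectoryRules()
    mc = mc or MachineConstraints()
    rng = np.random.default_rng(spec.seed)
    traj = generate_trajectory(int(rng.integers(0, 2 ** 31)), spec.n_subarcs, rules)
    beams = discretize_beams(traj, rules)
    positions, norms = build_control_points(beams)
    n_cp = len(positions)

    n = spec.n_leaf_pairs
    widths = np.full(n, spec.leaf_width_cm)
    base_left = np.full(n, -2.5)
    base_right = np.full(n, 2.5)
    # random-walk modulation, step bounded so leaf speeds stay feasible
    step = 0.6 * spec.complexity
    left = base_left.copy()
    right = base_right.copy()
    apertures = []
    for _ in range(n_cp):
        apertures.append(MLCAperture(left.copy(), right.copy(), widths))
        left = np.clip(left + rng.uniform(-step, step, n), -6.0, -0.2)
        right = np.clip(right + rng.uniform(-step, step, n), 0.2, 6.0)

    w = spec.mu_total / (n_cp - 1)
    cps = tuple(ControlPoint(positions[i], 0.0 if i == 0 else w, apertures[i])
                for i in range(n_cp))
    return DeliveryPlan(traj, cps, cp_norms=norms)


def _beam_frame(gantry_deg: float, ring_deg: float):
    """Orthonormal (u, v, axis) beam frame from machine angles.

    Gantry rotates about the lab y axis (longitudinal), the ring about
    the vertical z axis; at gantry 0 / ring 0 the beam points along -z.
    """
    g = math.radians(gantry_deg)
    r = math.radians(ring_deg)
    d_g = np.array([math.sin(g), 0.0, -math.cos(g)])
    rz = np.array([[math.cos(r), -math.sin(r), 0.0],
                   [math.sin(r), math.cos(r), 0.0],
                   [0.0, 0.0, 1.0]])
    axis = rz @ d_g
    v = rz @ np.array([0.0, 1.0, 0.0])   # leaf-index direction
    u = np.cross(v, axis)                # leaf-travel direction
    return u, v, axis


def toy_dose_engine(plan: DeliveryPlan,
                    grid_shape: tuple[int, int, int] = (21, 21, 21),
                    grid_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
                    *, penumbra_sigma_mm: float = 4.0,
                    attenuation_per_mm: float = 0.004,
                    gy_per_mu: float = 0.01) -> DoseGrid3D:
    """Non-physical projection dose engine for fixtures.

    dose(x) = sum_cp mu_cp * T_cp(u, v) * exp(-mu_att * depth), where
    T_cp is the MLC aperture indicator smoothed along the leaf-travel
    axis with a Gaussian penumbra and depth is measured along the beam
    axis from the grid's upstream face.  Linear in MU by construction;
    closed leaf pairs transmit nothing.
    """
    shape = np.array(grid_shape)
    spacing = np.array(grid_spacing_mm, dtype=float)
    origin = -spacing * (shape - 1) / 2.0  # isocenter at the grid center
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    dose = np.zeros(pts.shape[0])
    for cp in plan.control_points[1:]:
        if cp.mu_weight == 0 or cp.mlc is None:
            continue
        u_ax, v_ax, axis = _beam_frame(cp.position.gantry, cp.position.ring)
        u = pts @ u_ax
        v = pts @ v_ax
        depth = pts @ axis
        depth -= depth.min()
        ap = cp.mlc
        widths_mm = ap.leaf_widths * 10.0
        v_edges = np.concatenate([[0.0], np.cumsum(widths_mm)])
        v_edges -= v_edges[-1] / 2.0
        trans = np.zeros_like(u)
        s = penumbra_sigma_mm
        for j in range(ap.n_pairs):
            if ap.right[j] <= ap.left[j]:
                continue
            in_strip = (v >= v_edges[j]) & (v < v_edges[j + 1])
            if not in_strip.any():
                continue
            l_mm, r_mm = ap.left[j] * 10.0, ap.right[j] * 10.0
            t = ndtr((u[in_strip] - l_mm) / s) * ndtr((r_mm - u[in_strip]) / s)
            trans[in_strip] += t
        dose += cp.mu_weight * trans * np.exp(-attenuation_per_mm * depth)
    values = (gy_per_mu * dose).reshape(tuple(shape))
    return DoseGrid3D(origin, spacing, values)


def default_diode_planes(grid: DoseGrid3D, pitch_mm: float = 5.0,
                         margin_mm: float = 2.0) -> np.ndarray:
    """Diode coordinates on two orthogonal planes through the grid center.

    Plane 0 lies at the central x, plane 1 at the central y; both share
    the grid's central vertical axis (duplicated axis points are kept
    only once).  Returns (points (N,3), plane labels (N,)).
    """
    lo, hi = grid.bounds()
    c = (lo + hi) / 2.0

    def axis_pts(i):
        a = np.arange(c[i], hi[i] - margin_mm + 1e-9, pitch_mm)
        b = np.arange(c[i] - pitch_mm, lo[i] + margin_mm - 1e-9, -pitch_mm)
        return np.sort(np.concatenate([b, a]))

    ys, zs, xs = axis_pts(1), axis_pts(2), axis_pts(0)
    p0 = np.array([[c[0], y, z] for y in ys for z in zs])
    p1 = np.array([[x, c[1], z] for x in xs for z in zs if x != c[0]])
    points = np.vstack([p0, p1]) if p1.size else p0
    planes = np.concatenate([np.zeros(len(p0), dtype=int),
                             np.ones(len(p1), dtype=int)])
    return points, planes


def perturb_measurement(planned: DoseGrid3D, points: np.ndarray,
                        planes: np.ndarray | None = None, *,
                        noise_sd_pct: float = 0.0,
                        shift_mm=(0.0, 0.0, 0.0),
                        scale_pct: float = 0.0,
                        seed: int = 0) -> DiodePlaneSet:
    """Sample the planned grid at diode points with a measurement model.

    measured_i = (1 + scale) * D_plan(p_i + shift) + eps_i, with eps
    Gaussian with sd ``noise_sd_pct`` percent of the grid maximum.  The
    zero-noise identity model returns exact planned samples; points
    (after shift) outside the grid raise.
    """
    interp = planned.interpolator()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    shifted = pts + np.asarray(shift_mm, dtype=float)
    try:
        doses = interp(shifted)
    except ValueError as exc:
        raise WaveArcError("diode (after shift) outside planned grid") from exc
    doses = (1.0 + scale_pct / 100.0) * doses
    if noise_sd_pct > 0:
        rng = np.random.default_rng(seed)
        doses = doses + rng.normal(
            0.0, noise_sd_pct / 100.0 * planned.values.max(), doses.shape)
    doses = np.clip(doses, 0.0, None)
    return DiodePlaneSet(pts, doses, planes)
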