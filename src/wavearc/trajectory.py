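"""Gantry-ring wave trajectories: definition, validation and discretization.

A wave trajectory for an O-ring linac is an ordered sequence of
*manipulation points* (MPs) in (gantry, ring) angle space.  The segment
between two consecutive MPs is a *sub-arc*; the ring rotation direction may
only reverse at an MP, while the gantry rotates monotonically along the
whole path.  Beam angles are laid out along the path at (nominally) uniform
increments of the Euclidean norm sqrt(dgantry^2 + dring^2), so a steep ring
excursion shortens the gantry spacing of the beams rather than being
ignored.  Two control points are then attached to every beam angle.

Angle conventions: gantry in degrees in [0, 360], IEC 61217 sense; ring in
degrees, positive clockwise viewed from above; all interpolation is linear
in angle space.  Sub-arcs must not cross the 0/360 gantry seam -- split
them beforehand if they do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, box

from .errors import TrajectoryError

GANTRY = "gantry"
RING = "ring"

_ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class AngularPosition:
    """A (gantry, ring) machine orientation in degrees."""

    gantry: float
    ring: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gantry) and math.isfinite(self.ring)):
            raise TrajectoryError("angles must be finite")
        if not (0.0 <= self.gantry <= 360.0):
            raise TrajectoryError(
                f"gantry angle {self.gantry} outside [0, 360]; "
                "normalize before constructing"
            )

    def as_tuple(self) -> tuple[float, float]:
        return (self.gantry, self.ring)


@dataclass(frozen=True)
class TrajectoryRules:
    """Vendor-style trajectory legality rules and beam spacing.

    dominant_multiple
        The dominant (larger) angular span of every sub-arc must be a
        multiple of this many degrees (default 4).
    min_subarc_span
        Minimum dominant span per sub-arc in degrees (default 24).
    max_ring_per_gantry
        Maximum ring-span/gantry-span ratio per sub-arc (default 1), which
        forbids sub-arcs that are too steep in ring rotation.
    beam_spacing
        Euclidean-norm increment between beam angles (default 24 degrees).
    ring_limit
        Symmetric ring range: ring must stay within [-limit, +limit].
    forbidden_zones
        Axis-aligned rectangles (gmin, gmax, rmin, rmax) in angle space a
        sub-arc segment may not intersect (configurable stand-in for the
        vendor's unpublished ring-table collision map).
    """

    dominant_multiple: float = 4.0
    min_subarc_span: float = 24.0
    max_ring_per_gantry: float = 1.0
    beam_spacing: float = 24.0
    ring_limit: float = 60.0
    forbidden_zones: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        for name in ("dominant_multiple", "min_subarc_span",
                     "max_ring_per_gantry", "beam_spacing", "ring_limit"):
            if getattr(self, name) <= 0:
                raise TrajectoryError(f"{name} must be positive")


@dataclass(frozen=True)
class WaveArcTrajectory:
    """Ordered manipulation points defining a gantry-ring wave path."""

    manipulation_points: tuple[AngularPosition, ...]

    def __init__(self, manipulation_points) -> None:
        mps = tuple(manipulation_points)
        if len(mps) < 2:
            raise TrajectoryError("a trajectory needs at least 2 manipulation points")
        object.__setattr__(self, "manipulation_points", mps)

    @property
    def sub_arcs(self) -> list[tuple[AngularPosition, AngularPosition]]:
        mps = self.manipulation_points
        return [(mps[i], mps[i + 1]) for i in range(len(mps) - 1)]

    @property
    def n_subarcs(self) -> int:
        return len(self.manipulation_points) - 1

    def subarc_norms(self) -> np.ndarray:
        """Euclidean norm of every sub-arc, in degrees."""
        out = np.empty(self.n_subarcs)
        for i, (a, b) in enumerate(self.sub_arcs):
            out[i] = math.hypot(b.gantry - a.gantry, b.ring - a.ring)
        return out

    def cumulative_norms(self) -> np.ndarray:
        """Cumulative Euclidean path length at each MP (starts at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.subarc_norms())])

    def position_at_norm(self, s: float) -> AngularPosition:
        """Linearly interpolated (gantry, ring) at cumulative norm ``s``."""
        cum = self.cumulative_norms()
        total = cum[-1]
        if s < -_ANGLE_TOL or s > total + _ANGLE_TOL:
            raise TrajectoryError(f"norm {s} outside [0, {total}]")
        s = min(max(s, 0.0), total)
        k = int(np.searchsorted(cum, s, side="right") - 1)
        k = min(k, self.n_subarcs - 1)
        a, b = self.sub_arcs[k]
        span = cum[k + 1] - cum[k]
        t = 0.0 if span <= _ANGLE_TOL else (s - cum[k]) / span
        return AngularPosition(a.gantry + t * (b.gantry - a.gantry),
                               a.ring + t * (b.ring - a.ring))


def subarc_dominant_angle(a: AngularPosition, b: AngularPosition) -> str:
    """Return which axis dominates a sub-arc: ``"gantry"`` or ``"ring"``.

    The dominant axis is the one with the larger absolute span; ties go to
    the gantry (the primary rotation axis).  A sub-arc with zero span on
    both axes is degenerate and raises :class:`TrajectoryError`.
    """
    gs = abs(b.gantry - a.gantry)
    rs = abs(b.ring - a.ring)
    if gs <= _ANGLE_TOL and rs <= _ANGLE_TOL:
        raise TrajectoryError("degenerate sub-arc: zero span on both axes")
    return GANTRY if gs >= rs else RING


@dataclass(frozen=True)
class Violation:
    """One broken trajectory rule; ``subarc`` is None for global rules."""

    rule: str
    message: str
    subarc: int | None = None


def _is_multiple(value: float, base: float, tol: float = 1e-6) -> bool:
    ratio = value / base
    return abs(ratio - round(ratio)) <= tol


def validate_trajectory(traj: WaveArcTrajectory,
                        rules: TrajectoryRules | None = None) -> list[Violation]:
    """Check every trajectory rule; an empty report means the path is legal.

    Violations are data, not exceptions: all broken rules are reported with
    the index of the offending sub-arc.  Checks per sub-arc: distinct
    endpoints, dominant span a multiple of ``dominant_multiple`` and at
    least ``min_subarc_span``, ring/gantry span ratio at most
    ``max_ring_per_gantry``, ring inside the machine range, no forbidden
    zone crossed.  Globally: gantry monotone (only the ring may reverse at
    an MP).
    """
    rules = rules or TrajectoryRules()
    out: list[Violation] = []

    mps = traj.manipulation_points
    for i, mp in enumerate(mps):
        if abs(mp.ring) > rules.ring_limit + _ANGLE_TOL:
            out.append(Violation("ring_range",
                                 f"MP {i} ring {mp.ring} outside "
                                 f"[-{rules.ring_limit}, {rules.ring_limit}]"))

    signs = set()
    for i, (a, b) in enumerate(traj.sub_arcs):
        dg = b.gantry - a.gantry
        dr = b.ring - a.ring
        gs, rs = abs(dg), abs(dr)
        if gs <= _ANGLE_TOL and rs <= _ANGLE_TOL:
            out.append(Violation("degenerate_subarc",
                                 "consecutive identical MPs", i))
            continue
        if gs > _ANGLE_TOL:
            signs.add(1 if dg > 0 else -1)
        dom = max(gs, rs)
        if not _is_multiple(dom, rules.dominant_multiple):
            out.append(Violation(
                "dominant_multiple",
                f"dominant span {dom:g} not a multiple of "
                f"{rules.dominant_multiple:g} deg", i))
        if dom < rules.min_subarc_span - _ANGLE_TOL:
            out.append(Violation(
                "min_subarc_span",
                f"dominant span {dom:g} < {rules.min_subarc_span:g} deg", i))
        if rs > rules.max_ring_per_gantry * gs + _ANGLE_TOL:
            out.append(Violation(
                "ring_per_gantry",
                f"ring span {rs:g} exceeds {rules.max_ring_per_gantry:g} x "
                f"gantry span {gs:g}", i))
        for zone in rules.forbidden_zones:
            gmin, gmax, rmin, rmax = zone
            seg = LineString([a.as_tuple(), b.as_tuple()])
            if seg.intersects(box(gmin, rmin, gmax, rmax)):
                out.append(Violation(
                    "forbidden_zone",
                    f"sub-arc crosses forbidden zone {zone}", i))
    if len(signs) > 1:
        out.append(Violation("gantry_monotone",
                             "gantry direction reverses along the path"))
    return out


def path_length_euclidean(traj: WaveArcTrajectory) -> float:
    """Total Euclidean path length sum_i sqrt(dg_i^2 + dr_i^2), degrees."""
    return float(traj.subarc_norms().sum())


@dataclass(frozen=True)
class BeamAngleSet:
    """Beam angles laid out on a trajectory, with cumulative path norms."""

    trajectory: WaveArcTrajectory
    positions: tuple[AngularPosition, ...]
    cumulative_norm: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.positions)


def discretize_beams(traj: WaveArcTrajectory,
                     rules: TrajectoryRules | None = None) -> BeamAngleSet:
    """Place beam angles along the path at uniform Euclidean-norm spacing.

    Per sub-arc of norm L the segment count is n = round(L / beam_spacing)
    (half-up, minimum 1), so the actual spacing L/n is as close to the
    nominal spacing as possible while keeping every MP a beam angle.  A
    sub-arc shorter than the spacing contributes no interior beams.
    """
    rules = rules or TrajectoryRules()
    cum = traj.cumulative_norms()
    norms: list[float] = [0.0]
    for k, (a, b) in enumerate(traj.sub_arcs):
        L = cum[k + 1] - cum[k]
        if L <= _ANGLE_TOL:
            raise TrajectoryError(f"degenerate sub-arc {k}")
        n = max(1, int(math.floor(L / rules.beam_spacing + 0.5)))
        for j in range(1, n + 1):
            norms.append(cum[k] + L * j / n)
    arr = np.asarray(norms)
    positions = tuple(traj.position_at_norm(s) for s in arr)
    return BeamAngleSet(traj, positions, arr)


def build_control_points(beams: BeamAngleSet) -> tuple[tuple[AngularPosition, ...], np.ndarray]:
    """Attach two control points to every beam angle.

    CPs straddle each beam position symmetrically at +-1/4 of the local
    inter-beam norm (left gap for the lower CP, right gap for the upper),
    clamped to the trajectory ends, so consecutive CPs around a beam are
    equally distributed between adjacent beams.  Returns the CP angle
    list and their cumulative norms, strictly ordered.
    """
    s = beams.cumulative_norm
    if len(s) < 2:
        raise TrajectoryError("need at least 2 beam positions")
    norms: list[float] = []
    m = len(s) - 1
    for i in range(m + 1):
        lo = s[i] if i == 0 else s[i] - (s[i] - s[i - 1]) / 4.0
        hi = s[i] if i == m else s[i] + (s[i + 1] - s[i]) / 4.0
        norms.extend([lo, hi])
    arr = np.asarray(norms)
    if not np.all(np.diff(arr) > 0):
        raise TrajectoryError("control-point norms are not strictly increasing")
    positions = tuple(beams.trajectory.position_at_norm(v) for v in arr)
    return positions, arr


def project_onto_trajectory(traj: WaveArcTrajectory, pos: AngularPosition,
                            tol: float = 1e-3) -> float:
    """Cumulative norm of a point lying on the trajectory.

    Raises :class:`TrajectoryError` if the point is farther than ``tol``
    degrees from every sub-arc segment (used to validate that loaded
    control points actually lie on the plan's trajectory).
    """
    cum = traj.cumulative_norms()
    for k, (a, b) in enumerate(traj.sub_arcs):
        dg = b.gantry - a.gantry
        dr = b.ring - a.ring
        L2 = dg * dg + dr * dr
        if L2 <= _ANGLE_TOL:
            continue
        t = ((pos.gantry - a.gantry) * dg + (pos.ring - a.ring) * dr) / L2
        t = min(max(t, 0.0), 1.0)
        err = math.hypot(a.gantry + t * dg - pos.gantry,
                         a.ring + t * dr - pos.ring)
        if err <= tol:
            return float(cum[k] + t * math.sqrt(L2))
    raise TrajectoryError(
        f"point (g={pos.gantry}, r={pos.ring}) not on trajectory (tol {tol} deg)")
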