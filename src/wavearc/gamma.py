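"""Minimum 3D gamma-index dose verification for diode-plane measurements.

A diode array samples the delivered dose on two orthogonal planes.  Each
diode is scored against the *full* planned 3D dose grid: the gamma index
is the minimum over all search points r of

    sqrt( ((D_plan(r) - d_meas) / (dd% * D_max))^2  +  (|r - r_diode| / DTA)^2 )

with global normalisation (dd% of the planned grid maximum) and
distance-to-agreement DTA.  Diodes below the low-dose threshold (percent
of the planned maximum) are excluded from the passing-rate denominator.
A diode passes when gamma <= 1 (a 1e-9 numerical tolerance absorbs float
rounding at the exact boundary).

Pulse-resolved measurements can be re-binned into control points by the
planned cumulative MU and corrected with per-CP angular factors before
scoring, mirroring how noncoplanar deliveries are reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .delivery import DeliveryPlan
from .errors import WaveArcError

__all__ = [
    "DoseGrid3D", "DiodePlaneSet", "GammaCriteria", "GammaResult",
    "gamma_min3d", "passing_rate", "bin_pulses_to_cps",
    "apply_angular_corrections", "identity_correction",
    "cosine_falloff_correction",
]

_PASS_TOL = 1e-9


@dataclass(frozen=True)
class DoseGrid3D:
    """Dose values (Gy) on a regular lattice; origin/spacing in mm."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if origin.shape != (3,) or spacing.shape != (3,) or values.ndim != 3:
            raise WaveArcError("grid needs 3D origin/spacing and a 3D value array")
        if np.any(spacing <= 0):
            raise WaveArcError("grid spacing must be positive")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise WaveArcError("dose values must be finite and non-negative")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
                     for i in range(3))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        hi = self.origin + self.spacing * (np.array(self.shape) - 1)
        return self.origin.copy(), hi

    def interpolator(self) -> RegularGridInterpolator:
        """Trilinear interpolator over the grid (error outside bounds)."""
        return RegularGridInterpolator(self.axes(), self.values,
                                       method="linear", bounds_error=True)

    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class DiodePlaneSet:
    """Diode coordinates (mm) and measured doses (Gy) on two planes."""

    points: np.ndarray
    doses: np.ndarray
    planes: np.ndarray = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        doses = np.asarray(self.doses, dtype=float)
        if pts.shape[1] != 3 or doses.shape != (pts.shape[0],):
            raise WaveArcError("points must be (N, 3) with matching doses")
        uniq = np.unique(pts, axis=0)
        if uniq.shape[0] != pts.shape[0]:
            raise WaveArcError("diode coordinates must be unique")
        planes = (np.zeros(pts.shape[0], dtype=int) if self.planes is None
                  else np.asarray(self.planes))
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "planes", planes)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class GammaCriteria:
    """Acceptance parameters: dd% of global max / DTA mm / threshold %."""

    dose_tolerance: float = 3.0
    distance_tolerance: float = 3.0
    low_dose_threshold: float = 20.0

    def __post_init__(self) -> None:
        if min(self.dose_tolerance, self.distance_tolerance,
               self.low_dose_threshold) <= 0:
            raise WaveArcError("gamma criteria must be positive")


@dataclass(frozen=True)
class GammaResult:
    """Per-diode gamma values (NaN where below threshold) and pass rate."""

    gamma: np.ndarray
    passing_rate: float
    evaluated_count: int


def _axis_offsets(center: float, lo: float, hi: float, step: float,
                  radius: float) -> np.ndarray:
    r = min(radius, max(hi - center, center - lo))
    k = int(np.floor(r / step + 1e-12))
    offs = center + step * np.arange(-k, k + 1)
    return offs[(offs >= lo - 1e-9) & (offs <= hi + 1e-9)]


def gamma_min3d(measured: DiodePlaneSet, planned: DoseGrid3D,
                crit: GammaCriteria = GammaCriteria()) -> GammaResult:
    """Minimum 3D gamma index of each diode against the planned volume.

    The search lattice is anchored at the diode with a sub-voxel step of
    DTA/10 in every axis; the dose-difference gamma at the diode itself
    bounds the useful search radius (beyond best*DTA the distance term
    alone already exceeds the running best), so the search is restricted
    to that ball without changing the minimum over the lattice.  Planned
    dose is interpolated trilinearly.
    """
    gmax = float(planned.values.max())
    if gmax <= 0:
        raise WaveArcError("planned grid maximum must be positive")
    lo, hi = planned.bounds()
    if np.any(measured.points < lo - 1e-9) or np.any(measured.points > hi + 1e-9):
        raise WaveArcError("planned grid must enclose the diode planes")
    dd_abs = crit.dose_tolerance / 100.0 * gmax
    dta = crit.distance_tolerance
    thr = crit.low_dose_threshold / 100.0 * gmax
    step = dta / 10.0
    interp = planned.interpolator()

    gamma = np.full(len(measured), np.nan)
    eval_idx = np.nonzero(measured.doses >= thr)[0]
    if eval_idx.size == 0:
        raise WaveArcError("no diode above the low-dose threshold")
    for i in eval_idx:
        p = measured.points[i]
        d = measured.doses[i]
        best = abs(float(interp(p)[0]) - d) / dd_abs
        if best > 0:
            radius = best * dta
            ox = _axis_offsets(p[0], lo[0], hi[0], step, radius)
            oy = _axis_offsets(p[1], lo[1], hi[1], step, radius)
            oz = _axis_offsets(p[2], lo[2], hi[2], step, radius)
            # chunk along x to bound memory on large search balls
            for x in ox:
                yy, zz = np.meshgrid(oy, oz, indexing="ij")
                pts = np.column_stack([np.full(yy.size, x),
                                       yy.ravel(), zz.ravel()])
                dist2 = ((pts - p) ** 2).sum(axis=1)
                keep = dist2 <= radius * radius + 1e-9
                if not keep.any():
                    continue
                dvals = interp(pts[keep])
                g2 = ((dvals - d) / dd_abs) ** 2 + dist2[keep] / (dta * dta)
                best = min(best, float(np.sqrt(g2.min())))
        gamma[i] = best
    rate = 100.0 * float(np.sum(gamma[eval_idx] <= 1.0 + _PASS_TOL)) / eval_idx.size
    return GammaResult(gamma, rate, int(eval_idx.size))


def passing_rate(result: GammaResult) -> float:
    """Percent of evaluated diodes with gamma <= 1 (1 counts as a pass)."""
    if result.evaluated_count == 0:
        raise WaveArcError("no evaluated diodes")
    return result.passing_rate


def bin_pulses_to_cps(pulse_mu: np.ndarray, pulse_values: np.ndarray,
                      plan: DeliveryPlan) -> np.ndarray:
    """Sort delivery-ordered dose pulses into control-point bins by MU.

    Bin boundaries are the plan's cumulative MU per CP; a pulse straddling
    a boundary is split pro-rata.  ``pulse_values`` is (n_pulses,) or
    (n_pulses, n_diodes); returns per-CP-gap sums with the matching
    trailing shape.  Raises if the pulse MU total differs from the plan
    total by more than 1%.
    """
    mu = np.asarray(pulse_mu, dtype=float)
    vals = np.asarray(pulse_values, dtype=float)
    if vals.shape[0] != mu.size:
        raise WaveArcError("pulse_values must align with pulse_mu")
    cp_mu = np.array([cp.mu_weight for cp in plan.control_points[1:]])
    total = cp_mu.sum()
    if total <= 0:
        raise WaveArcError("plan has zero MU")
    if abs(mu.sum() - total) > 0.01 * total:
        raise WaveArcError(
            f"pulse MU total {mu.sum():g} differs from plan total {total:g} by >1%")
    edges = np.concatenate([[0.0], np.cumsum(cp_mu)])
    out = np.zeros((cp_mu.size,) + vals.shape[1:])
    start = np.concatenate([[0.0], np.cumsum(mu)[:-1]])
    for j in range(mu.size):
        a, b = start[j], start[j] + mu[j]
        if mu[j] <= 0:
            continue
        for k in range(cp_mu.size):
            lo, hi = max(a, edges[k]), min(b, edges[k + 1])
            if k == cp_mu.size - 1:
                hi = min(b, max(edges[k + 1], b))  # last bin absorbs rounding
            if hi > lo:
                out[k] += vals[j] * (hi - lo) / mu[j]
    return out


def identity_correction(gantry: float, ring: float,
                        planes: np.ndarray | None = None):
    """Angular correction model that applies no correction."""
    return 1.0


def cosine_falloff_correction(strength: float = 0.05) -> Callable:
    """Example pluggable model: mild cosine falloff with ring tilt.

    Returns factor 1 - strength * (1 - cos(ring)); a stand-in shape for
    detector angular response, not a vendor calibration.
    """
    def model(gantry: float, ring: float, planes=None):
        return 1.0 - strength * (1.0 - np.cos(np.deg2rad(ring)))
    return model


def apply_angular_corrections(per_cp_doses: np.ndarray, plan: DeliveryPlan,
                              correction_model: Callable = identity_correction
                              ) -> np.ndarray:
    """Per-CP angular factors applied during dose reconstruction.

    ``per_cp_doses`` is (n_gaps,) or (n_gaps, n_diodes), aligned with the
    CP gaps (the angles of the CP ending each gap are used).  The model
    maps (gantry, ring, planes) to a positive multiplicative factor
    (scalar or per-diode).  Returns the corrected summed dose.
    """
    doses = np.asarray(per_cp_doses, dtype=float)
    cps = plan.control_points[1:]
    if doses.shape[0] != len(cps):
        raise WaveArcError("per_cp_doses must align with the plan's CP gaps")
    total = np.zeros(doses.shape[1:])
    for k, cp in enumerate(cps):
        f = np.asarray(correction_model(cp.position.gantry, cp.position.ring))
        if np.any(f <= 0):
            raise WaveArcError("angular correction factors must be positive")
        total = total + f * doses[k]
    return total
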