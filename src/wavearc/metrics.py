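"""Plan-quality metrics and the comparative statistics for benchmarks.

Covers the target/spillage ratios and DVH point queries used to compare
delivery techniques, plus percent-change reporting and the paired
two-tailed t-test (p < 0.05 significant) used for technique comparisons.

Conventions: all dose thresholds are closed (>=); D_x% is the dose
received by the hottest x% of the structure volume, linearly interpolated
on the sorted voxel-dose curve; voxels are uniform rectilinear boxes with
volume equal to the product of the grid spacings (no partial-volume
weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, WaveArcError
from .gamma import DoseGrid3D

__all__ = [
    "StructureMask", "PlanMetricsReport", "coverage_ratio",
    "low_dose_spillage", "dvh_point", "percent_change", "paired_t_test",
]


@dataclass(frozen=True)
class StructureMask:
    """Boolean occupancy of a structure on a dose grid's lattice."""

    name: str
    mask: np.ndarray = field(repr=False)
    voxel_volume_cc: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if self.voxel_volume_cc <= 0:
            raise WaveArcError("voxel volume must be positive")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_grid(cls, name: str, mask: np.ndarray, grid: DoseGrid3D) -> "StructureMask":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise WaveArcError("mask must share the dose grid's lattice")
        return cls(name, mask, grid.voxel_volume_cc())

    @property
    def volume_cc(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_cc


@dataclass(frozen=True)
class PlanMetricsReport:
    """Summary of one plan's quality and delivery figures."""

    coverage: float
    low_dose_spillage: float
    dvh_points: dict
    mu: float | None = None
    time_min: float | None = None


def _check_alignment(mask: StructureMask, dose: DoseGrid3D) -> None:
    if mask.mask.shape != dose.shape:
        raise WaveArcError("mask and dose grid lattices differ")
    if not mask.mask.any():
        raise WaveArcError(f"structure '{mask.name}' is empty")


def coverage_ratio(ptv: StructureMask, dose: DoseGrid3D,
                   prescription: float) -> float:
    """Fraction of PTV volume inside the prescription isodose (>=)."""
    _check_alignment(ptv, dose)
    inside = dose.values[ptv.mask] >= prescription
    return float(inside.sum()) / float(ptv.mask.sum())


def low_dose_spillage(ptv: StructureMask, dose: DoseGrid3D,
                      prescription: float) -> float:
    """Volume receiving >=50% of prescription over PTV volume.

    The 50% isodose volume is taken over the whole grid (it includes the
    PTV itself).
    """
    _check_alignment(ptv, dose)
    v50 = float((dose.values >= 0.5 * prescription).sum())
    return v50 / float(ptv.mask.sum())


def dvh_point(mask: StructureMask, dose: DoseGrid3D, query: str) -> float:
    """Evaluate one DVH query on a structure.

    Supported queries: ``"D2%"`` (dose to the hottest 2% of the volume,
    Gy), ``"Dmean"``, ``"Dmax"``, ``"V30Gy"`` (volume in cc receiving
    >= 30 Gy), ``"V30Gy%"`` (same as percent of structure volume).
    Percent arguments must lie in (0, 100].
    """
    _check_alignment(mask, dose)
    doses = np.sort(dose.values[mask.mask])[::-1]
    q = query.strip()
    if q == "Dmean":
        return float(doses.mean())
    if q == "Dmax":
        return float(doses[0])
    if q.startswith("D") and q.endswith("%"):
        x = float(q[1:-1])
        if not (0 < x <= 100):
            raise WaveArcError("D_x% requires x in (0, 100]")
        n = doses.size
        # dose of the hottest x%: k voxels cover a fraction k/n
        fracs = np.arange(1, n + 1) / n
        return float(np.interp(x / 100.0, fracs, doses))
    if q.startswith("V") and q.endswith("Gy%"):
        x = float(q[1:-3])
        frac = float((doses >= x).sum()) / doses.size
        return 100.0 * frac
    if q.startswith("V") and q.endswith("Gy"):
        x = float(q[1:-2])
        return float((doses >= x).sum()) * mask.voxel_volume_cc
    raise WaveArcError(f"unrecognized DVH query '{query}'")


def percent_change(reference: float, new: float, mode: str = "reduction",
                   *, rounded: bool = False) -> float:
    """Percent change of ``new`` relative to ``reference``.

    ``reduction`` = 100*(ref - new)/ref; ``increase`` = 100*(new - ref)/ref.
    Rounding (half up, to the nearest integer) is applied only when
    ``rounded`` is requested, i.e. at report level.
    """
    if reference <= 0:
        raise WaveArcError("reference must be positive")
    if mode == "reduction":
        value = 100.0 * (reference - new) / reference
    elif mode == "increase":
        value = 100.0 * (new - reference) / reference
    else:
        raise WaveArcError("mode must be 'reduction' or 'increase'")
    if rounded:
        return float(np.floor(value + 0.5))
    return value


def paired_t_test(sample_a, sample_b) -> dict:
    """Paired two-tailed Student's t-test (n-1 degrees of freedom).

    Returns ``{"t", "p", "significant"}`` with significance at p < 0.05.
    Raises :class:`DegenerateInputError` when the paired differences have
    zero variance (all equal, including all zero), where t is undefined
    or infinite.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise WaveArcError("samples must be equal-length with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateInputError("paired differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < 0.05)}
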