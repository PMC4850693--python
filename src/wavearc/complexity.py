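"""Modulation complexity score (MCS) for dynamic-MLC arc plans.

The MCS combines, per control point, the leaf sequence variability (LSV,
how ragged each leaf bank is relative to its own maximal position spread)
and the aperture area variability (AAV, the aperture area relative to the
arc's maximal per-leaf envelope).  Adjacent-CP means of LSV and AAV are
multiplied, weighted by the fraction of monitor units delivered between
the two CPs, and summed over the arc.  MCS lies in [0, 1]; 1 means an
unmodulated (constant, maximally open) delivery.

Conventions frozen here: a leaf pair is *open* when right > left; closed
pairs are excluded from the LSV position sets and contribute zero area;
when the open pairs form several disjoint runs the positions are
concatenated in leaf-index order; a degenerate bank whose open-leaf
positions all coincide scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateApertureError

__all__ = ["MLCAperture", "ArcSequence", "lsv", "aav", "mcs_arc"]


@dataclass(frozen=True)
class MLCAperture:
    """Opposing-bank MLC aperture; positions in cm at isocenter."""

    left: np.ndarray
    right: np.ndarray
    leaf_widths: np.ndarray

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        widths = np.asarray(self.leaf_widths, dtype=float)
        if left.shape != right.shape or left.shape != widths.shape:
            raise DegenerateApertureError("bank/width arrays must share a shape")
        if np.any(widths <= 0):
            raise DegenerateApertureError("leaf widths must be positive")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        object.__setattr__(self, "leaf_widths", widths)

    @property
    def open_flags(self) -> np.ndarray:
        return self.right > self.left

    @property
    def n_pairs(self) -> int:
        return self.left.size

    def area(self) -> float:
        """Open aperture area (cm^2); closed pairs contribute nothing."""
        o = self.open_flags
        return float(np.sum((self.right[o] - self.left[o]) * self.leaf_widths[o]))


@dataclass(frozen=True)
class ArcSequence:
    """Per-CP apertures plus the MU delivered between consecutive CPs."""

    apertures: tuple[MLCAperture, ...]
    mu_between: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_between, dtype=float)
        if len(self.apertures) < 2:
            raise DegenerateApertureError("an arc needs at least 2 control points")
        if mu.size != len(self.apertures) - 1:
            raise DegenerateApertureError("len(mu_between) must be n_cp - 1")
        if np.any(mu < 0):
            raise DegenerateApertureError("mu_between must be non-negative")
        object.__setattr__(self, "mu_between", mu)

    @property
    def mu_total(self) -> float:
        return float(self.mu_between.sum())


def _bank_lsv(positions: np.ndarray) -> float:
    # positions of the open-region leaves of one bank, in index order
    if positions.size < 2:
        return 1.0
    pos_max = float(positions.max() - positions.min())
    if pos_max == 0.0:
        return 1.0
    diffs = np.abs(np.diff(positions))
    return float(np.sum(pos_max - diffs) / ((positions.size - 1) * pos_max))


def lsv(aperture: MLCAperture) -> float:
    """Leaf sequence variability of one aperture, in [0, 1].

    Per bank, with p_i the positions of the N leaves spanning the open
    region and pos_max their spread:
    LSV_bank = sum_{i<N} (pos_max - |p_{i+1} - p_i|) / ((N-1) * pos_max),
    and LSV = LSV_left * LSV_right.  Raises if no pair is open.
    """
    o = aperture.open_flags
    if not o.any():
        raise DegenerateApertureError("aperture has no open leaf pair")
    return _bank_lsv(aperture.left[o]) * _bank_lsv(aperture.right[o])


def aav(aperture: MLCAperture, arc: ArcSequence) -> float:
    """Aperture area variability: CP area over the arc's maximal envelope.

    The envelope is computed per leaf pair as (max over the arc of the
    right position minus min over the arc of the left position), taking
    the max/min over the CPs where that pair is open, and summed over all
    pairs that open anywhere in the arc.
    """
    n = aperture.n_pairs
    env = np.zeros(n)
    widths = aperture.leaf_widths
    ever_open = np.zeros(n, dtype=bool)
    rmax = np.full(n, -np.inf)
    lmin = np.full(n, np.inf)
    for ap in arc.apertures:
        o = ap.open_flags
        ever_open |= o
        rmax[o] = np.maximum(rmax[o], ap.right[o])
        lmin[o] = np.minimum(lmin[o], ap.left[o])
    if not ever_open.any():
        raise DegenerateApertureError("no leaf pair opens anywhere in the arc")
    env[ever_open] = (rmax[ever_open] - lmin[ever_open]) * widths[ever_open]
    denom = float(env.sum())
    if denom <= 0:
        raise DegenerateApertureError("arc envelope has zero area")
    return aperture.area() / denom


def mcs_arc(arc: ArcSequence) -> float:
    """Arc modulation complexity score in [0, 1] (1 = no modulation).

    MCS = sum_i (AAV_i + AAV_{i+1})/2 * (LSV_i + LSV_{i+1})/2
                * mu_between_i / mu_total.
    """
    if arc.mu_total <= 0:
        raise DegenerateApertureError("arc has zero total MU")
    lsvs = np.array([lsv(ap) for ap in arc.apertures])
    aavs = np.array([aav(ap, arc) for ap in arc.apertures])
    w = arc.mu_between / arc.mu_total
    pair_lsv = 0.5 * (lsvs[:-1] + lsvs[1:])
    pair_aav = 0.5 * (aavs[:-1] + aavs[1:])
    return float(np.sum(pair_lsv * pair_aav * w))
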