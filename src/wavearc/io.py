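"""File formats: YAML plan files, text dose grids, RLE masks, CSV traces.

Plan and configuration files are versioned YAML; dose grids are plain
text with a JSON header line (origin/spacing/shape, dose unit Gy);
structure masks are run-length encoded text aligned to the grid header;
traces and diode data are CSV.  DICOM-RT Plan files can be read (never
written) to import per-CP gantry/ring geometry.

Units on disk: angles in degrees, lengths in mm, MLC positions in cm at
isocenter (converted nowhere -- the aperture interface is cm throughout).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .complexity import MLCAperture
from .delivery import ControlPoint, DeliveryPlan, MachineConstraints
from .errors import PlanFileError, WaveArcError
from .gamma import DoseGrid3D
from .metrics import StructureMask
from .trajectory import AngularPosition, TrajectoryRules, WaveArcTrajectory

log = logging.getLogger("wavearc")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PlanFile:
    """A parsed plan file: the plan plus optional rule/machine blocks."""

    plan: DeliveryPlan
    rules: TrajectoryRules | None = None
    machine: MachineConstraints | None = None


def _round6(x: float) -> float:
    return float(round(float(x), 6))


def write_plan(pf: PlanFile | DeliveryPlan, path) -> None:
    """Write a plan (and optional rules/machine blocks) as canonical YAML."""
    if isinstance(pf, DeliveryPlan):
        pf = PlanFile(pf)
    plan = pf.plan
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "trajectory": {
            "manipulation_points": [
                {"gantry": _round6(mp.gantry), "ring": _round6(mp.ring)}
                for mp in plan.trajectory.manipulation_points
            ]
        },
        "control_points": [
            {
                "gantry": _round6(cp.position.gantry),
                "ring": _round6(cp.position.ring),
                "mu_weight": _round6(cp.mu_weight),
                **({"left": [_round6(v) for v in cp.mlc.left],
                    "right": [_round6(v) for v in cp.mlc.right]}
                   if cp.mlc is not None else {}),
            }
            for cp in plan.control_points
        ],
    }
    first_mlc = plan.control_points[0].mlc
    if first_mlc is not None:
        doc["leaf_widths"] = [_round6(v) for v in first_mlc.leaf_widths]
    if pf.rules is not None:
        doc["rules"] = {
            "dominant_multiple": pf.rules.dominant_multiple,
            "min_subarc_span": pf.rules.min_subarc_span,
            "max_ring_per_gantry": pf.rules.max_ring_per_gantry,
            "beam_spacing": pf.rules.beam_spacing,
            "ring_limit": pf.rules.ring_limit,
            "forbidden_zones": [list(z) for z in pf.rules.forbidden_zones],
        }
    if pf.machine is not None:
        doc["machine"] = {
            "gantry_speed": list(pf.machine.gantry_speed),
            "ring_speed": list(pf.machine.ring_speed),
            "dose_rate_table": list(pf.machine.dose_rate_table),
            "leaf_speed_max": pf.machine.leaf_speed_max,
            "mp_stop_duration": pf.machine.mp_stop_duration,
            "mp_ramp_dose_rate": pf.machine.mp_ramp_dose_rate,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_plan(path) -> PlanFile:
    """Read and schema-validate a plan file; errors list every bad field."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise PlanFileError([f"unparseable YAML: {exc}"]) from exc
    if not isinstance(doc, dict):
        raise PlanFileError(["file is not a mapping"])
    problems: list[str] = []
    if doc.get("schema_version") != SCHEMA_VERSION:
        problems.append(f"schema_version must be {SCHEMA_VERSION}")
    traj_doc = doc.get("trajectory")
    if not isinstance(traj_doc, dict) or "manipulation_points" not in traj_doc:
        problems.append("trajectory.manipulation_points missing")
        raise PlanFileError(problems)
    mps = []
    for i, rec in enumerate(traj_doc["manipulation_points"]):
        for key in ("gantry", "ring"):
            if key not in rec:
                problems.append(f"manipulation_points[{i}].{key} missing")
        if all(k in rec for k in ("gantry", "ring")):
            mps.append(AngularPosition(rec["gantry"], rec["ring"]))
    cps_doc = doc.get("control_points")
    if not isinstance(cps_doc, list) or len(cps_doc) < 2:
        problems.append("control_points must be a list with >= 2 entries")
        raise PlanFileError(problems)
    widths = doc.get("leaf_widths")
    cps = []
    for i, rec in enumerate(cps_doc):
        for key in ("gantry", "ring", "mu_weight"):
            if key not in rec:
                problems.append(f"control_points[{i}].{key} missing")
        if problems:
            continue
        mlc = None
        if "left" in rec or "right" in rec:
            if widths is None:
                problems.append("leaf_widths missing while CPs carry MLC banks")
                continue
            mlc = MLCAperture(np.asarray(rec["left"], dtype=float),
                              np.asarray(rec["right"], dtype=float),
                              np.asarray(widths, dtype=float))
        cps.append(ControlPoint(AngularPosition(rec["gantry"], rec["ring"]),
                                float(rec["mu_weight"]), mlc))
    if problems:
        raise PlanFileError(problems)
    try:
        plan = DeliveryPlan(WaveArcTrajectory(mps), tuple(cps))
    except WaveArcError as exc:
        raise PlanFileError([str(exc)]) from exc
    rules = None
    if "rules" in doc:
        r = doc["rules"]
        rules = TrajectoryRules(
            dominant_multiple=r.get("dominant_multiple", 4.0),
            min_subarc_span=r.get("min_subarc_span", 24.0),
            max_ring_per_gantry=r.get("max_ring_per_gantry", 1.0),
            beam_spacing=r.get("beam_spacing", 24.0),
            ring_limit=r.get("ring_limit", 60.0),
            forbidden_zones=tuple(tuple(z) for z in r.get("forbidden_zones", [])),
        )
    machine = None
    if "machine" in doc:
        m = doc["machine"]
        machine = MachineConstraints(
            gantry_speed=tuple(m.get("gantry_speed", (0.1, 6.0))),
            ring_speed=tuple(m.get("ring_speed", (0.1, 2.5))),
            dose_rate_table=tuple(m.get("dose_rate_table",
                                        (150, 200, 250, 300, 350, 400))),
            leaf_speed_max=m.get("leaf_speed_max", 4.0),
            mp_stop_duration=m.get("mp_stop_duration", 0.1),
            mp_ramp_dose_rate=m.get("mp_ramp_dose_rate", 100.0),
        )
    return PlanFile(plan, rules, machine)


def write_dose_grid(grid: DoseGrid3D, path) -> None:
    """Text grid format: one '#'-prefixed JSON header line, then values."""
    header = json.dumps({
        "origin_mm": list(grid.origin), "spacing_mm": list(grid.spacing),
        "shape": list(grid.shape), "unit": "Gy",
    })
    np.savetxt(path, grid.values.ravel(), header=header, fmt="%.9g")


def read_dose_grid(path) -> DoseGrid3D:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise WaveArcError("dose grid file missing JSON header line")
    meta = json.loads(first[1:].strip())
    values = np.loadtxt(path).reshape(meta["shape"])
    return DoseGrid3D(np.array(meta["origin_mm"]), np.array(meta["spacing_mm"]),
                      values)


def write_mask(mask: StructureMask, shape, path) -> None:
    """Run-length-encoded text mask: header JSON, then 'value length' rows."""
    flat = np.asarray(mask.mask, dtype=np.int8).ravel()
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    lines = [json.dumps({"name": mask.name, "shape": list(shape),
                         "voxel_volume_cc": mask.voxel_volume_cc})]
    lines += [f"{int(flat[s])} {int(e - s)}" for s, e in zip(starts, ends)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mask(path) -> StructureMask:
    lines = Path(path).read_text().splitlines()
    meta = json.loads(lines[0])
    runs = [tuple(int(v) for v in ln.split()) for ln in lines[1:] if ln.strip()]
    flat = np.concatenate([np.full(n, v, dtype=bool) for v, n in runs])
    if flat.size != int(np.prod(meta["shape"])):
        raise WaveArcError("mask RLE length does not match the header shape")
    return StructureMask(meta["name"], flat.reshape(meta["shape"]),
                         meta["voxel_volume_cc"])


def read_dicom_rt_plan(path, ring_attribute: str = "TableTopEccentricAngle"):
    """Read per-CP gantry/ring geometry from a DICOM-RT Plan file.

    The O-ring angle is not a standard DICOM attribute; the control-point
    attribute holding it is configurable (default: the table-top
    eccentric angle slot).  Coplanar files without it get ring 0 with a
    logged warning.  Returns one record per beam with CP angle pairs,
    cumulative meterset weights and MLC positions when present (missing
    pieces are reported as None, never guessed).
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise WaveArcError(f"not a DICOM-RT Plan file: modality {getattr(ds, 'Modality', '?')}")
    beams = []
    for beam in getattr(ds, "BeamSequence", []):
        angles, weights, mlc = [], [], []
        warned = False
        for cp in beam.ControlPointSequence:
            gantry = float(getattr(cp, "GantryAngle", angles[-1][0] if angles else 0.0))
            ring_val = getattr(cp, ring_attribute, None)
            if ring_val is None:
                if not warned:
                    log.warning("no %s attribute; ring defaults to 0", ring_attribute)
                    warned = True
                ring_val = 0.0
            angles.append((gantry, float(ring_val)))
            weights.append(float(getattr(cp, "CumulativeMetersetWeight", 0.0)))
            positions = None
            for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                    positions = np.asarray(bld.LeafJawPositions, dtype=float)
            mlc.append(positions)
        beams.append({
            "beam_name": getattr(beam, "BeamName", ""),
            "angles": angles,
            "cumulative_meterset_weight": weights,
            "mlc": mlc if any(p is not None for p in mlc) else None,
        })
    return beams
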