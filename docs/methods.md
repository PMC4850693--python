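# Methods

This note documents the models implemented in `wavearc`, the conventions
that were genuinely open and had to be fixed, and what the synthetic
fixtures do and do not emulate.

## Trajectory model

A wave trajectory is a polyline of manipulation points (MPs) in
(gantry, ring) angle space. Modelling assumptions:

- **Gantry monotonicity.** The gantry never reverses along the path; only
  the ring direction may change, and only at an MP. This mirrors how O-ring
  wave deliveries are driven in practice (the ring "waves" around a
  monotone gantry sweep).
- **Rules** (all configurable, defaults in degrees): dominant sub-arc span
  a multiple of 4, dominant span ≥ 24, ring/gantry span ratio ≤ 1, ring in
  [−60, +60]. The dominant-axis tie goes to the gantry. The
  multiple-of-4 rule is applied to the *span*, not to the absolute MP
  coordinates (the published rule wording is ambiguous; span was chosen and
  frozen). Collision limits are a configurable list of forbidden rectangles
  in angle space, since real ring–table collision maps are vendor-specific.
- **Discretization.** Beam angles are spaced by the Euclidean norm
  √(Δg²+Δr²), nominally every 24°. When a sub-arc norm L is not a multiple
  of the spacing, the segment count is n = round(L/spacing) (half-up,
  minimum 1) and the actual spacing L/n; this keeps MPs on the beam grid
  and the spacing as close to nominal as possible. Vendors do not publish
  their renormalization rule; this one is fixed and tested.
- **Control points.** Two CPs per beam angle at ±¼ of the local inter-beam
  norm (left gap below, right gap above), clamped at the trajectory ends.
  This realises "two CPs per beam angle, equally distributed between
  adjacent beams" with a deterministic, testable convention.
- Interpolation is linear in angle space; sub-arcs must not cross the
  0/360 gantry seam (split them first). In the coplanar limit (constant
  ring) the norm equals the gantry span and the beam set reduces to a
  plain VMAT angular grid.

## Delivery-time models

Machine constraints (defaults): gantry speed 0.1–6 °/s, ring speed
0.1–2.5 °/s, dose rate from a discrete table within 150–400 MU/min, MLC
leaf speed ≤ 4 cm/s at isocenter, MP stop 0.1 s, MP ramp dose rate
100 MU/min. The exact dose-rate table entries are not public; the default
is a 50 MU/min grid over the machine range and is pure configuration.

**MU bookkeeping.** Control point *i* carries the MU delivered between CP
*i−1* and CP *i* (the first CP carries 0). MU is spread uniformly along the
path between consecutive CPs when attributing MU to sub-arcs.

**Planner model.** One constant gantry speed and one constant dose rate
across the whole arc; only ring speed varies per sub-arc
(v_ring = v_g · ring_span/gantry_span, which must stay in range). The
implementation is closed-form rather than a search: the fastest feasible
gantry speed gives the motion time, the dose rate is snapped up to the
smallest table entry that fits the MU, and if none fits, the largest entry
sets an MU-limited time. This is equivalent to minimising over the
(speed × table) product space and is verified in the tests against an
exhaustive grid search at 0.001 °/s resolution.

**Controller model.** Per sub-arc, the fastest axis-feasible time is
computed, then the smallest dose-rate table entry that delivers the
sub-arc's MU within that time is chosen (so MU and motion finish together
when the required rate is exactly a table entry; when even the largest
entry is too slow, delivery is MU-limited at that entry and the axes slow
down to match). Between sub-arcs the axes stop for 0.1 s while the beam
stays on at the ramp dose rate; the MU delivered during the ramp is debited
from the following sub-arc so the trace conserves total MU exactly (a
beam-hold variant with zero MU at stops is available). Speeds are
piecewise-constant: no acceleration limits are modelled, because none are
published. Traces are sampled at 100 Hz with analytically integrated
cumulative MU, so MU conservation does not depend on the sampling step.

Consequences worth knowing: for a single sub-arc both models coincide; for
multiple sub-arcs the controller is never slower than the planner estimate
plus (n−1)·0.1 s of stops, and is usually faster because it is released
from the global constant-speed/constant-rate constraint. Plans whose
MU-limited axis speeds would fall below the 0.1 °/s minima raise an
infeasibility error naming the binding constraint rather than silently
stepping the axes.

## Modulation complexity score

LSV and AAV follow the standard VMAT complexity-score lineage; the exact
formulas are frozen in `complexity.py` as this package's contract. Fixed
conventions: a leaf pair is open iff right > left; closed pairs are
excluded from LSV position sets and contribute zero area; disjoint open
runs are concatenated in leaf-index order; a bank whose open-leaf positions
coincide scores 1; the AAV envelope per leaf pair is (max right − min left)
over the CPs where that pair is open. MU weighting uses per-gap MU ("MU
delivered between two consecutive CPs"), and the score is invariant under
uniform MU rescaling.

## Gamma evaluation

Global normalisation: the dose tolerance is a percent of the planned grid
maximum, which also defines the low-dose threshold ("maximum expected
dose" = planned maximum, because measured maxima are noisy). The threshold
is applied to the measured diode dose. γ = 1 counts as a pass, with a 1e-9
numerical tolerance so the exact boundary case (a flat +3%-of-max offset)
is not failed by float rounding.

The search lattice is anchored at each diode with step DTA/10 (0.3 mm at
default criteria) in all three axes; the dose-only gamma at the diode
bounds the search radius (beyond best·DTA the distance term alone exceeds
it), so restricting the search to that ball is exact with respect to the
lattice. The tests verify equality with a full-grid brute-force search to
1e-9. Planned dose is interpolated trilinearly.

Pulse binning assigns delivery-ordered dose pulses to CP gaps by cumulative
planned MU, splitting straddling pulses pro-rata, and refuses pulse trains
whose MU total is off by more than 1%. Angular corrections are a pluggable
per-CP multiplicative model; the package ships the identity and a cosine
falloff example only — real detector factors are proprietary, which is also
why published clinical passing rates are not reproducible here. Collapsing
all ring angles to 0 in the correction step reproduces the coplanar QA
mapping.

## Plan metrics

All dose thresholds are closed (≥). D_x% is the dose received by the
hottest x% of the structure, linearly interpolated on the descending sorted
voxel-dose curve (ICRU-style near-maximum convention). Low-dose spillage
counts the ≥50%-of-prescription volume over the whole grid, PTV included
(whether the clinical definition excludes the PTV is unstated; including it
is documented here). Voxels are uniform boxes with volume equal to the
product of grid spacings; no partial-volume weighting. The paired t-test
uses n−1 degrees of freedom (scipy's paired test) with an explicit
zero-variance guard: constant differences raise a degenerate-input error
instead of returning infinite t.

## Synthetic fixtures

The generator emulates a mid-size single-arc case: 3 gantry-dominant
sub-arcs with spans that are multiples of 4° in [24°, 40°], alternating
ring direction, 300 MU total at constant MU per CP, a 10-pair MLC with
0.5 cm leaves, and a 21³ grid at 2 mm spacing. Aperture modulation is a
seeded random walk whose step scales with a `complexity` knob in [0, 1]
(0 reproduces an identical aperture at every CP and hence MCS = 1); steps
are small enough to stay leaf-speed feasible at the controller's segment
times, which the tests verify. These sizes keep every test and the
acceptance run comfortably desk-scale.

The toy dose engine is *not* a clinical dose algorithm: it projects the
error-function-smoothed aperture along each CP's beam axis with a fixed
exponential attenuation (0.004/mm) and a 4 mm penumbra sigma, all
non-physical fixture parameters. It is linear in MU, rotates with the plan
angles and produces smooth gradients — which is exactly what the gamma and
metrics tests need — but it models no scatter, heterogeneity or realistic
depth dose. Passing tests therefore demonstrate the correctness of the
*scoring and timing machinery*, not clinical dose accuracy.

Pseudo-measurements sample the planned grid at diode positions on two
orthogonal planes (5 mm pitch by default) with optional rigid shift, global
scale and seeded Gaussian noise; the zero-noise model returns exact
samples.

## Known limitations

- No acceleration modelling, servo dynamics or beam-hold gating beyond the
  MP stop model; the real controller's small cumulative-MU loss at MP
  ramps is represented as an MU-conserving debit instead.
- DICOM-RT Plan import is read-only and maps the ring angle from a
  configurable attribute, since no standard attribute carries it.
- Local-normalisation gamma and conformity indices beyond
  coverage/spillage are not implemented.
- Sub-arcs crossing the 0/360° gantry seam must be split by the caller.
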