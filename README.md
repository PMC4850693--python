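# wavearc

A desk-scale toolkit for **noncoplanar gantry–ring arc radiotherapy
delivery** on O-ring linacs, where the treatment ring rotates in synchrony
with the gantry ("wave arc" delivery) instead of requiring couch kicks.
It is aimed at medical physicists and researchers who want to study the
*computational* side of such deliveries — trajectory legality, control-point
discretization, delivery-time behaviour, plan complexity and dose-QA
scoring — without a commercial planning system or machine access.

## What it computes

**Trajectory model.** A wave trajectory is an ordered list of manipulation
points (MPs) in (gantry `g`, ring `r`) angle space; only the ring may reverse
direction at an MP. Sub-arcs are checked against vendor-style rules (dominant
span a multiple of 4°, at least 24° per sub-arc, ring/gantry span ratio ≤ 1,
configurable forbidden zones). Beam angles are placed along the path at
uniform increments of the Euclidean norm `√(Δg² + Δr²)` (nominally 24°), and
each beam angle gets two control points (CPs) straddling it at ±¼ of the
local inter-beam spacing.

**Delivery time, two ways.** The *planner model* assumes one constant gantry
speed and one constant dose rate for the whole arc (ring speed alone is
modulated per sub-arc) so that constant MU per CP is deliverable:

    T = max( G / v_g_max ,  MU · 60 / DR )

with `v_g_max` the tightest gantry-speed bound over all sub-arcs and `DR`
the smallest dose-rate table entry that fits. The *controller emulation*
instead re-optimises (gantry speed, ring speed, dose rate) independently per
sub-arc for the fastest delivery, inserts a 0.1 s axis stop at every MP with
the dose rate ramped to ~100 MU/min, and emits a 100 Hz log-file-like trace.
The difference between the two is the planner's delivery-time
overestimation, `100·(T_tps − T_actual)/T_tps`.

**Plan complexity.** The modulation complexity score
`MCS = Σ_i (AAV_i+AAV_{i+1})/2 · (LSV_i+LSV_{i+1})/2 · MU_i/MU_total`
from leaf-sequence variability (LSV) and aperture-area variability (AAV);
1 means no modulation.

**Gamma QA.** Diode doses on two orthogonal planes are scored against the
full planned 3D grid with the *minimum 3D gamma index* (global 3%/3 mm,
20% low-dose threshold by default), with per-CP pulse binning by planned MU
and pluggable angular correction factors.

**Plan metrics.** PTV coverage (fraction of PTV inside the prescription
isodose), low-dose spillage (V50%/PTV volume), DVH points (D2%, Dmean,
VxGy …), percent-change reporting and the paired two-tailed t-test.

A seeded fixture generator (plans, toy dose grids, pseudo-measurements)
makes everything testable with no external data.

## Worked example

```
$ wavearc fixtures --seed 7 --mu-total 120 --out fx7
$ wavearc simulate fx7/plan.yaml
tps_beam_on_time_s: 33.280
tps_gantry_speed_deg_s: 3.125
tps_dose_rate_mu_min: 250
controller_time_s: 30.600
overestimation_pct: 8.1
mean_gantry_speed: 3.421
mean_ring_speed: 2.500
mean_dose_rate: 236.222
total_time: 30.600
total_mu: 120.000
```

The planner's single constant gantry speed (3.125°/s) is pinned by the
steepest sub-arc's ring-speed limit, so it quotes 33.3 s; the controller
runs each sub-arc at its own fastest settings (mean 3.42°/s, ring at its
2.5°/s limit where needed) and finishes in 30.6 s including two 0.1 s MP
stops — an 8.1% overestimation by the planner. On the same fixture:

```
$ wavearc mcs fx7/plan.yaml
mcs: 0.368211
$ wavearc gamma --grid fx7/dose.txt --measured fx7/measured.csv
evaluated: 91
passing_rate_pct: 100.00
```

A moderately modulated arc (MCS ≈ 0.37, well below the unmodulated score
of 1) whose noise-free pseudo-measurement passes 3%/3 mm gamma at 100%.

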