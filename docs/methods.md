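# Methods

## Problem and scope

`angioimr` estimates the index of microcirculatory resistance from
angiography-derived geometry alone (CAG-IMR), without a pressure wire, and
validates such estimates against wire-based IMR with the standard
diagnostic-accuracy toolkit.  The package starts from a *pre-extracted*
vessel tree: image segmentation and 3D reconstruction from projections are
out of scope; geometry arrives in the documented `angioimr-tree/1` JSON
schema or from the phantom generator.

## Geometry model

A tree is a rooted, directed set of segments; each segment is a conical
frustum between its proximal and distal diameters (mm).  Mean diameter is
`(d_prox + d_dist)/2`; the mean cross-sectional area is the frustum volume
divided by length, `A = (π/12)(d1² + d1·d2 + d2²)`; the frustum volume has
the closed form `(π·L/12)(d1² + d1·d2 + d2²)`.  Closed forms are used
throughout — they are exact for this lumen profile, which is why the solver
matches the analytic Poiseuille oracle to machine precision rather than to a
discretization tolerance.

### Reference diameter

The healthy ("reference") diameter apportions flow, standing in for the
unpublished QCA-style method such studies cite.  Per root-to-leaf path we
fit a length-weighted linear regression of mean segment diameter on
cumulative centerline distance, excluding segments flagged stenotic, with
three guards:

- the slope is clamped non-positive (a reference lumen never widens
  distally);
- the fitted value is floored at the measured mean diameter — the linear
  fit undershoots on strongly (exponentially) tapering vessels, and below
  the measurement it is not credible; on stenotic segments this floor also
  enforces `Dref ≥ measured`;
- after averaging over the paths that share a segment, the profile is
  re-clamped non-increasing from the inlet toward each leaf.

If every segment on some path is flagged stenotic the fit is impossible and
the code raises with guidance rather than guessing.

## Hemodynamic model

The proprietary 3D CFD such methods use clinically is replaced by a declared
reduced-order network model.  It preserves exactly the quantities the IMR
formula needs — per-node pressure and per-segment mean velocity — at desk
scale, and the solver interface (`solve_network`) is the single place a
finer model could be swapped in.

**Inlet flow.** `Q_rest = tree volume / (frame_count / frame_rate)`: the
contrast bolus traverses the imaged tree in `frame_count` cine frames.
Frame rates ≤ 7.5 fps are rejected (quality exclusion).  Hyperemia is a
single multiplicative factor, `Q_hyp = α·Q_rest`, default α = 2.1.  The
empirical hyperemia models in the literature are undisclosed; α is the one
exposed knob, and transit times are computed in the hyperemic regime,
mirroring the wire measurement under sustained hyperemia.

**Flow distribution.** Along a vessel, flow decays with the reference
diameter, `Q_i = Q_parent·(Dref_i/Dref_parent)^m` — this is how unmodelled
small daughter branches bleed flow without explicit leak terms.  At a
junction (≥ 2 children) the children split the parent flow in proportion to
`Dref^m` and sum to it exactly: mass conservation overrides the power law
within a junction (residuals are at float rounding, ~1e-16 mL/s).  Default
m = 2.27 from the coronary branching literature (Murray's law would give
m = 3); configurable.

**Pressure.** Marching from `P(inlet) = mean aortic pressure`, each segment
subtracts
`ΔP = (128 μ Q/π)·L(d1²+d1d2+d2²)/(3 d1³d2³)` — the exact Poiseuille
integral over the frustum — plus, on widening segments only, a Borda–Carnot
expansion loss `K_e·ρQ²/2·(1/A_min − 1/A_dist)²` (K_e default 1.0).  The
model is feed-forward, so the solve is direct, deterministic, and needs no
iteration; any node pressure ≤ 0 raises a "non-physical solution" error
naming the node.  Fluid constants default to μ = 0.0035 Pa·s,
ρ = 1050 kg/m³.

**Assumptions.** Steady, Newtonian, fully developed laminar flow; rigid
walls; no pulsatility; pressure read at steady state rather than
time-averaged over the cycle.  These are the standard reductions for
desk-scale coronary network models.

## IMR engine

`IMR_CAG,k = P_k · Σ_i L_i/V_i` over the inlet→branch path, in U = mmHg·s;
`FFR_CAG = P_k/P_in`.  All leaves are reported in a single pass (labeled
internal nodes opt-in).  CMD is called at IMR ≥ 25 U, **boundary
inclusive**, matching the wire-based convention.  The wire side
(`IMR_wire = Pd × mean of exactly three transit times`) and the
pressure-drift gate (wire mean pressure / MAP within 0.97–1.03, both ends
inclusive — the published window is ambiguous about the boundary, so we
include it) are provided for validation work.

## Synthetic data

The phantom generator emulates image-derived geometry: binary trees with a
3.5 mm root, diameters shrinking ×0.8 per generation (continuous across
junctions), segment lengths uniform in 15–30 mm, all behind one seeded
generator.  `generate_random_tree` draws free topologies (chains, tridents,
unbalanced trees) floored at 1.5 mm caliber for solver property-testing.
The default phantom boundary conditions — 90 mmHg aortic pressure, a
resting contrast traversal of 12 frames at 30 fps (0.4 s, i.e. resting mean
velocities of ~15–20 cm/s over a 7–8 cm tree) — put a healthy phantom at
IMR ≈ 14–19 U, inside the normal range.

The cohort generator emulates a ~200-vessel validation study: truth CAG-IMR
from a lognormal mixture (CMD-negative median 15 U truncated below 25 U;
CMD-positive 25 U plus a lognormal excess) at prevalence 0.204; wire IMR =
truth + 0.88 U bias + Gaussian noise (SD 4.75 U); a second observer adds
Gaussian noise of SD 2.5 U.  Defaults are calibrated to the agreement
parameters such studies report; the mixture's shape beyond that is a
modelling choice exposed as config.  Wire values are deliberately not
clipped, so agreement statistics recover the generator's bias/SD without
truncation bias.  What the phantoms do **not** emulate: real lumen-contour
noise, diffuse disease, vessel overlap/foreshortening, or the correlation
structure of repeated measurements within a patient — passing tests show
internal consistency of the method and statistics, not clinical accuracy.

## Diagnostics layer

- **Confusion matrix** at the shared 25 U threshold (≥ on both series).
- **Wald CIs** `p ± 1.96√(p(1−p)/n)` per metric with its own denominator,
  clipped to [0, 100] and rounded **half-up** to 0.1 — this convention
  exactly reproduces the interval endpoints printed in published tables of
  this kind (e.g. accuracy 95.0% → 92.0–98.0 at n = 201); zero-denominator
  metrics are flagged undefined, not raised.
- **Summary-to-matrix reconstruction**: exhaustive search over integer
  matrices of size n whose rounded sensitivity/specificity/accuracy match
  printed values; all solutions are returned so uniqueness is checkable.
- **Bland–Altman** with differences oriented reference − test (wire − CAG),
  so a positive mean difference reads as the angiographic method slightly
  underestimating; SD uses n−1; LoA = mean ± 1.96 SD.  Note 0.88 − 1.96·4.75
  = −8.43; a published −8.44 is that table's rounding.
- **Spearman** via rank correlation with average ranks (scipy),
  **ROC/AUC** by the Mann–Whitney statistic with ties counted half and a
  hand-implemented DeLong CI (no installed package provides one),
  **reproducibility** as Pearson r + two-sided paired t (p = 1 by convention
  for identical series) + Bland–Altman, and a pooled two-proportion z-test
  for subgroup-accuracy contrasts (published tables of this kind do not name
  their test; this is the documented assumption).  No multiple-testing
  correction is applied, matching field practice for these tables.

## Numerical and design choices

- Units fixed at interfaces: mm, mL, s, mmHg, mL/s; SI internally for the
  loss formulas (1 mmHg = 133.322 Pa).
- Determinism everywhere: no global RNG state; configs carry mandatory
  seeds; CLI runs are pure functions of (inputs, config, seed) and exit
  0/1/2 for success/computation error/input error.
- The acceptance script uses 100-point oracle sweeps, 1000 random trees and
  10⁵-vessel cohorts — sizes at which Monte-Carlo error is far below the
  quantities of interest while the whole run stays in seconds.

## Known limitations

- The reduced-order model has no pulsatility, wall compliance, or inlet
  waveform; branch-level IMR differences driven by those effects are
  invisible to it.
- The hyperemia factor α is a crude stand-in for drug-induced hyperemia;
  real CFR varies per patient and lesion.
- Reference-diameter fitting is linear per path; diffusely diseased vessels
  with no healthy anchor violate its premise (the code raises rather than
  extrapolating).
- Cohort-level published statistics (r, AUC, subgroup accuracies) depend on
  private patient data and cannot be re-derived here; the pipeline that
  would compute them is exercised on synthetic cohorts instead.
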