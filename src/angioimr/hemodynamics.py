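"""Reduced-order steady hemodynamics on a coronary tree.

The pressure/flow problem is solved with a 1D network model: segment flows
follow a reference-diameter power law (flow decays along a vessel as unseen
daughter branches bleed it off, and splits at junctions in proportion to
``Dref^m``), and nodal pressures are obtained by marching from the inlet and
subtracting a per-segment pressure drop composed of the exact Poiseuille
integral over the conical frustum plus a Borda–Carnot expansion loss on
widening segments.

Interfaces use clinical units (mmHg, mL/s, mm, mm/s); the loss formulas work
in SI internally.  1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .vessel_tree import (
    GeometryError,
    ReferenceDiameterProfile,
    VesselSegment,
    VesselTree,
    reference_diameter_profile,
    validate_tree,
)

MMHG_PER_PA = 1.0 / 133.322


class QualityExclusionError(ValueError):
    """Acquisition fails an image-quality gate (e.g. cine frame rate too low)."""


class NonPhysicalSolutionError(RuntimeError):
    """The solved pressure field is non-physical (a node pressure <= 0)."""


#: cine acquisitions at or below this frame rate are excluded as unanalyzable
MIN_FRAME_RATE_FPS = 7.5


@dataclass(frozen=True)
class BoundaryConditions:
    """Patient-specific boundary data and model constants.

    p_in_mmHg        mean aortic pressure at the inlet
    q_in_ml_s        resting inlet flow (from contrast transit)
    alpha            multiplicative hyperemia factor (>= 1); scales the
                     resting flow to its maximal-vasodilation value
    split_exponent   exponent m of the Dref^m flow-distribution law
                     (m = 3 is Murray's law; coronary data favour ~2.27)
    viscosity_pa_s   dynamic viscosity of blood
    density_kg_m3    blood density
    expansion_k      Borda-Carnot loss coefficient K_e
    """

    p_in_mmHg: float
    q_in_ml_s: float
    alpha: float = 2.1
    split_exponent: float = 2.27
    viscosity_pa_s: float = 0.0035
    density_kg_m3: float = 1050.0
    expansion_k: float = 1.0

    def __post_init__(self) -> None:
        if self.p_in_mmHg <= 0:
            raise ValueError("inlet pressure must be > 0 mmHg")
        if self.q_in_ml_s <= 0:
            raise ValueError("inlet flow must be > 0 mL/s")
        if self.alpha < 1:
            raise ValueError("hyperemia factor must be >= 1")
        if self.split_exponent <= 0:
            raise ValueError("flow-split exponent must be > 0")
        if self.viscosity_pa_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("fluid constants must be > 0")


@dataclass
class HemodynamicSolution:
    """Per-segment flow/velocity and per-node pressure of a steady solve."""

    flow_ml_s: dict[str, float]
    velocity_mm_s: dict[str, float]
    pressure_mmHg: dict[str, float]
    model: str = "poiseuille-frustum+expansion/1D"
    residual: float = 0.0


def inlet_flow_from_timi(volume_ml: float, frame_count: int, frame_rate_fps: float) -> float:
    """Resting inlet flow from contrast transit: Q = vascular volume / flow time.

    The flow time is the TIMI frame count divided by the cine frame rate.
    Acquisitions at <= 7.5 frames/s are rejected as an image-quality exclusion.
    """
    if volume_ml <= 0:
        raise ValueError("vascular volume must be > 0 mL")
    if frame_count < 1:
        raise ValueError("frame count must be >= 1")
    if frame_rate_fps <= MIN_FRAME_RATE_FPS:
        raise QualityExclusionError(
            f"frame rate {frame_rate_fps} fps fails the > {MIN_FRAME_RATE_FPS} fps "
            "acquisition-quality requirement"
        )
    flow_time_s = frame_count / frame_rate_fps
    return volume_ml / flow_time_s


def apply_hyperemia(q_rest_ml_s: float, alpha: float) -> float:
    """Hyperemic flow as a multiplicative scaling of resting flow."""
    if q_rest_ml_s <= 0:
        raise ValueError("resting flow must be > 0")
    if alpha < 1:
        raise ValueError("hyperemia factor must be >= 1")
    return alpha * q_rest_ml_s


def distribute_flow(
    tree: VesselTree,
    profile: ReferenceDiameterProfile,
    q_inlet_ml_s: float,
    m: float,
) -> dict[str, float]:
    """Per-segment flow from the reference-diameter power law.

    Along a single-child chain the flow decays by ``(Dref_child/Dref_parent)^m``
    (unmodelled small daughters take the difference); at a junction the
    children split the parent flow in proportion to ``Dref_child^m`` and sum
    exactly to it — mass conservation overrides the power law there.
    """
    if q_inlet_ml_s <= 0:
        raise ValueError("inlet flow must be > 0")
    for sid, d in profile.dref_mm.items():
        if d <= 0:
            raise GeometryError(f"non-positive reference diameter on segment {sid}")

    flows: dict[str, float] = {}

    def descend(node: str, q_avail: float, dref_parent: float | None) -> None:
        children = tree.children_segments_of(node)
        if not children:
            return
        if len(children) == 1:
            seg = children[0]
            d = profile.dref_mm[seg.id]
            q = q_avail if dref_parent is None else q_avail * (d / dref_parent) ** m
            q = min(q, q_avail)
            flows[seg.id] = q
            descend(seg.child_node, q, d)
        else:
            weights = [profile.dref_mm[s.id] ** m for s in children]
            wsum = sum(weights)
            for seg, w in zip(children, weights):
                q = q_avail * (w / wsum)
                flows[seg.id] = q
                descend(seg.child_node, q, profile.dref_mm[seg.id])

    descend(tree.inlet_node, q_inlet_ml_s, None)
    return flows


def segment_pressure_drop(
    seg: VesselSegment, q_ml_s: float, bc: BoundaryConditions
) -> float:
    """Pressure drop over one tapered segment, in mmHg.

    Viscous part: exact integral of local Poiseuille resistance over the
    frustum,

        dP_visc = (128 mu Q / pi) * L (d1^2 + d1 d2 + d2^2) / (3 d1^3 d2^3),

    which reduces to 128 mu L Q / (pi d^4) for a uniform tube.  Expansion
    part (only on widening segments, d_dist > d_min): Borda–Carnot loss
    K_e * rho Q^2 / 2 * (1/A_min - 1/A_dist)^2.
    """
    if q_ml_s < 0:
        raise ValueError("flow must be >= 0")
    mu = bc.viscosity_pa_s
    q = q_ml_s * 1e-6  # m^3/s
    d1 = seg.d_prox_mm * 1e-3
    d2 = seg.d_dist_mm * 1e-3
    length = seg.length_mm * 1e-3
    dp_visc = (
        128.0 * mu * q / math.pi
        * length * (d1 * d1 + d1 * d2 + d2 * d2) / (3.0 * d1**3 * d2**3)
    )
    dp_exp = 0.0
    d_min = min(d1, d2)
    if d2 > d_min:  # widening segment: jet expansion loss at the distal end
        a_min = math.pi * d_min * d_min / 4.0
        a_dist = math.pi * d2 * d2 / 4.0
        dp_exp = bc.expansion_k * bc.density_kg_m3 * q * q / 2.0 * (1.0 / a_min - 1.0 / a_dist) ** 2
    return (dp_visc + dp_exp) * MMHG_PER_PA


def solve_network(
    tree: VesselTree,
    bc: BoundaryConditions,
    profile: ReferenceDiameterProfile | None = None,
) -> HemodynamicSolution:
    """Steady flow/pressure solve on the whole tree under hyperemic inflow.

    Flows come from :func:`distribute_flow` with the hyperemic inlet flow;
    pressures march from ``P(inlet) = p_in`` down each path, subtracting
    :func:`segment_pressure_drop`; velocities are ``Q_i / A_i`` with the mean
    frustum cross-section.  The model is feed-forward, so the solve is direct
    and deterministic (residual 0).
    """
    rep = validate_tree(tree)
    if not rep.passed:
        raise ValueError("invalid tree: " + "; ".join(rep.violations))
    if profile is None:
        profile = reference_diameter_profile(tree)

    q_hyp = apply_hyperemia(bc.q_in_ml_s, bc.alpha)
    flows = distribute_flow(tree, profile, q_hyp, bc.split_exponent)

    velocities: dict[str, float] = {}
    for s in tree.segments:
        # mL/s -> mm^3/s over mm^2 gives mm/s
        velocities[s.id] = flows[s.id] * 1000.0 / s.mean_area_mm2

    pressures: dict[str, float] = {tree.inlet_node: bc.p_in_mmHg}
    stack = [tree.inlet_node]
    while stack:
        node = stack.pop()
        for seg in tree.children_segments_of(node):
            p = pressures[node] - segment_pressure_drop(seg, flows[seg.id], bc)
            if p <= 0:
                raise NonPhysicalSolutionError(
                    f"non-physical solution: pressure {p:.3f} mmHg at node "
                    f"{seg.child_node!r}"
                )
            pressures[seg.child_node] = p
            stack.append(seg.child_node)

    return HemodynamicSolution(
        flow_ml_s=flows, velocity_mm_s=velocities, pressure_mmHg=pressures
    )
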