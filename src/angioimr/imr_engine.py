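"""Index of microcirculatory resistance from solved tree hemodynamics.

For branch ``k`` the angiographic IMR is the product of the distal pressure
``P_k`` (mmHg) and the cumulative transit time ``T_mn`` (s) of blood from the
inlet to the distal point of that branch:

    IMR_CAG,k = P_k * T_mn,      T_mn = sum_i L_i / V_i

over the segments ``i`` on the inlet-to-branch path, using hyperemic
velocities.  The unit "U" is mmHg*s.  The same-threshold wire reference,
IMR_wire = Pd * mean transit time of three saline injections, is provided for
validation work.  CMD (coronary microvascular dysfunction) is called at
IMR >= 25 U, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hemodynamics import HemodynamicSolution
from .vessel_tree import VesselSegment, VesselTree, path_to_node

#: diagnostic threshold for CMD, in U (mmHg*s); boundary inclusive
CMD_THRESHOLD_U = 25.0

#: acceptance window for wire pressure drift (wire mean pressure / MAP)
DRIFT_WINDOW = (0.97, 1.03)


@dataclass(frozen=True)
class BranchIMRResult:
    branch_node: str
    label: str
    p_k_mmHg: float
    t_mn_s: float
    imr_u: float
    ffr: float
    cmd_positive: bool


@dataclass(frozen=True)
class WireMeasurement:
    """One wire-based acquisition: Pa/Pd and a thermodilution triplet.

    ``0 < Pd <= Pa`` is physiologically expected but not enforced — transient
    drift or damping can invert it and the record should still be loadable.
    """

    pa_mmHg: float
    pd_mmHg: float
    transit_times_s: tuple[float, float, float]
    drift_ratio: float = 1.0

    def __post_init__(self) -> None:
        if len(self.transit_times_s) != 3:
            raise ValueError("exactly three saline-injection transit times required")
        if any(t <= 0 for t in self.transit_times_s):
            raise ValueError("transit times must be > 0")
        if self.pa_mmHg <= 0 or self.pd_mmHg <= 0:
            raise ValueError("pressures must be > 0")


def transit_time(path: list[VesselSegment], velocities_mm_s: dict[str, float]) -> float:
    """Cumulative transit time sum(L_i / V_i) over a path, in seconds."""
    total = 0.0
    for seg in path:
        v = velocities_mm_s[seg.id]
        if v <= 0:
            raise ValueError(f"non-positive velocity on segment {seg.id}")
        total += seg.length_mm / v
    return total


def cag_imr_branch(p_k_mmHg: float, t_mn_s: float) -> float:
    """IMR of one branch: distal pressure times transit time (U = mmHg*s)."""
    if p_k_mmHg <= 0:
        raise ValueError("distal pressure must be > 0 mmHg")
    if t_mn_s < 0:
        raise ValueError("transit time must be >= 0 s")
    return p_k_mmHg * t_mn_s


def classify_cmd(imr_u: float, threshold_u: float = CMD_THRESHOLD_U) -> bool:
    """CMD-positive iff IMR >= threshold (inclusive)."""
    if imr_u < 0:
        raise ValueError("IMR must be >= 0")
    return imr_u >= threshold_u


def compute_all_branches(
    tree: VesselTree,
    solution: HemodynamicSolution,
    threshold_u: float = CMD_THRESHOLD_U,
    include_internal: bool = False,
) -> list[BranchIMRResult]:
    """Per-branch IMR/FFR in a single pass over the solved tree.

    Reports every leaf; with ``include_internal`` also every labeled internal
    node.  No re-solve is performed — all quantities are read off the solution.
    """
    p_in = solution.pressure_mmHg[tree.inlet_node]
    targets = list(tree.leaves())
    if include_internal:
        targets += [
            n for n in sorted(tree.branch_labels) if n in tree.nodes and n not in targets
        ]
    results = []
    for node in targets:
        path = path_to_node(tree, node)
        t_mn = transit_time(path, solution.velocity_mm_s)
        p_k = solution.pressure_mmHg[node]
        imr = cag_imr_branch(p_k, t_mn)
        results.append(
            BranchIMRResult(
                branch_node=node,
                label=tree.branch_labels.get(node, node),
                p_k_mmHg=p_k,
                t_mn_s=t_mn,
                imr_u=imr,
                ffr=p_k / p_in,
                cmd_positive=classify_cmd(imr, threshold_u),
            )
        )
    return results


def mean_transit_time(times_s) -> float:
    """Mean of exactly three positive saline-injection transit times."""
    times = tuple(times_s)
    if len(times) != 3:
        raise ValueError("exactly three transit times required")
    if any(t <= 0 for t in times):
        raise ValueError("transit times must be > 0")
    return sum(times) / 3.0


def wire_imr(m: WireMeasurement) -> float:
    """Wire-based IMR: Pd times the mean thermodilution transit time."""
    return m.pd_mmHg * mean_transit_time(m.transit_times_s)


def drift_check(mean_wire_pressure_mmHg: float, map_mmHg: float) -> tuple[bool, float]:
    """Pressure-drift gate: wire mean pressure over MAP must lie in 0.97–1.03.

    Both bounds inclusive.  Returns (passed, ratio).
    """
    if mean_wire_pressure_mmHg <= 0 or map_mmHg <= 0:
        raise ValueError("pressures must be > 0")
    ratio = mean_wire_pressure_mmHg / map_mmHg
    lo, hi = DRIFT_WINDOW
    return (lo <= ratio <= hi), ratio
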