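"""Synthetic phantoms and cohorts for end-to-end testing without patient data.

Provides (a) binary-branching vessel phantoms with generation-wise taper,
(b) focal stenoses, (c) virtual pressure-wire measurements whose computed IMR
carries configurable Gaussian noise, and (d) paired-measurement cohorts
(truth angiographic IMR, noisy wire IMR, second-observer angiographic IMR)
with configurable CMD prevalence, systematic bias and noise — emulating a
validation study of an angiography-derived IMR against the wire reference.

All randomness flows through one explicitly seeded ``numpy`` generator; the
same config and seed reproduce outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hemodynamics import BoundaryConditions, inlet_flow_from_timi
from .imr_engine import WireMeasurement
from .vessel_tree import VesselSegment, VesselTree, tree_volume, validate_tree

COHORT_COLUMNS = [
    "vessel_id",
    "truth_cag_imr_U",
    "wire_imr_U",
    "cag_imr_obs2_U",
    "cmd_truth",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Binary-tree phantom: coronary-like sizes by default.

    Diameters shrink by ``taper_ratio`` per generation and each segment
    itself tapers from its generation diameter to the next one, so lumen
    caliber is continuous across junctions.
    """

    seed: int
    depth: int = 3
    taper_ratio: float = 0.8
    root_diameter_mm: float = 3.5
    length_range_mm: tuple[float, float] = (15.0, 30.0)
    stenoses: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 < self.taper_ratio < 1):
            raise ValueError("taper ratio must be in (0, 1)")
        if self.root_diameter_mm <= 0:
            raise ValueError("root diameter must be > 0")
        lo, hi = self.length_range_mm
        if not (0 < lo <= hi):
            raise ValueError("invalid segment length range")
        for _, sev in self.stenoses:
            if not (0 < sev < 1):
                raise ValueError("stenosis severity must be in (0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Paired-measurement cohort emulating a wire-vs-angiography validation.

    Defaults mirror a ~200-vessel study with ~20% CMD prevalence, a slight
    systematic underestimation by the angiographic index (wire reads higher
    by ``bias_u``) and wire noise of a few U.
    """

    seed: int
    n_vessels: int = 201
    prevalence: float = 0.204
    wire_noise_sd_u: float = 4.75
    bias_u: float = 0.88
    interobserver_sd_u: float = 2.5
    neg_median_u: float = 15.0
    neg_sigma: float = 0.30
    pos_excess_median_u: float = 6.0
    pos_sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.n_vessels < 2:
            raise ValueError("need at least 2 vessels")
        if not (0 <= self.prevalence <= 1):
            raise ValueError("prevalence must be in [0, 1]")
        if self.wire_noise_sd_u < 0 or self.interobserver_sd_u < 0:
            raise ValueError("noise SDs must be >= 0")


def generate_phantom_tree(cfg: PhantomConfig) -> VesselTree:
    """Deterministic (seeded) binary phantom with 2^depth - 1 segments."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range_mm
    segments: list[VesselSegment] = []

    def grow(parent_node: str, generation: int, tag: str) -> None:
        if generation >= cfg.depth:
            return
        d_prox = cfg.root_diameter_mm * cfg.taper_ratio**generation
        d_dist = cfg.root_diameter_mm * cfg.taper_ratio ** (generation + 1)
        length = float(rng.uniform(lo, hi))
        child = f"n{tag}"
        segments.append(
            VesselSegment(
                id=f"s{tag}",
                parent_node=parent_node,
                child_node=child,
                length_mm=length,
                d_prox_mm=d_prox,
                d_dist_mm=d_dist,
            )
        )
        grow(child, generation + 1, tag + "0")
        grow(child, generation + 1, tag + "1")

    grow("root", 0, "0")
    tree = VesselTree(segments=segments, inlet_node="root")
    for seg_id, severity in cfg.stenoses:
        tree = add_stenosis(tree, seg_id, severity)
    rep = validate_tree(tree)
    assert rep.passed, rep.violations
    return tree


def generate_random_tree(
    rng: np.random.Generator | int, max_segments: int = 20
) -> VesselTree:
    """Random valid rooted tree with arbitrary topology and coronary calibers.

    Unlike :func:`generate_phantom_tree` (regular binary branching), topology
    is drawn freely: each new segment attaches to a uniformly chosen existing
    node, so chains, tridents and unbalanced trees all occur.  Diameters taper
    toward the periphery but are floored at epicardial caliber (1.5 mm).
    Intended for property testing of the solver.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = int(rng.integers(1, max_segments + 1))
    segments = []
    nodes = ["root"]
    diam = {"root": float(rng.uniform(3.0, 4.5))}
    for i in range(n):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        d_prox = max(diam[parent] * float(rng.uniform(0.75, 0.98)), 1.5)
        d_dist = max(d_prox * float(rng.uniform(0.8, 1.0)), 1.5)
        child = f"n{i}"
        segments.append(
            VesselSegment(
                id=f"s{i}",
                parent_node=parent,
                child_node=child,
                length_mm=float(rng.uniform(5.0, 30.0)),
                d_prox_mm=d_prox,
                d_dist_mm=d_dist,
            )
        )
        nodes.append(child)
        diam[child] = d_dist
    return VesselTree(segments=segments, inlet_node="root")


def default_boundary_conditions(
    tree: VesselTree,
    p_in_mmHg: float = 90.0,
    frame_count: int = 12,
    frame_rate_fps: float = 30.0,
    **overrides,
) -> BoundaryConditions:
    """Physiological boundary conditions for a phantom case.

    Mean aortic pressure 90 mmHg; resting inlet flow from the phantom's own
    lumen volume and a normal contrast traversal of 12 cine frames at 30
    frames/s (0.4 s — resting coronary mean velocities of ~15–20 cm/s over a
    7–8 cm tree).  Extra keywords override the model constants.
    """
    q_rest = inlet_flow_from_timi(tree_volume(tree), frame_count, frame_rate_fps)
    return BoundaryConditions(p_in_mmHg=p_in_mmHg, q_in_ml_s=q_rest, **overrides)


def add_stenosis(tree: VesselTree, segment_id: str, severity: float) -> VesselTree:
    """New tree with the named segment's minimum diameter scaled by (1-severity).

    The input tree is left unmodified.  The narrower end of the frustum is
    pinched (distal end when the segment is uniform), and the segment is
    flagged stenotic so reference-diameter fitting excludes it.
    """
    if not (0 < severity < 1):
        raise ValueError("severity must be in (0, 1)")
    target = tree.segment_by_id(segment_id)  # raises on unknown id
    new_segments = []
    for s in tree.segments:
        if s.id != segment_id:
            new_segments.append(s)
            continue
        if s.d_prox_mm < s.d_dist_mm:
            s = dataclasses.replace(
                s, d_prox_mm=s.d_prox_mm * (1 - severity), stenotic=True
            )
        else:
            s = dataclasses.replace(
                s, d_dist_mm=s.d_dist_mm * (1 - severity), stenotic=True
            )
        new_segments.append(s)
    return VesselTree(
        segments=new_segments,
        inlet_node=tree.inlet_node,
        branch_labels=dict(tree.branch_labels),
    )


def virtual_wire_measurement(
    truth_imr_u: float,
    pa_mmHg: float,
    noise_sd_u: float,
    rng: np.random.Generator | int,
    drift_within_window: bool = True,
) -> WireMeasurement:
    """Virtual wire acquisition whose computed IMR is truth + N(0, sd).

    Pd is drawn as a plausible hyperemic distal pressure (0.80–0.95 of Pa);
    the thermodilution triplet is built around the implied mean transit time
    with +/- jitter that leaves the mean exact, so ``wire_imr`` of the result
    reproduces the noisy target exactly.  Measured IMR is floored at 1 U.
    """
    if truth_imr_u <= 0:
        raise ValueError("truth IMR must be > 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    measured = truth_imr_u + (rng.normal(0.0, noise_sd_u) if noise_sd_u > 0 else 0.0)
    measured = max(measured, 1.0)
    pd_mmHg = pa_mmHg * rng.uniform(0.80, 0.95)
    t_mean = measured / pd_mmHg
    jitter = rng.uniform(0.0, 0.15) * t_mean
    times = (t_mean - jitter, t_mean, t_mean + jitter)
    if drift_within_window:
        drift = rng.uniform(0.97, 1.03)
    else:
        drift = 0.96 if rng.random() < 0.5 else 1.04
    return WireMeasurement(
        pa_mmHg=pa_mmHg, pd_mmHg=pd_mmHg, transit_times_s=times, drift_ratio=drift
    )


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Paired cohort table (truth angiographic IMR, wire IMR, observer 2).

    Truth IMR is drawn from a two-component lognormal mixture: CMD-negative
    vessels lognormal with the configured median, resampled below 25 U;
    CMD-positive vessels 25 U plus a lognormal excess, so truth >= 25 U.
    The wire reading is truth + bias + Gaussian noise (no clipping, so
    agreement statistics recover the generator's bias/SD unbiasedly);
    observer 2 is truth + Gaussian inter-observer noise.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_vessels
    is_pos = rng.random(n) < cfg.prevalence

    truth = np.empty(n)
    neg_idx = np.flatnonzero(~is_pos)
    pos_idx = np.flatnonzero(is_pos)
    mu_neg = np.log(cfg.neg_median_u)
    draws = rng.lognormal(mu_neg, cfg.neg_sigma, size=neg_idx.size)
    while True:  # truncate negatives below the diagnostic threshold
        bad = draws >= 25.0
        if not bad.any():
            break
        draws[bad] = rng.lognormal(mu_neg, cfg.neg_sigma, size=int(bad.sum()))
    truth[neg_idx] = draws
    truth[pos_idx] = 25.0 + rng.lognormal(
        np.log(cfg.pos_excess_median_u), cfg.pos_sigma, size=pos_idx.size
    )

    wire = truth + cfg.bias_u + rng.normal(0.0, cfg.wire_noise_sd_u, size=n)
    obs2 = truth + rng.normal(0.0, cfg.interobserver_sd_u, size=n)

    return pd.DataFrame(
        {
            "vessel_id": [f"v{i:05d}" for i in range(n)],
            "truth_cag_imr_U": truth,
            "wire_imr_U": wire,
            "cag_imr_obs2_U": obs2,
            "cmd_truth": is_pos,
        },
        columns=COHORT_COLUMNS,
    )


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    return df
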