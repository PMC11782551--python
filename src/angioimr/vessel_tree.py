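"""Coronary vessel trees: data model, validation, geometry, serialization.

A vessel tree is a rooted, directed tree of tapered conical segments.  Each
segment runs from its parent node to its child node in the direction of flow;
the unique root node is the arterial inlet.  Geometry is held in millimetres,
volumes are reported in millilitres.

The on-disk format is a small versioned JSON dialect, ``angioimr-tree/1``::

    {"schema": "angioimr-tree/1",
     "inlet": "n0",
     "segments": [{"id": "s1", "from": "n0", "to": "n1",
                   "length_mm": 20.0, "d_prox_mm": 3.5, "d_dist_mm": 3.1,
                   "stenotic": false}, ...],
     "labels": {"n3": "LAD", "n4": "LCX"}}
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

TREE_SCHEMA = "angioimr-tree/1"

#: sanity bound on lumen diameters (mm); coronary arteries never approach this
MAX_DIAMETER_MM = 20.0


class GeometryError(ValueError):
    """Raised for non-physical segment or tree geometry."""


class TreeStructureError(ValueError):
    """Raised when a tree query references unknown nodes/segments."""


@dataclass(frozen=True)
class VesselSegment:
    """A tapered (conical-frustum) vessel segment directed parent -> child."""

    id: str
    parent_node: str
    child_node: str
    length_mm: float
    d_prox_mm: float
    d_dist_mm: float
    stenotic: bool = False

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise GeometryError(f"segment {self.id}: length must be > 0")
        for name, d in (("d_prox_mm", self.d_prox_mm), ("d_dist_mm", self.d_dist_mm)):
            if not (0 < d <= MAX_DIAMETER_MM):
                raise GeometryError(
                    f"segment {self.id}: {name}={d} outside (0, {MAX_DIAMETER_MM}] mm"
                )

    @property
    def mean_diameter_mm(self) -> float:
        return 0.5 * (self.d_prox_mm + self.d_dist_mm)

    @property
    def mean_area_mm2(self) -> float:
        """Mean cross-sectional area of the frustum (volume / length)."""
        d1, d2 = self.d_prox_mm, self.d_dist_mm
        return math.pi / 12.0 * (d1 * d1 + d1 * d2 + d2 * d2)


@dataclass
class VesselTree:
    """A rooted tree of :class:`VesselSegment` with a single inlet node."""

    segments: list[VesselSegment]
    inlet_node: str
    branch_labels: dict[str, str] = field(default_factory=dict)

    # --- derived topology -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        out = {self.inlet_node}
        for s in self.segments:
            out.add(s.parent_node)
            out.add(s.child_node)
        return out

    def segment_by_id(self, seg_id: str) -> VesselSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise TreeStructureError(f"unknown segment id {seg_id!r}")

    def parent_segment_of(self, node: str) -> VesselSegment | None:
        for s in self.segments:
            if s.child_node == node:
                return s
        return None

    def children_segments_of(self, node: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.parent_node == node]

    def leaves(self) -> list[str]:
        has_child = {s.parent_node for s in self.segments}
        return sorted(n for n in self.nodes if n not in has_child)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s in self.segments:
            g.add_edge(s.parent_node, s.child_node, segment=s)
        return g


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str]


@dataclass
class ReferenceDiameterProfile:
    """Per-segment healthy reference diameters from a monotone taper fit.

    ``dref_mm`` maps segment id -> reference diameter; ``fits`` records the
    (slope, intercept) of the length-weighted linear fit along each
    root-to-leaf path, keyed by leaf node; ``excluded`` lists the segment ids
    left out of the fits as diseased.
    """

    dref_mm: dict[str, float]
    fits: dict[str, tuple[float, float]]
    excluded: list[str]


def validate_tree(tree: VesselTree) -> ValidationReport:
    """Check tree-level invariants and report all violations found."""
    violations: list[str] = []
    ids = [s.id for s in tree.segments]
    if len(ids) != len(set(ids)):
        violations.append("segment ids not unique")

    if not tree.segments:
        violations.append("tree has no segments")
        return ValidationReport(False, violations)

    children = {s.child_node for s in tree.segments}
    parentless = sorted({s.parent_node for s in tree.segments} - children)
    if parentless != [tree.inlet_node]:
        violations.append(
            f"single inlet violated: parentless nodes {parentless}, "
            f"declared inlet {tree.inlet_node!r}"
        )
    from collections import Counter

    indeg = Counter(s.child_node for s in tree.segments)
    multi = [n for n, k in indeg.items() if k > 1]
    if multi:
        violations.append(f"nodes with more than one parent segment: {sorted(multi)}")
    if tree.inlet_node in indeg:
        violations.append("inlet node has a parent segment")

    g = tree.graph()
    if not nx.is_directed_acyclic_graph(g):
        violations.append("graph is not acyclic")
    elif tree.inlet_node in g:
        reachable = nx.descendants(g, tree.inlet_node) | {tree.inlet_node}
        unreachable = sorted(set(g.nodes) - reachable)
        if unreachable:
            violations.append(f"nodes unreachable from inlet: {unreachable}")

    return ValidationReport(not violations, violations)


def segment_volume(seg: VesselSegment) -> float:
    """Conical-frustum lumen volume in mL.

    V = (pi * L / 12) * (d1^2 + d1*d2 + d2^2), with lengths/diameters in mm
    (1000 mm^3 = 1 mL).
    """
    d1, d2 = seg.d_prox_mm, seg.d_dist_mm
    vol_mm3 = math.pi * seg.length_mm / 12.0 * (d1 * d1 + d1 * d2 + d2 * d2)
    return vol_mm3 / 1000.0


def path_to_node(tree: VesselTree, node: str) -> list[VesselSegment]:
    """Ordered inlet -> node segment sequence (empty for the inlet itself)."""
    if node not in tree.nodes:
        raise TreeStructureError(f"unknown node {node!r}")
    path: list[VesselSegment] = []
    cur = node
    while cur != tree.inlet_node:
        seg = tree.parent_segment_of(cur)
        if seg is None:
            raise TreeStructureError(f"node {cur!r} has no parent segment")
        path.append(seg)
        cur = seg.parent_node
    path.reverse()
    return path


def tree_volume(tree: VesselTree, up_to: str | None = None) -> float:
    """Lumen volume in mL: the whole tree, or the inlet->``up_to`` path."""
    if up_to is None:
        return sum(segment_volume(s) for s in tree.segments)
    return sum(segment_volume(s) for s in path_to_node(tree, up_to))


def _fit_path(segs: list[VesselSegment]) -> tuple[float, float]:
    """Length-weighted linear fit of mean diameter vs cumulative mid-distance.

    The slope is clamped to be non-positive so the reference taper never
    widens distally.  Returns (slope, intercept) with x in mm from the inlet.
    """
    x = []
    pos = 0.0
    for s in segs:
        x.append(pos + 0.5 * s.length_mm)
        pos += s.length_mm
    x = np.asarray(x)
    y = np.asarray([s.mean_diameter_mm for s in segs])
    w = np.asarray([s.length_mm for s in segs])
    if len(segs) == 1:
        return 0.0, float(y[0])
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    sxx = float(np.sum(w * (x - xm) ** 2))
    if sxx == 0.0:
        return 0.0, float(ym)
    slope = float(np.sum(w * (x - xm) * (y - ym)) / sxx)
    if slope > 0.0:
        slope = 0.0
    intercept = float(ym - slope * xm)
    return slope, intercept


def reference_diameter_profile(tree: VesselTree) -> ReferenceDiameterProfile:
    """Healthy reference diameter per segment.

    For each root-to-leaf path, mean segment diameter is regressed on
    cumulative centerline distance (length-weighted), excluding segments
    flagged stenotic; each segment's reference diameter is the fit evaluated
    at its midpoint.  Segments shared by several paths take the mean of the
    per-path values.  On stenotic segments the reference is never below the
    measured diameter; along every path the profile is forced non-increasing.
    """
    rep = validate_tree(tree)
    if not rep.passed:
        raise TreeStructureError("invalid tree: " + "; ".join(rep.violations))

    acc: dict[str, list[float]] = {s.id: [] for s in tree.segments}
    fits: dict[str, tuple[float, float]] = {}
    excluded = sorted({s.id for s in tree.segments if s.stenotic})

    for leaf in tree.leaves():
        segs = path_to_node(tree, leaf)
        healthy = [s for s in segs if not s.stenotic]
        if not healthy:
            raise GeometryError(
                f"every segment on the path to {leaf!r} is flagged stenotic; "
                "supply at least one healthy segment per path or set "
                "reference diameters manually"
            )
        # fit on healthy segments at their true positions along the path
        pos = 0.0
        xs, ys, ws = [], [], []
        mids = {}
        for s in segs:
            mids[s.id] = pos + 0.5 * s.length_mm
            pos += s.length_mm
        for s in healthy:
            xs.append(mids[s.id])
            ys.append(s.mean_diameter_mm)
            ws.append(s.length_mm)
        if len(healthy) == 1:
            slope, intercept = 0.0, ys[0]
        else:
            x = np.asarray(xs)
            y = np.asarray(ys)
            w = np.asarray(ws)
            xm = np.average(x, weights=w)
            ym = np.average(y, weights=w)
            sxx = float(np.sum(w * (x - xm) ** 2))
            slope = 0.0 if sxx == 0 else float(np.sum(w * (x - xm) * (y - ym)) / sxx)
            slope = min(slope, 0.0)
            intercept = float(ym - slope * xm)
        fits[leaf] = (slope, intercept)
        for s in segs:
            d = slope * mids[s.id] + intercept
            # the linear fit can undershoot on strongly tapering vessels;
            # never trust it below the measured lumen (and on stenotic
            # segments the reference is the healthy estimate, >= measured)
            d = max(d, s.mean_diameter_mm)
            acc[s.id].append(d)

    dref = {sid: float(np.mean(v)) for sid, v in acc.items() if v}
    # enforce monotone non-increase from inlet toward each leaf
    order = nx.topological_sort(tree.graph())
    for node in order:
        parent = tree.parent_segment_of(node)
        if parent is None:
            continue
        for child in tree.children_segments_of(node):
            dref[child.id] = min(dref[child.id], dref[parent.id])
    for sid, d in dref.items():
        if d <= 0:
            raise GeometryError(f"non-positive reference diameter on segment {sid}")
    return ReferenceDiameterProfile(dref_mm=dref, fits=fits, excluded=excluded)


# --- serialization --------------------------------------------------------

def tree_to_dict(tree: VesselTree) -> dict:
    return {
        "schema": TREE_SCHEMA,
        "inlet": tree.inlet_node,
        "segments": [
            {
                "id": s.id,
                "from": s.parent_node,
                "to": s.child_node,
                "length_mm": s.length_mm,
                "d_prox_mm": s.d_prox_mm,
                "d_dist_mm": s.d_dist_mm,
                "stenotic": s.stenotic,
            }
            for s in tree.segments
        ],
        "labels": dict(tree.branch_labels),
    }


def tree_from_dict(data: dict) -> VesselTree:
    schema = data.get("schema")
    if schema != TREE_SCHEMA:
        raise ValueError(f"unsupported tree schema {schema!r}; expected {TREE_SCHEMA!r}")
    segments = [
        VesselSegment(
            id=d["id"],
            parent_node=d["from"],
            child_node=d["to"],
            length_mm=float(d["length_mm"]),
            d_prox_mm=float(d["d_prox_mm"]),
            d_dist_mm=float(d["d_dist_mm"]),
            stenotic=bool(d.get("stenotic", False)),
        )
        for d in data["segments"]
    ]
    return VesselTree(
        segments=segments,
        inlet_node=data["inlet"],
        branch_labels=dict(data.get("labels", {})),
    )


def write_tree_json(tree: VesselTree, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_tree_json(path) -> VesselTree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))


def write_tree_csv(tree: VesselTree, path) -> None:
    """Per-segment geometry export for spreadsheets."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "from", "to", "length_mm", "d_prox_mm", "d_dist_mm",
             "mean_diameter_mm", "volume_mL", "stenotic"]
        )
        for s in tree.segments:
            w.writerow(
                [s.id, s.parent_node, s.child_node, s.length_mm, s.d_prox_mm,
                 s.d_dist_mm, s.mean_diameter_mm, segment_volume(s), s.stenotic]
            )
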