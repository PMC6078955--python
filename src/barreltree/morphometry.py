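"""Morphometry of traced L4 neurons in the neonatal barrel cortex.

Data model for traced neurons (soma, apical dendrite, basal-dendrite trees,
axon) and barrel-map geometry, plus the quantities derived from them:

* segment partition of an arbor under the 5 µm process rule,
* the inside/outside boundary through the soma, perpendicular to the
  soma -> barrel-center direction,
* the orientation bias index (OBI): basal-dendrite segment length in the
  barrel-center half divided by total segment length,
* barrel-edge vs barrel-center soma classification (12.5 µm rule),
* apical-dendrite trajectory classification (Group 1 retracting /
  Group 2 continuously extending),
* per-tree and per-neuron totals and first-to-last-session fold changes.

All coordinates are in µm; the tangential (imaging) plane is x-y and depth
is z. Angles are in degrees, 0° toward the home-barrel center,
counter-clockwise positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "BarrelMap",
    "Barrel",
    "DendriticTree",
    "TracedNeuron",
    "ADTrajectory",
    "ObiResult",
    "Segment",
    "MorphometryError",
    "StructuralError",
    "UndefinedOBIError",
    "DegenerateGeometryError",
    "SEGMENT_MIN_UM",
    "EDGE_DISTANCE_UM",
    "partition_segments",
    "inside_outside_boundary",
    "compute_obi",
    "classify_barrel_position",
    "classify_group",
    "tree_side",
    "tree_origin_angle",
    "tree_metrics",
    "neuron_totals",
    "fold_change",
]

#: processes of at most this arc length are twigs, not segments
SEGMENT_MIN_UM = 5.0
#: somata within this planar distance of the barrel boundary are "edge"
EDGE_DISTANCE_UM = 12.5


class MorphometryError(ValueError):
    """Base class for morphometry failures."""


class StructuralError(MorphometryError):
    """Tree is malformed: cycle, disconnection, orphan node."""


class UndefinedOBIError(MorphometryError):
    """OBI requested for a neuron with zero basal-dendrite length."""


class DegenerateGeometryError(MorphometryError):
    """Boundary direction undefined (soma coincides with barrel center)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Barrel:
    barrel_id: str
    center: np.ndarray          # (2,) µm
    boundary: np.ndarray        # (n, 2) closed ring, µm

    def polygon(self) -> Polygon:
        return Polygon(self.boundary)


@dataclass
class BarrelMap:
    """2-D barrel polygons and centers delineating the barrel field."""

    barrels: list[Barrel]
    field_bbox: tuple[float, float, float, float] | None = None  # xmin,ymin,xmax,ymax

    def __post_init__(self) -> None:
        ids = [b.barrel_id for b in self.barrels]
        if len(set(ids)) != len(ids):
            raise MorphometryError("barrel ids must be unique")
        for b in self.barrels:
            poly = b.polygon()
            if not poly.is_valid:
                raise MorphometryError(
                    f"barrel {b.barrel_id}: polygon is self-intersecting or invalid"
                )
            if not poly.contains(Point(b.center)):
                raise MorphometryError(
                    f"barrel {b.barrel_id}: center not inside its polygon"
                )
        if self.field_bbox is None:
            xs = np.concatenate([b.boundary[:, 0] for b in self.barrels])
            ys = np.concatenate([b.boundary[:, 1] for b in self.barrels])
            self.field_bbox = (xs.min(), ys.min(), xs.max(), ys.max())

    def barrel(self, barrel_id: str) -> Barrel:
        for b in self.barrels:
            if b.barrel_id == barrel_id:
                return b
        raise KeyError(barrel_id)

    def nearest_barrel(self, xy: Sequence[float]) -> Barrel:
        p = Point(xy[0], xy[1])
        return min(self.barrels, key=lambda b: b.polygon().distance(p))


@dataclass
class DendriticTree:
    """One rooted dendritic (or axonal) arbor.

    ``nodes`` is an (n, 3) array of µm coordinates; ``parents`` gives the
    index of each node's parent, with -1 for the single root.  The root is
    the tree origin on the soma surface.
    """

    tree_id: str
    nodes: np.ndarray
    parents: np.ndarray
    kind: Literal["AD", "BD", "axon"] = "BD"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise StructuralError(f"tree {self.tree_id}: nodes must be (n, 3)")
        if self.parents.shape != (len(self.nodes),):
            raise StructuralError(f"tree {self.tree_id}: parents length mismatch")
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1:
            raise StructuralError(
                f"tree {self.tree_id}: expected exactly one root, found {len(roots)}"
            )
        n = len(self.nodes)
        if np.any(self.parents >= n):
            raise StructuralError(f"tree {self.tree_id}: parent index out of range")
        # connectivity + acyclicity: walk each node to the root
        for i in range(n):
            seen = set()
            j = i
            while self.parents[j] >= 0:
                if j in seen:
                    raise StructuralError(f"tree {self.tree_id}: cycle at node {j}")
                seen.add(j)
                j = self.parents[j]
        for i in range(n):
            p = self.parents[i]
            if p >= 0 and np.linalg.norm(self.nodes[i] - self.nodes[p]) <= 0.0:
                raise StructuralError(
                    f"tree {self.tree_id}: zero-length edge at node {i}"
                )

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parents < 0)[0])

    @property
    def origin(self) -> np.ndarray:
        """3-D origin of the tree on the soma surface."""
        return self.nodes[self.root_index]

    def edge_lengths(self) -> np.ndarray:
        """Per-node length of the edge to the parent (0 for the root)."""
        out = np.zeros(len(self.nodes))
        has_parent = self.parents >= 0
        out[has_parent] = np.linalg.norm(
            self.nodes[has_parent] - self.nodes[self.parents[has_parent]], axis=1
        )
        return out

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(len(self.nodes))]
        for i, p in enumerate(self.parents):
            if p >= 0:
                out[p].append(i)
        return out


@dataclass
class TracedNeuron:
    """One labeled L4 neuron traced at one imaging session."""

    neuron_id: str
    session_id: str
    soma_center: np.ndarray       # (3,) µm
    trees: list[DendriticTree] = field(default_factory=list)
    home_barrel_id: str | None = None

    def __post_init__(self) -> None:
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        n_ad = sum(1 for t in self.trees if t.kind == "AD")
        if n_ad > 1:
            raise StructuralError(
                f"neuron {self.neuron_id}@{self.session_id}: more than one AD tree"
            )

    @property
    def bd_trees(self) -> list[DendriticTree]:
        return [t for t in self.trees if t.kind == "BD"]

    @property
    def ad_tree(self) -> DendriticTree | None:
        for t in self.trees:
            if t.kind == "AD":
                return t
        return None

    def ad_length(self) -> float:
        ad = self.ad_tree
        return ad.total_length() if ad is not None else 0.0


@dataclass
class ADTrajectory:
    """Apical-dendrite total length of one neuron over ordered sessions."""

    neuron_id: str
    sessions: list[str]
    lengths: np.ndarray           # µm, absent AD -> 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if len(self.lengths) != len(self.sessions):
            raise MorphometryError("sessions and lengths length mismatch")
        if np.any(self.lengths < 0):
            raise MorphometryError("AD lengths must be >= 0")


@dataclass(frozen=True)
class Segment:
    """A maximal branch-point-to-branch-point (or -to-tip) polyline."""

    polyline: np.ndarray          # (k, 3) µm
    length: float
    terminal: bool                # ends at a dendritic tip

    @property
    def klass(self) -> str:
        return "tip-terminal" if self.terminal else "branch"


@dataclass(frozen=True)
class ObiResult:
    """Orientation bias index with its ingredients.

    ``obi = inner_length / (inner_length + outer_length)``; lengths are
    summed over retained (> 5 µm) basal-dendrite segments, each assigned
    inside/outside by the majority of its arc length.  ``boundary`` is the
    (point, unit normal) pair defining the inside half-plane in the
    tangential plane; the normal points toward the barrel center.
    """

    obi: float
    inner_length: float
    outer_length: float
    boundary: tuple[np.ndarray, np.ndarray]


# ---------------------------------------------------------------------------
# segment partition (5 µm process rule)
# ---------------------------------------------------------------------------


def _raw_segments(tree: DendriticTree) -> tuple[list[list[int]], list[bool]]:
    """Node-index paths from root/branch points to next branch point/tip."""
    kids = tree.children()
    root = tree.root_index
    paths: list[list[int]] = []
    leaf: list[bool] = []
    # start a path at each child of the root or of a branch point
    stack = [(root, c) for c in kids[root]]
    while stack:
        start, node = stack.pop()
        path = [start, node]
        while len(kids[node]) == 1:
            node = kids[node][0]
            path.append(node)
        paths.append(path)
        if len(kids[node]) == 0:
            leaf.append(True)
        else:
            leaf.append(False)
            stack.extend((node, c) for c in kids[node])
    return paths, leaf


def _path_length(tree: DendriticTree, path: Sequence[int]) -> float:
    pts = tree.nodes[list(path)]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def partition_segments(
    tree: DendriticTree, min_um: float = SEGMENT_MIN_UM
) -> tuple[list[Segment], float]:
    """Partition an arbor into dendritic segments under the 5 µm rule.

    Terminal processes of arc length <= ``min_um`` are twigs: they are
    pruned (their branch point dissolves and flanking paths merge) and do
    not count as segments or tips, although their length still contributes
    to the tree's total length.  Pruning is iterated to a fixed point, so a
    branch that becomes terminal after its twigs are removed is itself
    subject to the rule.

    Returns ``(segments, excluded_length)`` where ``excluded_length`` is the
    total arc length of pruned twigs.  The sum of segment lengths plus
    ``excluded_length`` equals the tree's total edge length.
    """
    # work on a mutable copy of the topology: keep set of pruned nodes
    pruned = np.zeros(len(tree.nodes), dtype=bool)
    excluded = 0.0

    def live_children() -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(len(tree.nodes))]
        for i, p in enumerate(tree.parents):
            if p >= 0 and not pruned[i]:
                out[p].append(i)
        return out

    elen = tree.edge_lengths()
    root = tree.root_index
    while True:
        kids = live_children()
        # find terminal paths: walk up from each live leaf to the nearest
        # upstream branch point (or root)
        changed = False
        leaves = [
            i
            for i in range(len(tree.nodes))
            if not pruned[i] and i != root and not kids[i]
        ]
        for lf in leaves:
            path = [lf]
            j = lf
            while True:
                p = tree.parents[j]
                if p == root or len(kids[p]) != 1:
                    break
                path.append(p)
                j = p
            plen = float(elen[path].sum())
            if plen <= min_um:
                pruned[path] = True
                excluded += plen
                changed = True
        if not changed:
            break

    # partition the retained topology
    kids = live_children()
    segments: list[Segment] = []
    stack = [(root, c) for c in kids[root]]
    while stack:
        start, node = stack.pop()
        path = [start, node]
        while len(kids[node]) == 1:
            node = kids[node][0]
            path.append(node)
        terminal = len(kids[node]) == 0
        segments.append(
            Segment(
                polyline=tree.nodes[path].copy(),
                length=_path_length(tree, path),
                terminal=terminal,
            )
        )
        if not terminal:
            stack.extend((node, c) for c in kids[node])
    return segments, excluded


# ---------------------------------------------------------------------------
# inside/outside boundary and OBI
# ---------------------------------------------------------------------------


def inside_outside_boundary(
    neuron: TracedNeuron, barrel_map: BarrelMap
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary separating the barrel-center half-plane from the far half.

    The boundary is the line through the soma center (projected to the
    tangential x-y plane) perpendicular to the soma -> home-barrel-center
    direction.  Returns ``(point, unit_normal)``; the normal points toward
    the barrel center, and "inside" is the half-plane it points into.
    """
    soma = neuron.soma_center[:2]
    if neuron.home_barrel_id is not None:
        barrel = barrel_map.barrel(neuron.home_barrel_id)
    else:
        barrel = barrel_map.nearest_barrel(soma)
    vec = np.asarray(barrel.center, float) - soma
    norm = np.linalg.norm(vec)
    if norm == 0.0:
        raise DegenerateGeometryError(
            f"neuron {neuron.neuron_id}: soma coincides with barrel center; "
            "inside/outside direction undefined"
        )
    return soma.copy(), vec / norm


def _edge_inside_lengths(
    polyline: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
    projected: bool = False,
) -> tuple[float, float]:
    """Arc length of a 3-D polyline on each side of the boundary.

    Side is decided in the tangential (x-y) plane; length is 3-D arc
    length unless ``projected`` (then 2-D).  Edges crossing the boundary
    are split at the crossing.
    """
    p = np.asarray(polyline, float)
    s = (p[:, :2] - point) @ normal  # signed planar distance per vertex
    seg3 = np.linalg.norm(np.diff(p, axis=0), axis=1)
    seg2 = np.linalg.norm(np.diff(p[:, :2], axis=0), axis=1)
    seg = seg2 if projected else seg3
    inside = 0.0
    outside = 0.0
    for i in range(len(p) - 1):
        a, b = s[i], s[i + 1]
        if a >= 0 and b >= 0:
            inside += seg[i]
        elif a < 0 and b < 0:
            outside += seg[i]
        else:
            # split at the boundary crossing
            t = a / (a - b)
            if a >= 0:
                inside += seg[i] * t
                outside += seg[i] * (1 - t)
            else:
                outside += seg[i] * t
                inside += seg[i] * (1 - t)
    return inside, outside


def compute_obi(
    neuron: TracedNeuron,
    barrel_map: BarrelMap,
    projected: bool = False,
) -> ObiResult:
    """Orientation bias index of a neuron's basal dendrites.

    Each retained BD segment is assigned inside (barrel-center half) or
    outside by the majority of its arc length; ties go inside.  OBI is the
    inner segment length over the total segment length.  Apical dendrite
    and axon are excluded.  ``projected=True`` uses 2-D projected lengths
    throughout; the default uses 3-D arc length with a 2-D side test.
    """
    point, normal = inside_outside_boundary(neuron, barrel_map)
    inner = 0.0
    outer = 0.0
    for tree in neuron.bd_trees:
        segments, _ = partition_segments(tree)
        for seg in segments:
            ins, outs = _edge_inside_lengths(seg.polyline, point, normal, projected)
            if ins >= outs:
                inner += ins + outs
            else:
                outer += ins + outs
    total = inner + outer
    if total <= 0.0:
        raise UndefinedOBIError(
            f"neuron {neuron.neuron_id}: zero basal-dendrite segment length"
        )
    return ObiResult(
        obi=inner / total,
        inner_length=inner,
        outer_length=outer,
        boundary=(point, normal),
    )


def classify_barrel_position(
    neuron: TracedNeuron,
    barrel_map: BarrelMap,
    edge_um: float = EDGE_DISTANCE_UM,
) -> str:
    """Classify the soma as ``edge``, ``center`` or ``outside_field``.

    Edge: planar distance from the soma center to the home-barrel boundary
    is <= 12.5 µm (inclusive), whether the soma sits just inside or just
    outside the polygon.  Center: inside the barrel and farther than
    12.5 µm from its boundary.  Anything else is outside the field.
    """
    soma = Point(neuron.soma_center[0], neuron.soma_center[1])
    if neuron.home_barrel_id is not None:
        barrel = barrel_map.barrel(neuron.home_barrel_id)
    else:
        barrel = barrel_map.nearest_barrel(neuron.soma_center[:2])
    poly = barrel.polygon()
    d_boundary = poly.exterior.distance(soma)
    if d_boundary <= edge_um:
        return "edge"
    if poly.contains(soma):
        return "center"
    return "outside_field"


# ---------------------------------------------------------------------------
# AD trajectory classification
# ---------------------------------------------------------------------------


def classify_group(traj: ADTrajectory, delta: float = 10.0) -> str:
    """Classify an AD-length trajectory as ``Group1`` or ``Group2``.

    Group 1 (prospective spiny stellate): the neuron had no AD at the first
    session, or its AD retracted — final length more than ``delta`` below
    the running maximum.  Group 2 (star pyramid): the AD extended
    continuously.  ``delta`` (µm) absorbs tracing jitter.
    """
    if len(traj.lengths) < 2:
        raise MorphometryError(
            f"neuron {traj.neuron_id}: need >= 2 sessions to classify AD dynamics"
        )
    if traj.lengths[0] == 0.0:
        return "Group1"
    running_max = np.maximum.accumulate(traj.lengths)
    if traj.lengths[-1] < running_max[-1] - delta:
        return "Group1"
    return "Group2"


# ---------------------------------------------------------------------------
# tree side, angle, totals
# ---------------------------------------------------------------------------


def tree_side(
    tree: DendriticTree,
    boundary: tuple[np.ndarray, np.ndarray],
) -> str:
    """``inner`` or ``outer`` by which half-plane holds the tree origin.

    An origin exactly on the boundary is inner (deterministic tie rule).
    """
    point, normal = boundary
    s = float((tree.origin[:2] - point) @ normal)
    return "inner" if s >= 0 else "outer"


def tree_origin_angle(
    tree: DendriticTree,
    boundary: tuple[np.ndarray, np.ndarray],
) -> float:
    """Angle of the tree origin about the soma, degrees in (-180, 180].

    0° points toward the barrel center; counter-clockwise positive.
    """
    point, normal = boundary
    v = tree.origin[:2] - point
    # rotate frame so that `normal` is the +x axis
    x = float(v @ normal)
    y = float(-v[0] * normal[1] + v[1] * normal[0])
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def tree_metrics(tree: DendriticTree) -> tuple[float, int, int]:
    """``(total length µm, tip count, segment count)`` for one tree.

    Length sums every edge; tips and segments obey the 5 µm twig rule.
    """
    segments, _ = partition_segments(tree)
    tips = sum(1 for s in segments if s.terminal)
    if not segments:
        # a whole arbor at or below the twig threshold: length only
        return tree.total_length(), 0, 0
    return tree.total_length(), tips, len(segments)


def neuron_totals(
    neuron: TracedNeuron,
    boundary: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Aggregate BD morphometry for one neuron at one session."""
    total_len = 0.0
    total_tips = 0
    n_inner = 0
    n_outer = 0
    for tree in neuron.bd_trees:
        length, tips, _ = tree_metrics(tree)
        total_len += length
        total_tips += tips
        if boundary is not None:
            if tree_side(tree, boundary) == "inner":
                n_inner += 1
            else:
                n_outer += 1
    return {
        "total_bd_length": total_len,
        "total_bd_tips": total_tips,
        "n_trees_inner": n_inner,
        "n_trees_outer": n_outer,
        "n_trees": len(neuron.bd_trees),
    }


def fold_change(
    first_values: Iterable[float], last_values: Iterable[float]
) -> tuple[float, np.ndarray]:
    """First-to-last-session fold change of a per-neuron metric.

    Returns the ratio of the mean over neurons at the final session to the
    mean at the first session, plus the vector of per-neuron ratios
    (NaN where the first-session value is zero).
    """
    first = np.asarray(list(first_values), float)
    last = np.asarray(list(last_values), float)
    if first.shape != last.shape or first.size == 0:
        raise MorphometryError("need matched non-empty first/last metric vectors")
    mean_first = first.mean()
    if mean_first == 0.0:
        raise MorphometryError("zero mean at first session: fold change undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_neuron = np.where(first > 0, last / first, np.nan)
    return float(last.mean() / mean_first), per_neuron
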