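"""Tree-level morphometrics for dendritic arbors.

Conventions
-----------
- Lengths are in micrometres; only compartments whose *child* node carries the
  dendrite structure code contribute to dendritic totals.
- A *branch* is a maximal unbranched path delimited by the root, branch points
  (nodes with >= 2 dendritic children) and terminals, so
  ``n_branches = n_terminals + n_branch_points`` (root excluded from the
  branch-point census).  A k-furcation ends the parent branch and starts k
  daughters.
- Strahler order: terminal branches are order 1; a parent branch whose child
  branches attain maximal order k gets k+1 when at least two children attain
  k, else k.  The branch containing the root attains the maximal order, so
  order 7 is the soma-adjacent primary branch of a deep arbor and order 1 the
  terminal tips.
- Sholl intersections count, per concentric radius, the dendritic compartments
  whose endpoint radial distances straddle the shell (crossing parity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree, box
from shapely.geometry import LineString

from .errors import ParameterError
from .recon_io import Arbor, compartmentalize, node_path_distances

logger = logging.getLogger("dendroquant")


# -- dendritic subtree helpers ----------------------------------------------------


def _dendritic_children(arbor: Arbor) -> dict[int, list[int]]:
    """Map node_id -> dendritic children (children whose structure code is 3)."""
    nodes = arbor.nodes
    dend = set(int(i) for i in nodes.loc[nodes["structure_code"] == 3, "node_id"])
    out: dict[int, list[int]] = {int(i): [] for i in nodes["node_id"]}
    for nid, pid in zip(nodes["node_id"], nodes["parent_id"]):
        if pid != -1 and int(nid) in dend:
            out[int(pid)].append(int(nid))
    return out


def total_dendritic_length(arbor: Arbor) -> float:
    """Sum of compartment lengths over dendritic compartments (um)."""
    comp = compartmentalize(arbor)
    dend = comp[comp["structure"] == "dendrite"]
    if len(dend) == 0:
        warnings.warn("arbor has no dendritic compartments; total length is 0")
        return 0.0
    return float(dend["length_um"].sum())


# -- branch decomposition and Strahler ordering -----------------------------------


@dataclass
class Branch:
    """A maximal unbranched dendritic path."""

    branch_id: int
    node_ids: list[int]  # child node of each compartment, proximal to distal
    order: int  # Strahler order shared by all compartments of the branch
    total_length: float  # um


def strahler_orders(arbor: Arbor) -> tuple[pd.Series, dict[int, int]]:
    """Strahler order of every dendritic compartment, plus the branch histogram.

    Returns
    -------
    orders:
        Series indexed by compartment child node_id (dendritic compartments
        only) giving the Strahler order of the branch the compartment lies on.
    histogram:
        Mapping order -> number of branches of that order.
    """
    children = _dendritic_children(arbor)
    root = arbor.root_id
    order: dict[int, int] = {}

    # iterative post-order over the dendritic subtree
    nodes = arbor.nodes
    dend_ids = [
        int(i) for i in nodes.loc[nodes["structure_code"] == 3, "node_id"]
    ]
    stack = [(root, False)]
    while stack:
        nid, processed = stack.pop()
        kids = children[nid]
        if not processed:
            stack.append((nid, True))
            for k in kids:
                stack.append((k, False))
        else:
            if nid == root:
                continue
            if not kids:
                order[nid] = 1
            else:
                ko = [order[k] for k in kids]
                mx = max(ko)
                order[nid] = mx + 1 if ko.count(mx) >= 2 else mx
    orders = pd.Series(order, name="strahler_order", dtype=int).loc[dend_ids]

    hist: dict[int, int] = {}
    for br in branches(arbor, orders):
        hist[br.order] = hist.get(br.order, 0) + 1
    return orders, hist


def branches(arbor: Arbor, orders: pd.Series | None = None) -> list[Branch]:
    """Decompose the dendritic subtree into maximal unbranched branches."""
    children = _dendritic_children(arbor)
    comp = compartmentalize(arbor)
    length = comp["length_um"]
    if orders is None and len(comp[comp["structure"] == "dendrite"]):
        orders, _hist = _orders_only(arbor)
    root = arbor.root_id
    out: list[Branch] = []
    # branch starts: dendritic children of the root and of every branch point
    starts = list(children[root])
    for nid, kids in children.items():
        if nid != root and len(kids) >= 2:
            starts.extend(kids)
    # preserve a deterministic proximal-first ordering
    seen_start = set()
    bid = 0
    for start in starts:
        if start in seen_start:
            continue
        seen_start.add(start)
        path = [start]
        cur = start
        while len(children[cur]) == 1:
            cur = children[cur][0]
            path.append(cur)
        total = float(length.loc[path].sum())
        o = int(orders.loc[start]) if orders is not None else 0
        out.append(Branch(branch_id=bid, node_ids=path, order=o, total_length=total))
        bid += 1
    return out


def _orders_only(arbor: Arbor) -> tuple[pd.Series, None]:
    """Strahler orders without the branch histogram (avoids recursion with branches)."""
    children = _dendritic_children(arbor)
    root = arbor.root_id
    order: dict[int, int] = {}
    stack = [(root, False)]
    while stack:
        nid, processed = stack.pop()
        kids = children[nid]
        if not processed:
            stack.append((nid, True))
            for k in kids:
                stack.append((k, False))
        elif nid != root:
            if not kids:
                order[nid] = 1
            else:
                ko = [order[k] for k in kids]
                mx = max(ko)
                order[nid] = mx + 1 if ko.count(mx) >= 2 else mx
    nodes = arbor.nodes
    dend_ids = [int(i) for i in nodes.loc[nodes["structure_code"] == 3, "node_id"]]
    return pd.Series(order, name="strahler_order", dtype=int).loc[dend_ids], None


def count_branches(arbor: Arbor) -> int:
    """Number of maximal unbranched dendritic paths."""
    return len(branches(arbor))


def branch_density(arbor: Arbor) -> float:
    """Branches per micrometre of dendritic cable."""
    total = total_dendritic_length(arbor)
    if total == 0:
        raise ParameterError("branch density undefined: zero dendritic length")
    return count_branches(arbor) / total


# -- Sholl profile ----------------------------------------------------------------


@dataclass
class ShollProfile:
    """Dendritic shell-crossing counts at evenly spaced radii from the soma."""

    radii: np.ndarray  # um, multiples of the step
    intersections: np.ndarray  # crossings per radius
    step: float

    @property
    def peak_intersections(self) -> int:
        return int(self.intersections.max())

    @property
    def peak_radius(self) -> float:
        # proximal tie-break: first radius attaining the maximum
        return float(self.radii[int(np.argmax(self.intersections))])


def sholl_profile(arbor: Arbor, step_um: float = 10.0, projected: bool = False) -> ShollProfile:
    """Count dendritic compartments crossing concentric shells around the root.

    Radial distance is 3-D Euclidean from the root by default; ``projected``
    uses the x-y projection (matching analyses on maximum-intensity
    projections).  A compartment crosses the shell of radius ``r`` when its
    endpoint distances straddle ``r`` (``min < r <= max``, crossing parity).
    """
    if step_um <= 0:
        raise ParameterError("Sholl step must be > 0")
    nodes = arbor.nodes.set_index("node_id")
    root = arbor.root_id
    dims = ["x", "y"] if projected else ["x", "y", "z"]
    origin = nodes.loc[root, dims].to_numpy(dtype=float)
    radial = np.linalg.norm(nodes[dims].to_numpy(dtype=float) - origin, axis=1)
    rad = pd.Series(radial, index=nodes.index)

    comp = compartmentalize(arbor)
    dend = comp[comp["structure"] == "dendrite"]
    r_child = rad.loc[dend.index].to_numpy()
    r_parent = rad.loc[dend["parent_id"]].to_numpy()
    lo = np.minimum(r_child, r_parent)
    hi = np.maximum(r_child, r_parent)

    max_extent = float(rad.max())
    n = int(np.floor(max_extent / step_um))
    if n < 1:
        warnings.warn("Sholl step exceeds the arbor extent; single-radius profile")
        n = 1
    radii = step_um * np.arange(1, n + 1)
    inter = np.array([int(np.sum((lo < r) & (r <= hi))) for r in radii])
    return ShollProfile(radii=radii, intersections=inter, step=float(step_um))


# -- internal field coverage ------------------------------------------------------


@dataclass
class CoverageGrid:
    """Grid occupancy of the x-y bounding rectangle of the dendritic field."""

    box_size: float  # um
    n_boxes_total: int
    n_boxes_occupied: int

    @property
    def proportion_covered(self) -> float:
        return self.n_boxes_occupied / self.n_boxes_total


def internal_coverage(arbor: Arbor, box_size_um: float = 10.0) -> CoverageGrid:
    """Proportion of grid boxes containing dendrite within the bounding rectangle.

    The rectangle is bounded by the outermost dendritic node on each side
    (x-y projection), partitioned into ``box_size x box_size`` squares with
    partial boxes at the far edges included.  A box is occupied when any
    projected dendritic compartment segment intersects it.
    """
    if box_size_um <= 0:
        raise ParameterError("coverage box size must be > 0")
    nodes = arbor.nodes.set_index("node_id")
    comp = compartmentalize(arbor)
    dend = comp[comp["structure"] == "dendrite"]
    if len(dend) < 1:
        raise ParameterError("coverage needs at least one dendritic compartment")
    pts = nodes.loc[
        nodes["structure_code"] == 3, ["x", "y"]
    ].to_numpy(dtype=float)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    width, height = xmax - xmin, ymax - ymin
    if width == 0 or height == 0:
        warnings.warn("degenerate bounding box; coverage computed on a 1-D strip")
    nx = max(1, int(np.ceil(width / box_size_um)))
    ny = max(1, int(np.ceil(height / box_size_um)))

    segs = [
        LineString(
            [
                nodes.loc[cid, ["x", "y"]].to_numpy(dtype=float),
                nodes.loc[pid, ["x", "y"]].to_numpy(dtype=float),
            ]
        )
        for cid, pid in zip(dend.index, dend["parent_id"])
    ]
    tree = STRtree(segs)
    occupied = 0
    for i in range(nx):
        for j in range(ny):
            cell = box(
                xmin + i * box_size_um,
                ymin + j * box_size_um,
                xmin + (i + 1) * box_size_um,
                ymin + (j + 1) * box_size_um,
            )
            hits = tree.query(cell)
            if any(cell.intersects(segs[k]) for k in hits):
                occupied += 1
    return CoverageGrid(
        box_size=float(box_size_um), n_boxes_total=nx * ny, n_boxes_occupied=occupied
    )


# -- organelle statistics ---------------------------------------------------------


def organelle_density(positions: pd.DataFrame, arbor: Arbor) -> float:
    """Organelle count per 100 um of dendritic cable.

    ``positions`` carries one row per organelle with a ``path_um`` column
    (path distance from the soma).  Records beyond the arbor's maximal path
    extent are rejected with a warning.
    """
    total = total_dendritic_length(arbor)
    if total == 0:
        raise ParameterError("organelle density undefined: zero dendritic length")
    max_path = float(node_path_distances(arbor).max())
    ok = positions["path_um"].to_numpy(dtype=float) <= max_path
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} organelle position(s) beyond the arbor extent rejected"
        )
    return 100.0 * float(ok.sum()) / total


def branch_points(arbor: Arbor) -> list[int]:
    """Dendritic branch points: non-root nodes with >= 2 dendritic children."""
    children = _dendritic_children(arbor)
    root = arbor.root_id
    return [nid for nid, kids in children.items() if nid != root and len(kids) >= 2]


def branchpoint_occupancy(positions: pd.DataFrame, arbor: Arbor) -> float:
    """Percentage of dendritic branch points carrying >= 1 flagged organelle.

    Rows with ``at_branch_point`` truthy are attributed to the branch point at
    the distal end of the branch named by their ``branch_id``; flags on
    terminal branches are rejected with a warning.
    """
    bps = set(branch_points(arbor))
    if not bps:
        raise ParameterError("arbor has no dendritic branch points")
    brs = {b.branch_id: b for b in branches(arbor)}
    occupied: set[int] = set()
    n_rejected = 0
    flagged = positions[positions["at_branch_point"].astype(bool)]
    for row in flagged.itertuples(index=False):
        br = brs.get(int(row.branch_id))
        tip = br.node_ids[-1] if br is not None else None
        if tip in bps:
            occupied.add(tip)
        else:
            n_rejected += 1
    if n_rejected:
        warnings.warn(
            f"{n_rejected} flagged organelle(s) not at a branch point rejected"
        )
    return 100.0 * len(occupied) / len(bps)


# -- per-neuron summary -----------------------------------------------------------


def morphometry_summary(
    arbor: Arbor,
    sholl_step: float = 10.0,
    coverage_box: float = 10.0,
    projected: bool = False,
) -> dict[str, float]:
    """Standard scalar morphometrics for one arbor, as a flat feature dict."""
    orders, hist = strahler_orders(arbor)
    sholl = sholl_profile(arbor, sholl_step, projected=projected)
    cov = internal_coverage(arbor, coverage_box)
    out = {
        "total_length_um": total_dendritic_length(arbor),
        "n_branches": float(sum(hist.values())),
        "branch_density_per_um": branch_density(arbor),
        "proportion_covered": cov.proportion_covered,
        "max_strahler_order": float(max(hist)),
        "sholl_peak": float(sholl.peak_intersections),
        "sholl_peak_radius_um": sholl.peak_radius,
    }
    for k in range(1, max(hist) + 1):
        out[f"strahler_n{k}"] = float(hist.get(k, 0))
    return out
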