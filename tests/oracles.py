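"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (naive recursion,
per-segment enumeration, parametric line clipping) and never calls the code
paths it validates.
"""

import numpy as np


def tree_children(arbor):
    """node_id -> children (dendritic only), computed by a plain scan."""
    nodes = arbor.nodes
    dend = set(
        int(i) for i in nodes.loc[nodes["structure_code"] == 3, "node_id"]
    )
    kids = {int(i): [] for i in nodes["node_id"]}
    for nid, pid in zip(nodes["node_id"], nodes["parent_id"]):
        if pid != -1 and int(nid) in dend:
            kids[int(pid)].append(int(nid))
    return kids


def strahler_recursive(arbor):
    """Edge Strahler orders by direct post-order recursion on the definition."""
    kids = tree_children(arbor)
    orders = {}

    def visit(nid):
        cs = kids[nid]
        if not cs:
            return 1
        child_orders = [visit(c) for c in cs]
        m = max(child_orders)
        return m + 1 if child_orders.count(m) >= 2 else m

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(10000)
    try:
        root = arbor.root_id
        for nid in kids:
            if nid == root:
                continue
            # order of the edge above nid = order of nid's subtree
            orders[nid] = visit(nid)
    finally:
        sys.setrecursionlimit(old)
    return orders


def total_length_edgewalk(arbor, code=3):
    """Total cable length by naive per-edge enumeration."""
    nodes = arbor.nodes.set_index("node_id")
    total = 0.0
    for nid, row in nodes.iterrows():
        if row["parent_id"] == -1 or int(row["structure_code"]) != code:
            continue
        p = nodes.loc[int(row["parent_id"])]
        total += float(
            np.sqrt(
                (row["x"] - p["x"]) ** 2
                + (row["y"] - p["y"]) ** 2
                + (row["z"] - p["z"]) ** 2
            )
        )
    return total


def branch_count_degree_census(arbor):
    """Branches = dendritic terminals + non-root dendritic branch points."""
    kids = tree_children(arbor)
    nodes = arbor.nodes
    dend = set(int(i) for i in nodes.loc[nodes["structure_code"] == 3, "node_id"])
    root = arbor.root_id
    terminals = sum(1 for n in dend if not kids[n])
    bps = sum(1 for n in dend if n != root and len(kids[n]) >= 2)
    return terminals + bps


def sholl_crossings(arbor, radius, projected=False):
    """Sphere-segment crossing parity at one radius, segment by segment."""
    nodes = arbor.nodes.set_index("node_id")
    root = arbor.root_id
    dims = ["x", "y"] if projected else ["x", "y", "z"]
    o = nodes.loc[root, dims].to_numpy(dtype=float)
    count = 0
    for nid, row in nodes.iterrows():
        if row["parent_id"] == -1 or int(row["structure_code"]) != 3:
            continue
        p = nodes.loc[int(row["parent_id"])]
        rc = float(np.linalg.norm(row[dims].to_numpy(dtype=float) - o))
        rp = float(np.linalg.norm(p[dims].to_numpy(dtype=float) - o))
        if min(rc, rp) < radius <= max(rc, rp):
            count += 1
    return count


def segment_intersects_rect(p0, p1, xlo, ylo, xhi, yhi):
    """Liang-Barsky parametric clipping of a 2-D segment against a rectangle."""
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - xlo),
        (dx, xhi - x0),
        (-dy, y0 - ylo),
        (dy, yhi - y0),
    ):
        if p == 0:
            if q < 0:
                return False
        else:
            t = q / p
            if p < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
            if t0 > t1:
                return False
    return True


def coverage_bruteforce(arbor, box_size):
    """Grid occupancy by testing every box against every dendritic segment."""
    nodes = arbor.nodes.set_index("node_id")
    dend_nodes = nodes[nodes["structure_code"] == 3]
    xmin, ymin = dend_nodes[["x", "y"]].min()
    xmax, ymax = dend_nodes[["x", "y"]].max()
    nx = max(1, int(np.ceil((xmax - xmin) / box_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / box_size)))
    segs = []
    for nid, row in nodes.iterrows():
        if row["parent_id"] == -1 or int(row["structure_code"]) != 3:
            continue
        p = nodes.loc[int(row["parent_id"])]
        segs.append(((row["x"], row["y"]), (p["x"], p["y"])))
    occ = 0
    for i in range(nx):
        for j in range(ny):
            xlo = xmin + i * box_size
            ylo = ymin + j * box_size
            if any(
                segment_intersects_rect(a, b, xlo, ylo, xlo + box_size, ylo + box_size)
                for a, b in segs
            ):
                occ += 1
    return occ, nx * ny


def quantity_bruteforce(arbor, channel):
    """Total Q_c by naive node-pair enumeration of the I*F*D*L products."""
    nodes = arbor.nodes.set_index("node_id")
    sig = arbor.signals[arbor.signals["channel"] == channel].set_index("node_id")
    total = 0.0
    for nid, row in nodes.iterrows():
        if row["parent_id"] == -1 or int(row["structure_code"]) != 3:
            continue
        pid = int(row["parent_id"])
        p = nodes.loc[pid]
        Is, Fs = [], []
        for end in (nid, pid):
            if end in sig.index:
                Is.append(float(sig.loc[end, "intensity_I"]))
                Fs.append(float(sig.loc[end, "fraction_F"]))
        if not Is:
            continue
        I = sum(Is) / len(Is)
        F = sum(Fs) / len(Fs)
        L = float(
            np.sqrt(
                (row["x"] - p["x"]) ** 2
                + (row["y"] - p["y"]) ** 2
                + (row["z"] - p["z"]) ** 2
            )
        )
        D = float(row["radius"] + p["radius"])
        total += I * F * D * L
    return total
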