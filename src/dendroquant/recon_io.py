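"""Reading, validating and writing SWC reconstructions and channel sidecar tables.

An :class:`Arbor` couples a standard 7-column SWC node table with an optional
per-node channel table (tab-separated: ``node_id``, ``channel``,
``intensity_I``, ``fraction_F``).  The channel sidecar keeps the SWC file
itself NeuroMorpho-compatible while carrying the relative signal intensity
``I`` and occupied volume fraction ``F`` that the quantification stage
consumes.

All downstream analyses operate on *compartments*: the edge between a
non-root node and its parent, carrying a Euclidean length ``L`` (um), a
diameter ``D`` (um, the sum of the two endpoint radii, i.e. the mean endpoint
diameter) and a path distance from the root to the edge midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ChannelJoinError,
    DegenerateGeometryError,
    SWCParseError,
    TopologyError,
    ValidationError,
)

logger = logging.getLogger("dendroquant")

#: SWC structure codes used by this package.
STRUCTURE_CODES = {1: "soma", 2: "axon", 3: "dendrite"}

NODE_COLUMNS = ["node_id", "structure_code", "x", "y", "z", "radius", "parent_id"]
SIGNAL_COLUMNS = ["node_id", "channel", "intensity_I", "fraction_F"]


@dataclass
class Arbor:
    """A rooted neuronal reconstruction with optional per-node channel signals.

    Parameters
    ----------
    nodes:
        One row per reconstruction point with columns ``node_id``,
        ``structure_code`` (1 soma, 2 axon, 3 dendrite), ``x``/``y``/``z``
        (um), ``radius`` (um, > 0) and ``parent_id`` (-1 for the root).
    signals:
        Channel table rows joined to nodes; may be empty.
    metadata:
        Free-form provenance: source path, cell class label, group label.
    """

    nodes: pd.DataFrame
    signals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SIGNAL_COLUMNS)
    )
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        validate_arbor(self)

    # -- basic topology accessors -------------------------------------------------

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].iloc[0])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def children_map(self) -> dict[int, list[int]]:
        """Map node_id -> list of child node_ids, in file order."""
        out: dict[int, list[int]] = {int(i): [] for i in self.nodes["node_id"]}
        for nid, pid in zip(self.nodes["node_id"], self.nodes["parent_id"]):
            if pid != -1:
                out[int(pid)].append(int(nid))
        return out

    def structure_class(self) -> pd.Series:
        """Per-node structure class name, indexed by node_id."""
        s = self.nodes.set_index("node_id")["structure_code"].map(STRUCTURE_CODES)
        s.name = "structure"
        return s

    def channels(self) -> list[str]:
        return sorted(self.signals["channel"].unique().tolist())


def validate_arbor(arbor: Arbor) -> None:
    """Check every structural invariant; raise on the first violation."""
    nodes = arbor.nodes
    missing = [c for c in NODE_COLUMNS if c not in nodes.columns]
    if missing:
        raise ValidationError(f"node table missing columns: {missing}")
    if len(nodes) < 2:
        raise ValidationError("an arbor needs at least 2 nodes")
    ids = nodes["node_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = nodes.loc[nodes["node_id"].duplicated(), "node_id"].tolist()
        raise ValidationError(f"duplicate node_id(s): {dup}")
    if (ids <= 0).any():
        raise ValidationError("node_id must be a positive integer")
    bad_code = set(nodes["structure_code"]) - set(STRUCTURE_CODES)
    if bad_code:
        raise ValidationError(f"unknown structure code(s): {sorted(bad_code)}")
    if (nodes["radius"].to_numpy() <= 0).any():
        raise ValidationError("all radii must be > 0")

    roots = nodes.loc[nodes["parent_id"] == -1, "node_id"]
    if len(roots) != 1:
        raise TopologyError(f"expected exactly one root, found {len(roots)}")
    id_set = set(int(i) for i in ids)
    parents = nodes["parent_id"].to_numpy()
    orphans = [int(p) for p in parents if p != -1 and int(p) not in id_set]
    if orphans:
        raise TopologyError(f"parent reference(s) to missing node(s): {sorted(set(orphans))}")

    # acyclicity + connectivity: every node must reach the root
    parent_of = dict(zip((int(i) for i in ids), (int(p) for p in parents)))
    root = int(roots.iloc[0])
    reaches: dict[int, bool] = {root: True}
    for nid in parent_of:
        chain = []
        cur = nid
        while cur not in reaches:
            chain.append(cur)
            cur = parent_of[cur]
            if cur in chain:
                raise TopologyError(f"cycle in parent relation involving node {cur}")
        for c in chain:
            reaches[c] = True

    sig = arbor.signals
    missing = [c for c in SIGNAL_COLUMNS if c not in sig.columns]
    if missing:
        raise ValidationError(f"signal table missing columns: {missing}")
    if len(sig):
        unknown = sorted(set(int(i) for i in sig["node_id"]) - id_set)
        if unknown:
            raise ChannelJoinError(f"channel rows reference unknown node(s): {unknown}")
        if sig.duplicated(subset=["node_id", "channel"]).any():
            raise ValidationError("duplicate (node_id, channel) pairs in channel table")
        if (sig["intensity_I"].to_numpy() < 0).any():
            raise ValidationError("intensity_I must be >= 0")
        f = sig["fraction_F"].to_numpy()
        if ((f < 0) | (f > 1)).any():
            raise ValidationError("fraction_F must lie in [0, 1]")


# -- SWC reading / writing --------------------------------------------------------


def _parse_swc_lines(lines) -> pd.DataFrame:
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(
                f"expected 7 whitespace-separated columns, got {len(parts)}", lineno
            )
        try:
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
        except ValueError as exc:
            raise SWCParseError(str(exc), lineno) from exc
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def read_channel_table(path: str | Path) -> pd.DataFrame:
    """Read a channel sidecar TSV (node_id, channel, intensity_I, fraction_F)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"channel table {path} missing columns: {missing}")
    return df[SIGNAL_COLUMNS].astype(
        {"node_id": int, "channel": str, "intensity_I": float, "fraction_F": float}
    )


def read_swc(path: str | Path, channel_table_path: str | Path | None = None) -> Arbor:
    """Read a 7-column SWC file (and an optional channel sidecar) into an Arbor.

    Comment lines start with ``#``.  Node order is preserved.  A missing
    channel table yields an Arbor with empty signals.
    """
    path = Path(path)
    with open(path) as fh:
        nodes = _parse_swc_lines(fh)
    signals = (
        read_channel_table(channel_table_path)
        if channel_table_path is not None
        else pd.DataFrame(columns=SIGNAL_COLUMNS)
    )
    return Arbor(nodes=nodes, signals=signals, metadata={"source": str(path)})


def write_swc(
    arbor: Arbor, path: str | Path, channel_table_path: str | Path | None = None
) -> list[Path]:
    """Write a standard 7-column SWC file (coordinates/radii to 4 decimals).

    When the arbor carries channel signals they are written to a sidecar TSV
    (default: ``<path>.channels.tsv``).  Returns the list of files written.
    """
    path = Path(path)
    written = [path]
    with open(path, "w") as fh:
        fh.write("# SWC reconstruction written by dendroquant\n")
        fh.write("# columns: node_id structure_code x y z radius parent_id (um)\n")
        for row in arbor.nodes.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} {int(row.structure_code)} "
                f"{row.x:.4f} {row.y:.4f} {row.z:.4f} {row.radius:.4f} "
                f"{int(row.parent_id)}\n"
            )
    if len(arbor.signals):
        cpath = (
            Path(channel_table_path)
            if channel_table_path is not None
            else path.with_suffix(path.suffix + ".channels.tsv")
        )
        arbor.signals.to_csv(cpath, sep="\t", index=False)
        written.append(cpath)
    return written


# -- compartments -----------------------------------------------------------------


def node_path_distances(arbor: Arbor) -> pd.Series:
    """Path distance (um) from the root to every node along the tree."""
    nodes = arbor.nodes.set_index("node_id")
    xyz = nodes[["x", "y", "z"]].to_numpy()
    pos = {int(i): xyz[k] for k, i in enumerate(nodes.index)}
    parent = dict(zip((int(i) for i in nodes.index), (int(p) for p in nodes["parent_id"])))
    dist: dict[int, float] = {arbor.root_id: 0.0}

    def _dist(nid: int) -> float:
        stack = []
        while nid not in dist:
            stack.append(nid)
            nid = parent[nid]
        d = dist[nid]
        for child in reversed(stack):
            d = d + float(np.linalg.norm(pos[child] - pos[parent[child]]))
            dist[child] = d
        return d

    for nid in parent:
        _dist(nid)
    return pd.Series(dist, name="path_um").loc[list(nodes.index)]


def compartmentalize(arbor: Arbor) -> pd.DataFrame:
    """Derive one compartment per non-root node.

    Returns a DataFrame indexed by the child ``node_id`` with columns

    - ``parent_id``
    - ``structure`` — class of the *child* node (soma/axon/dendrite)
    - ``length_um`` — Euclidean child-parent distance ``L``
    - ``diameter_um`` — sum of the endpoint radii ``D``
    - ``path_mid_um`` — path distance root -> parent plus ``L/2``

    Raises :class:`DegenerateGeometryError` if any edge has coincident
    endpoints.
    """
    nodes = arbor.nodes.set_index("node_id")
    non_root = nodes[nodes["parent_id"] != -1]
    pid = non_root["parent_id"].astype(int)
    child_xyz = non_root[["x", "y", "z"]].to_numpy()
    parent_xyz = nodes.loc[pid, ["x", "y", "z"]].to_numpy()
    length = np.linalg.norm(child_xyz - parent_xyz, axis=1)
    if (length == 0).any():
        raise DegenerateGeometryError(non_root.index[length == 0].tolist())
    diameter = non_root["radius"].to_numpy() + nodes.loc[pid, "radius"].to_numpy()
    dist = node_path_distances(arbor)
    comp = pd.DataFrame(
        {
            "parent_id": pid.to_numpy(),
            "structure": non_root["structure_code"].map(STRUCTURE_CODES).to_numpy(),
            "length_um": length,
            "diameter_um": diameter,
            "path_mid_um": dist.loc[pid].to_numpy() + length / 2.0,
        },
        index=non_root.index,
    )
    comp.index.name = "child_id"
    return comp
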