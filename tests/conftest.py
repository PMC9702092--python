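"""Shared fixtures: hand-built arbors and random-tree factories."""

import numpy as np
import pandas as pd
import pytest

from dendroquant.recon_io import Arbor, NODE_COLUMNS, SIGNAL_COLUMNS


def make_arbor(rows, signals=None, metadata=None):
    """Build an Arbor from (id, code, x, y, z, radius, parent) tuples."""
    nodes = pd.DataFrame(rows, columns=NODE_COLUMNS)
    sig = (
        pd.DataFrame(signals, columns=SIGNAL_COLUMNS)
        if signals is not None
        else pd.DataFrame(columns=SIGNAL_COLUMNS)
    )
    return Arbor(nodes=nodes, signals=sig, metadata=metadata or {})


def random_tree(rng, n_nodes, all_dendrite=True):
    """A random valid arbor: soma root, random attachment, jittered coordinates.

    Coordinates are drawn so no edge is degenerate.  With ``all_dendrite``
    every non-root node is a dendrite, which is what the tree-shape oracles
    assume.
    """
    rows = [(1, 1, 0.0, 0.0, 0.0, 2.0, -1)]
    for nid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, nid))
        px, py, pz = rows[parent - 1][2:5]
        step = rng.uniform(1.0, 10.0)
        theta = rng.uniform(0, 2 * np.pi)
        phi = rng.uniform(0, np.pi)
        x = px + step * np.sin(phi) * np.cos(theta)
        y = py + step * np.sin(phi) * np.sin(theta)
        z = pz + step * np.cos(phi)
        code = 3 if all_dendrite else int(rng.choice([2, 3]))
        rows.append((nid, code, x, y, z, float(rng.uniform(0.2, 1.5)), parent))
    return make_arbor(rows)


@pytest.fixture
def chain_arbor():
    """root -> A (10 um) -> B (10 um), all dendrite."""
    return make_arbor(
        [
            (1, 1, 0.0, 0.0, 0.0, 2.0, -1),
            (2, 3, 10.0, 0.0, 0.0, 1.0, 1),
            (3, 3, 20.0, 0.0, 0.0, 1.0, 2),
        ]
    )


@pytest.fixture
def bifurcation_arbor():
    """A 50 um stem carrying two 50 um daughters (3 branches)."""
    return make_arbor(
        [
            (1, 1, 0.0, 0.0, 0.0, 2.0, -1),
            (2, 3, 50.0, 0.0, 0.0, 1.0, 1),
            (3, 3, 100.0, 30.0, 0.0, 0.5, 2),
            (4, 3, 100.0, -30.0, 0.0, 0.5, 2),
        ]
    )


@pytest.fixture
def caterpillar_arbor():
    """A stem with three single side terminals along it."""
    rows = [
        (1, 1, 0.0, 0.0, 0.0, 2.0, -1),
        (2, 3, 10.0, 0.0, 0.0, 1.0, 1),  # stem nodes 2,3,4, tip 5
        (3, 3, 20.0, 0.0, 0.0, 1.0, 2),
        (4, 3, 30.0, 0.0, 0.0, 1.0, 3),
        (5, 3, 40.0, 0.0, 0.0, 1.0, 4),
        (6, 3, 10.0, 5.0, 0.0, 0.5, 2),  # side terminals
        (7, 3, 20.0, 5.0, 0.0, 0.5, 3),
        (8, 3, 30.0, 5.0, 0.0, 0.5, 4),
    ]
    return make_arbor(rows)


def uniform_signals(arbor, channel="MT", I=1.0, F=0.5):
    """Attach a constant (I, F) signal to every node for one channel."""
    sig = [(int(n), channel, I, F) for n in arbor.nodes["node_id"]]
    return make_arbor(
        list(arbor.nodes.itertuples(index=False, name=None)), signals=sig
    )
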