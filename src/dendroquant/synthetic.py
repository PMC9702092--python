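"""Synthetic data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here with known
truth: CI-like (sparse, ~4 Strahler orders) and CIV-like (space-filling,
~7 Strahler orders) dendritic arbors, per-node channel intensity fields,
photoconversion decay series, and direction-biased comet tables.

The arbor generator separates topology from geometry.  Topology is a
recursive split of the terminal budget with Beta-distributed balance, which
gives direct control over Strahler depth; geometry is stochastic
elongation in the x-y plane (md arbors are quasi-planar) with jittered
headings and, for space-filling classes, occupancy-grid avoidance steering —
a cheap stand-in for the dendritic self-avoidance that tiles the receptive
field.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .recon_io import SIGNAL_COLUMNS, Arbor, node_path_distances, write_swc

# -- specs ------------------------------------------------------------------------


@dataclass
class ArborSpec:
    """Growth parameters for one synthetic arbor class."""

    cell_class: str = "CI"  # label carried into Arbor metadata
    n_terminals: int = 30  # target terminal count (reached exactly)
    n_stems: int = 2  # primary dendrites leaving the soma
    seg_len_mean: float = 12.0  # um, per elongation step
    seg_len_sd: float = 4.0
    segs_per_branch_mean: float = 2.5  # mean segments per unbranched branch
    branch_angle_deg: float = 70.0  # total divergence between daughters
    heading_jitter_deg: float = 18.0  # per-segment heading noise (sd)
    split_balance: float = 2.0  # Beta(a, a) balance of terminal-budget splits
    domain_um: float = 240.0  # side of the square growth domain
    soma_radius: float = 3.0
    stem_radius: float = 1.2
    taper: float = 0.88  # radius decay per branch depth
    radius_min: float = 0.15
    avoidance: bool = False  # occupancy-grid steering (space-filling classes)
    z_jitter_sd: float = 0.0  # optional out-of-plane jitter (um)


@dataclass
class ChannelProfileSpec:
    """Spatial intensity/volume-fraction profile for one channel."""

    channel: str = "MT"
    baseline_I: float = 1.0
    profile: str = "uniform"  # uniform | linear_decay | gaussian_bump
    center_um: float = 100.0  # gaussian_bump center
    width_um: float = 40.0  # gaussian_bump sd
    amplitude: float = 1.0  # gaussian_bump height above baseline
    fraction_F: float = 0.5
    noise_sd: float = 0.0  # additive Gaussian noise on I (and F), clipped


@dataclass
class CohortSpec:
    """A multi-group cohort sharing one arbor class.

    ``groups`` maps a group label to its programmed effects:
    ``mt_ratio`` scales the MT baseline intensity relative to control and
    ``factin_peak_um`` places the F-actin intensity bump.
    """

    groups: dict = field(default_factory=lambda: {"control": {}})
    n_per_group: int = 5
    cell_class: str = "CI"
    arbor_overrides: dict = field(default_factory=dict)
    mt_baseline_I: float = 1.0
    factin_peak_default_um: float = 40.0
    channel_noise_sd: float = 0.05
    include_syn: bool = False
    master_seed: int = 0


def ci_like_spec(**overrides) -> ArborSpec:
    """Preset emulating a sparse Class I md arbor (~30 terminals, 4 orders)."""
    return replace(ArborSpec(), **overrides)


def civ_like_spec(**overrides) -> ArborSpec:
    """Preset emulating a space-filling Class IV md arbor (~400 terminals, 7 orders)."""
    base = ArborSpec(
        cell_class="CIV",
        n_terminals=400,
        n_stems=2,
        seg_len_mean=6.0,
        seg_len_sd=2.0,
        segs_per_branch_mean=4.0,
        branch_angle_deg=80.0,
        heading_jitter_deg=30.0,
        split_balance=5.0,
        domain_um=225.0,
        stem_radius=1.0,
        taper=0.90,
        avoidance=True,
    )
    return replace(base, **overrides)


PRESETS = {
    "ci-control": ci_like_spec,
    "civ-control": civ_like_spec,
}


# -- arbor generation -------------------------------------------------------------


def _split_topology(rng: np.random.Generator, n_leaves: int, a: float):
    """Binary branch topology over a terminal budget; returns nested tuples.

    A leaf is ``None``; an internal node is ``(left, right)``.  The split
    fraction is Beta(a, a): larger ``a`` gives more balanced (deeper-Strahler)
    trees.
    """
    if n_leaves == 1:
        return None
    f = rng.beta(a, a)
    left = min(max(1, int(round(f * n_leaves))), n_leaves - 1)
    return (
        _split_topology(rng, left, a),
        _split_topology(rng, n_leaves - left, a),
    )


class _Grower:
    """Walks a branch topology and lays out segments in the plane."""

    def __init__(self, spec: ArborSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.rows: list[tuple] = []  # (id, code, x, y, z, radius, parent)
        self.half = spec.domain_um / 2.0
        self.cell = 10.0  # occupancy-grid cell size (um)
        self.occ: dict[tuple[int, int], int] = {}

    def add_node(self, code: int, xyz, radius: float, parent: int) -> int:
        nid = len(self.rows) + 1
        self.rows.append(
            (nid, code, float(xyz[0]), float(xyz[1]), float(xyz[2]), radius, parent)
        )
        key = (int(xyz[0] // self.cell), int(xyz[1] // self.cell))
        self.occ[key] = self.occ.get(key, 0) + 1
        return nid

    def _steer(self, pos, heading: float) -> float:
        """Pick the least-crowded of five candidate headings (self-avoidance).

        The score looks one and two steps ahead on the occupancy grid, with a
        small straightness bonus so an uncrowded tip keeps its heading.
        """
        step = self.spec.seg_len_mean
        best, best_score = heading, None
        for dh in (0.0, -0.6, 0.6, -1.2, 1.2):
            h = heading + dh
            u = np.array([np.cos(h), np.sin(h)])
            score = 0.1 * abs(dh)
            for ahead in (1.0, 2.0):
                nxt = pos + ahead * step * u
                key = (int(nxt[0] // self.cell), int(nxt[1] // self.cell))
                score += self.occ.get(key, 0)
            if best_score is None or score < best_score:
                best, best_score = h, score
        return best

    def grow_branch(self, topo, parent_id: int, pos, heading: float, depth: int):
        """Lay out one branch then recurse into its daughters (explicit stack)."""
        stack = [(topo, parent_id, np.asarray(pos, float), heading, depth)]
        spec, rng = self.spec, self.rng
        jit = np.deg2rad(spec.heading_jitter_deg)
        half_angle = np.deg2rad(spec.branch_angle_deg) / 2.0
        while stack:
            topo, parent_id, pos, heading, depth = stack.pop()
            radius = max(spec.radius_min, spec.stem_radius * spec.taper**depth)
            n_seg = 1 + rng.poisson(max(0.0, spec.segs_per_branch_mean - 1.0))
            # terminal branches get one extra elongation step on average
            if topo is None:
                n_seg += rng.integers(0, 2)
            last = parent_id
            for _ in range(n_seg):
                heading = heading + rng.normal(0.0, jit)
                if spec.avoidance:
                    heading = self._steer(pos, heading)
                step = max(1.0, rng.normal(spec.seg_len_mean, spec.seg_len_sd))
                nxt = pos + step * np.array([np.cos(heading), np.sin(heading)])
                out = np.abs(nxt) > self.half
                if out.any():
                    # mirror reflection off the domain boundary, then clamp
                    if out[0]:
                        heading = np.pi - heading
                    if out[1]:
                        heading = -heading
                    nxt = np.clip(nxt, -self.half + 0.5, self.half - 0.5)
                if np.linalg.norm(nxt - pos) < 0.25:
                    break  # clamped into the tip; stop elongating this branch
                z = rng.normal(0.0, spec.z_jitter_sd) if spec.z_jitter_sd > 0 else 0.0
                last = self.add_node(3, (nxt[0], nxt[1], z), radius, last)
                pos = nxt
            if topo is not None:
                left, right = topo
                a1 = heading - half_angle + rng.normal(0.0, jit / 2)
                a2 = heading + half_angle + rng.normal(0.0, jit / 2)
                lx = self.rows[last - 1][2:5]
                stack.append((right, last, np.array(lx[:2]), a2, depth + 1))
                stack.append((left, last, np.array(lx[:2]), a1, depth + 1))


def generate_arbor(spec: ArborSpec, seed: int) -> Arbor:
    """Grow one synthetic arbor; deterministic for a given (spec, seed).

    The soma (structure code 1) roots the tree at the origin; ``n_stems``
    primary dendrites (code 3) leave it at evenly spread headings, and a
    short two-node axon stub (code 2) points between them.
    """
    if spec.n_terminals < spec.n_stems:
        raise ParameterError("terminal target must be >= the number of stems")
    if not 0 < spec.taper <= 1:
        raise ParameterError("taper must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * spec.n_terminals + 100))
    try:
        grower = _Grower(spec, rng)
        root = grower.add_node(1, (0.0, 0.0, 0.0), spec.soma_radius, -1)

        # split the terminal budget across stems (near-even shares)
        budgets = [spec.n_terminals // spec.n_stems] * spec.n_stems
        for i in range(spec.n_terminals % spec.n_stems):
            budgets[i] += 1
        stem_angles = 2 * np.pi * np.arange(spec.n_stems) / spec.n_stems + rng.uniform(
            0, 2 * np.pi / spec.n_stems
        )
        for budget, angle in zip(budgets, stem_angles):
            topo = _split_topology(rng, budget, spec.split_balance)
            grower.grow_branch(topo, root, (0.0, 0.0), float(angle), depth=0)

        # axon stub: two nodes heading between the first two stems
        axon_angle = float(stem_angles[0]) + np.pi / spec.n_stems
        ax_r = max(spec.radius_min, spec.stem_radius * 0.8)
        p = root
        pos = np.zeros(2)
        for _ in range(2):
            step = max(1.0, rng.normal(spec.seg_len_mean, spec.seg_len_sd))
            pos = pos + step * np.array([np.cos(axon_angle), np.sin(axon_angle)])
            p = grower.add_node(2, (pos[0], pos[1], 0.0), ax_r, p)
    finally:
        sys.setrecursionlimit(old_limit)

    nodes = pd.DataFrame(
        grower.rows,
        columns=["node_id", "structure_code", "x", "y", "z", "radius", "parent_id"],
    )
    try:
        return Arbor(
            nodes=nodes,
            metadata={"cell_class": spec.cell_class, "seed": int(seed), "synthetic": True},
        )
    except Exception as exc:  # pragma: no cover - growth always yields a valid tree
        raise GenerationError(f"generated arbor failed validation (seed {seed}): {exc}")


# -- channel fields ---------------------------------------------------------------


def _profile_values(spec: ChannelProfileSpec, dist: np.ndarray) -> np.ndarray:
    if spec.profile == "uniform":
        return np.full_like(dist, spec.baseline_I)
    if spec.profile == "linear_decay":
        dmax = dist.max() if dist.max() > 0 else 1.0
        return spec.baseline_I * np.clip(1.0 - dist / dmax, 0.0, None)
    if spec.profile == "gaussian_bump":
        return spec.baseline_I + spec.amplitude * np.exp(
            -((dist - spec.center_um) ** 2) / (2.0 * spec.width_um**2)
        )
    raise ParameterError(f"unknown channel profile {spec.profile!r}")


def attach_channels(
    arbor: Arbor, profiles: list[ChannelProfileSpec], seed: int
) -> Arbor:
    """Evaluate channel profiles at every node's path distance and attach them.

    Intensities get additive Gaussian noise (sd ``noise_sd``) clipped at 0;
    volume fractions get the same noise clipped to [0, 1].  A bump center
    beyond the arbor extent still generates (with a warning via the tail of
    the Gaussian).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dist = node_path_distances(arbor)
    rows = []
    for spec in profiles:
        base = _profile_values(spec, dist.to_numpy())
        if spec.noise_sd > 0:
            I = np.clip(base + rng.normal(0, spec.noise_sd, len(base)), 0.0, None)
            F = np.clip(
                spec.fraction_F + rng.normal(0, spec.noise_sd, len(base)), 0.0, 1.0
            )
        else:
            I = base
            F = np.full_like(base, spec.fraction_F)
        for nid, i_val, f_val in zip(dist.index, I, F):
            rows.append((int(nid), spec.channel, float(i_val), float(f_val)))
    signals = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    return Arbor(nodes=arbor.nodes.copy(), signals=signals, metadata=dict(arbor.metadata))


# -- photoconversion and comet generators -----------------------------------------


def generate_photoseries(
    lam: float,
    timepoints=(0.0, 30.0, 60.0),
    noise_sd: float = 0.0,
    n_series: int = 1,
    seed: int = 0,
    amplitude: float = 100.0,
    background: float = 20.0,
    channel: str = "tubulin",
) -> list:
    """Exponential-decay photoconversion series with additive detector noise.

    FI_converted(t) = B + A e^(-lam t) + eps;  FI_neighboring(t) = B + eps,
    with eps ~ N(0, noise_sd * A).  Truth (lam, A, B) travels in each series
    id; t = 0 is noise-free so the remaining-fraction denominator is exact.
    """
    from .dynamics import PhotoSeries

    if lam < 0:
        raise ParameterError("decay rate must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.asarray(timepoints, dtype=float)
    out = []
    for k in range(n_series):
        sd = noise_sd * amplitude
        eps_c = rng.normal(0, sd, len(t)) if sd > 0 else np.zeros(len(t))
        eps_n = rng.normal(0, sd, len(t)) if sd > 0 else np.zeros(len(t))
        eps_c[0] = eps_n[0] = 0.0
        fic = background + amplitude * np.exp(-lam * t) + eps_c
        fin = background + eps_n
        out.append(
            PhotoSeries(
                times=t,
                fi_converted=fic,
                fi_neighboring=fin,
                series_id=f"sim_lam{lam:g}_{k}",
                channel=channel,
            )
        )
    return out


def generate_comet_tracks(
    p_retrograde: float,
    n: int,
    speed_mean: float = 0.15,
    speed_sd: float = 0.05,
    length_mean: float = 3.0,
    length_sd: float = 1.0,
    class_mix: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli-direction comet tracks with truncated-normal speeds/lengths."""
    if not 0 <= p_retrograde <= 1:
        raise ParameterError("p_retrograde must lie in [0, 1]")
    if n < 1:
        raise ParameterError("need n >= 1 tracks")
    if class_mix is None:
        class_mix = {"dendrite_primary": 1.0}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    klass = rng.choice(classes, size=n, p=probs)
    retro = rng.random(n) < p_retrograde

    def _trunc_normal(mean, sd, size):
        v = rng.normal(mean, sd, size)
        bad = v <= 0
        while bad.any():
            v[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = v <= 0
        return v

    return pd.DataFrame(
        {
            "track_id": np.arange(1, n + 1),
            "class": klass,
            "direction": np.where(retro, "retrograde", "anterograde"),
            "speed_um_s": _trunc_normal(speed_mean, speed_sd, n),
            "length_um": _trunc_normal(length_mean, length_sd, n),
        }
    )


# -- feature-space cohorts (for embedding tests) ----------------------------------


def generate_feature_cohort(
    group_shifts: dict[str, float],
    n_per_group: int = 12,
    n_features: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian feature matrices with a programmed mean shift per group.

    Each group's features are N(shift, 1) i.i.d., so ``shift`` is the
    separation in within-group standard deviations.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames, labels = [], []
    for g, shift in group_shifts.items():
        X = rng.normal(shift, 1.0, size=(n_per_group, n_features))
        idx = [f"{g}_{i}" for i in range(n_per_group)]
        frames.append(pd.DataFrame(X, index=idx))
        labels.extend([(i, g) for i in idx])
    X = pd.concat(frames)
    X.columns = [f"f{j}" for j in range(n_features)]
    lab = pd.Series(dict(labels), name="group").loc[X.index]
    return X, lab


# -- cohorts on disk --------------------------------------------------------------


def _neuron_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write a multi-group cohort (SWC + channel TSVs) with a manifest and truth.

    Per neuron: an arbor of the cohort's cell class, a uniform MT field
    scaled by the group's ``mt_ratio``, an F-actin Gaussian bump at the
    group's ``factin_peak_um``, and (optionally) SYN/DenMark channels.
    Returns the manifest path; a ``truth.tsv`` beside it records every
    programmed parameter.  Fully reproducible from ``master_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = (
        civ_like_spec(**spec.arbor_overrides)
        if spec.cell_class == "CIV"
        else ci_like_spec(**spec.arbor_overrides)
    )
    manifest_rows, truth_rows = [], []
    index = 0
    for group, effects in spec.groups.items():
        mt_ratio = float(effects.get("mt_ratio", 1.0))
        peak = float(effects.get("factin_peak_um", spec.factin_peak_default_um))
        for k in range(spec.n_per_group):
            ss = _neuron_seed(spec.master_seed, index)
            arbor_seed, chan_seed = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)]
            arbor = generate_arbor(base, arbor_seed)
            profiles = [
                ChannelProfileSpec(
                    channel="MT",
                    baseline_I=spec.mt_baseline_I * mt_ratio,
                    profile="uniform",
                    noise_sd=spec.channel_noise_sd,
                ),
                ChannelProfileSpec(
                    channel="F-actin",
                    baseline_I=0.2,
                    profile="gaussian_bump",
                    center_um=peak,
                    width_um=30.0,
                    amplitude=1.0,
                    noise_sd=spec.channel_noise_sd,
                ),
            ]
            if spec.include_syn:
                profiles.append(
                    ChannelProfileSpec(
                        channel="SYN",
                        baseline_I=0.5,
                        profile="uniform",
                        noise_sd=max(spec.channel_noise_sd, 0.1),
                    )
                )
            arbor = attach_channels(arbor, profiles, chan_seed)
            neuron_id = f"{group}_{k:02d}"
            swc = out_dir / f"{neuron_id}.swc"
            chan = out_dir / f"{neuron_id}.channels.tsv"
            write_swc(arbor, swc, channel_table_path=chan)
            manifest_rows.append(
                {
                    "neuron_id": neuron_id,
                    "swc": swc.name,
                    "channels": chan.name,
                    "group": group,
                    "cell_class": spec.cell_class,
                }
            )
            truth_rows.append(
                {
                    "neuron_id": neuron_id,
                    "group": group,
                    "arbor_seed": arbor_seed,
                    "channel_seed": chan_seed,
                    "mt_ratio": mt_ratio,
                    "factin_peak_um": peak,
                }
            )
            index += 1
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest
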