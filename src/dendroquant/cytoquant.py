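"""Compartment-level cytoskeletal signal quantification.

The quantity of a channel (microtubule, F-actin, or the dendritic marker
DenMark) in a compartment is

    Q_c = I * F * D * L

where ``I`` is the relative signal intensity of the compartment, ``F`` the
fraction of the compartment volume occupied by the signal, ``D`` the
compartment diameter (um) and ``L`` its length (um).  For punctate channels
(Synaptotagmin) the length factor is dropped:

    SYN_i = I * F * D

Node-level signals are averaged onto edges: a compartment's ``I`` and ``F``
are the mean of the values at its two endpoint nodes (one endpoint suffices;
compartments with no signal at either endpoint are excluded and logged).

Cohort normalization divides every per-neuron quantity by the mean total of
the named control group, so the control mean total is exactly 1 and every
mutant group is expressed relative to it.  Profiles along the arbor bin each
compartment's quantity at its midpoint path distance into half-open 40 um
bins by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import NormalizationError, ParameterError
from .morphometry import strahler_orders, total_dendritic_length
from .recon_io import Arbor, compartmentalize

logger = logging.getLogger("dendroquant")


# -- scalar formulas --------------------------------------------------------------


def compartment_quantity(I: float, F: float, D: float, L: float) -> float:
    """Cytoskeletal quantity of one compartment: Q_c = I * F * D * L."""
    _check_if(I, F)
    return I * F * D * L


def denmark_quantity(I: float, F: float, D: float, L: float) -> float:
    """DenMark signal quantity, DEN_c = I * F * D * L (same contract as Q_c)."""
    return compartment_quantity(I, F, D, L)


def syn_intensity(I: float, F: float, D: float) -> float:
    """Length-independent punctate intensity, SYN_i = I * F * D."""
    _check_if(I, F)
    return I * F * D


def _check_if(I: float, F: float) -> None:
    if I < 0:
        raise ParameterError("intensity I must be >= 0")
    if not 0 <= F <= 1:
        raise ParameterError("volume fraction F must lie in [0, 1]")


# -- per-arbor quantification -----------------------------------------------------


def edge_signals(arbor: Arbor, channel: str) -> pd.DataFrame:
    """Edge-level I and F for a channel: mean over the endpoint nodes carrying it.

    Returns a DataFrame indexed by compartment child node_id with columns
    ``I`` and ``F``; compartments lacking the signal at both endpoints are
    omitted (and counted in the log).
    """
    comp = compartmentalize(arbor)
    sig = arbor.signals[arbor.signals["channel"] == channel].set_index("node_id")
    I = sig["intensity_I"]
    F = sig["fraction_F"]
    child_I = I.reindex(comp.index)
    parent_I = I.reindex(comp["parent_id"]).set_axis(comp.index)
    child_F = F.reindex(comp.index)
    parent_F = F.reindex(comp["parent_id"]).set_axis(comp.index)
    eI = pd.concat([child_I, parent_I], axis=1).mean(axis=1, skipna=True)
    eF = pd.concat([child_F, parent_F], axis=1).mean(axis=1, skipna=True)
    out = pd.DataFrame({"I": eI, "F": eF})
    n_missing = int(out["I"].isna().sum())
    if n_missing:
        logger.info(
            "channel %s: %d compartment(s) lack signal at both endpoints; excluded",
            channel,
            n_missing,
        )
    return out.dropna()


def compartment_quantities(arbor: Arbor, channel: str) -> pd.DataFrame:
    """Per-compartment Q_c and SYN_i for one channel.

    Columns: ``structure``, ``length_um``, ``diameter_um``, ``path_mid_um``,
    ``I``, ``F``, ``Q`` (= I F D L) and ``syn_i`` (= I F D), indexed by the
    compartment child node_id.  Compartments without signal are excluded.
    """
    comp = compartmentalize(arbor)
    sig = edge_signals(arbor, channel)
    df = comp.join(sig, how="inner")
    df["Q"] = df["I"] * df["F"] * df["diameter_um"] * df["length_um"]
    df["syn_i"] = df["I"] * df["F"] * df["diameter_um"]
    return df


def total_quantity(arbor: Arbor, channel: str, structure: str = "dendrite") -> float:
    """Total channel quantity over compartments of one structure class."""
    df = compartment_quantities(arbor, channel)
    return float(df.loc[df["structure"] == structure, "Q"].sum())


# -- binned profiles --------------------------------------------------------------


@dataclass
class QuantityProfile:
    """Per-bin summed channel quantity along path distance from the soma."""

    channel: str
    bin_width: float  # um
    values: np.ndarray  # summed quantity per bin, bin k = [k w, (k+1) w)
    neuron_id: str = ""
    group: str = ""
    normalized: bool = False
    normalization_factor: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        """Area-under-curve total: the plain sum of bin values."""
        return float(self.values.sum())

    @property
    def bin_edges(self) -> np.ndarray:
        return self.bin_width * np.arange(len(self.values) + 1)

    @property
    def bin_midpoints(self) -> np.ndarray:
        return self.bin_width * (np.arange(len(self.values)) + 0.5)


def bin_by_path_distance(
    arbor: Arbor,
    channel: str,
    bin_width: float = 40.0,
    structure: str = "dendrite",
    neuron_id: str = "",
    group: str = "",
) -> QuantityProfile:
    """Sum compartment quantities into half-open path-distance bins.

    Each compartment's Q_c is assigned wholly to the bin ``[k w, (k+1) w)``
    containing its midpoint path distance; bins run through the last
    non-empty one.
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be > 0")
    df = compartment_quantities(arbor, channel)
    df = df[df["structure"] == structure]
    idx = np.floor(df["path_mid_um"].to_numpy() / bin_width).astype(int)
    n_bins = int(idx.max()) + 1 if len(idx) else 1
    values = np.bincount(idx, weights=df["Q"].to_numpy(), minlength=n_bins)
    return QuantityProfile(
        channel=channel,
        bin_width=float(bin_width),
        values=values,
        neuron_id=neuron_id,
        group=group,
    )


def normalize_cohort(
    profiles: list[QuantityProfile], control_group: str
) -> tuple[list[QuantityProfile], float]:
    """Normalize a cohort of per-neuron profiles to the control-group mean total.

    The factor is ``1 / mean(control per-neuron totals)``; every profile
    (control and mutant alike) is scaled by it, so the control group's mean
    total becomes exactly 1.  Re-normalizing an already normalized cohort is
    refused.
    """
    if any(p.normalized for p in profiles):
        raise NormalizationError("cohort is already normalized")
    channels = {p.channel for p in profiles}
    if len(channels) != 1:
        raise NormalizationError(f"profiles mix channels: {sorted(channels)}")
    control_totals = [p.total for p in profiles if p.group == control_group]
    if not control_totals:
        raise NormalizationError(f"no profiles in control group {control_group!r}")
    mean_total = float(np.mean(control_totals))
    if mean_total == 0:
        raise NormalizationError("control mean total is zero")
    factor = 1.0 / mean_total
    out = [
        replace(
            p,
            values=p.values * factor,
            normalized=True,
            normalization_factor=factor,
        )
        for p in profiles
    ]
    return out, factor


def peak_intensity_distance(profile: QuantityProfile) -> float:
    """Path distance (um) of the peak bin: the midpoint of the maximal bin.

    Ties resolve toward the soma (smallest distance).
    """
    if len(profile.values) == 0 or profile.values.max() <= 0:
        raise ParameterError("peak undefined: profile is empty or all-zero")
    k = int(np.argmax(profile.values))  # argmax takes the first = most proximal
    return float(profile.bin_midpoints[k])


# -- Strahler stratification ------------------------------------------------------


def quantity_by_strahler(
    arbor: Arbor, channel: str, mode: str = "per_order_length"
) -> pd.DataFrame:
    """Channel quantity stratified by Strahler order.

    Returns one row per order 1..max with columns ``quantity`` (summed Q_c),
    ``order_length_um`` and ``per_length``; ``mode`` selects the
    normalization of ``per_length``:

    - ``per_order_length`` — quantity / summed dendritic length of that order
    - ``per_total_length`` — quantity / total dendritic length of the arbor

    Orders with no compartments report 0.
    """
    if mode not in ("per_order_length", "per_total_length"):
        raise ParameterError(f"unknown Strahler mode {mode!r}")
    orders, _hist = strahler_orders(arbor)
    df = compartment_quantities(arbor, channel)
    df = df[df["structure"] == "dendrite"].join(orders, how="inner")
    comp = compartmentalize(arbor)
    dend = comp[comp["structure"] == "dendrite"]
    length_by_order = dend.join(orders, how="inner").groupby("strahler_order")[
        "length_um"
    ].sum()
    max_order = int(orders.max())
    rows = []
    total_len = total_dendritic_length(arbor)
    for k in range(1, max_order + 1):
        q = float(df.loc[df["strahler_order"] == k, "Q"].sum())
        olen = float(length_by_order.get(k, 0.0))
        denom = olen if mode == "per_order_length" else total_len
        rows.append(
            {
                "order": k,
                "quantity": q,
                "order_length_um": olen,
                "per_length": q / denom if denom > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("order")


# -- Synaptotagmin puncta classification ------------------------------------------


@dataclass
class SynClassification:
    """Top-decile puncta calls over a pooled set of compartments."""

    threshold: float  # SYN_i of the weakest positive compartment
    positive_ids: list  # compartment ids flagged SYN-positive
    p_dendrite: float  # positives among dendritic / total dendritic compartments
    p_axon: float
    n_total: int


def classify_syn_positive(intensities: pd.DataFrame) -> SynClassification:
    """Flag the top 10% of compartments by SYN_i as SYN-positive.

    ``intensities`` has one row per compartment (pooled across the neurons of
    one cell class) with columns ``syn_i``, ``structure`` (dendrite/axon) and
    ``diameter_um``; the index is the compartment id.  Exactly
    ``ceil(0.10 N)`` compartments are flagged; ties are broken by larger
    diameter, then by lower compartment id.  The reported probabilities are
    the fraction of dendritic (axonal) compartments that are positive.
    """
    n = len(intensities)
    if n < 10:
        raise ParameterError(f"need >= 10 pooled compartments, got {n}")
    intensities = intensities.sort_index()  # id order backs the final tie-break
    syn = intensities["syn_i"].to_numpy(dtype=float)
    if (syn == 0).all():
        warnings.warn("all SYN intensities are zero; no positives called")
        return SynClassification(
            threshold=0.0, positive_ids=[], p_dendrite=0.0, p_axon=0.0, n_total=n
        )
    d = intensities["diameter_um"].to_numpy(dtype=float)
    ids = intensities.index.to_numpy()
    # lexsort: last key is primary; row position stands in for the (sorted) id
    rank = np.lexsort((np.arange(n), -d, -syn))
    n_pos = math.ceil(0.10 * n)
    pos = rank[:n_pos]
    positive_ids = [ids[i] for i in pos]
    threshold = float(syn[pos[-1]])
    struct = intensities["structure"].to_numpy()
    pos_mask = np.zeros(n, dtype=bool)
    pos_mask[pos] = True

    def _p(klass: str) -> float:
        in_class = struct == klass
        return float((pos_mask & in_class).sum() / in_class.sum()) if in_class.any() else 0.0

    return SynClassification(
        threshold=threshold,
        positive_ids=positive_ids,
        p_dendrite=_p("dendrite"),
        p_axon=_p("axon"),
        n_total=n,
    )


def pooled_syn_table(arbors: list[Arbor], channel: str = "SYN") -> pd.DataFrame:
    """Pool per-compartment SYN_i rows across neurons for classification.

    The index is (neuron position, compartment child id) so ids stay unique
    across neurons.
    """
    frames = []
    for i, arbor in enumerate(arbors):
        df = compartment_quantities(arbor, channel)
        df = df[df["structure"].isin(["dendrite", "axon"])]
        df = df[["syn_i", "structure", "diameter_um"]].copy()
        df.index = pd.MultiIndex.from_product([[i], df.index], names=["neuron", "child_id"])
        frames.append(df)
    return pd.concat(frames)
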