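"""Cohort-level orchestration: manifest -> morphometry -> quantification -> embedding.

A run consumes a manifest TSV (``neuron_id``, ``swc``, ``channels``,
``group``, ``cell_class``; paths relative to the manifest), computes
per-neuron morphometrics, per-channel normalized quantity profiles,
Strahler-stratified quantities, pooled SYN classification when a SYN channel
is requested, and a seeded 2-D phenotype embedding, writing everything as
TSV into the output directory together with a run log.

Outputs carry no timestamps, so re-running an identical configuration on
identical inputs reproduces every file byte-for-byte.  A failing neuron is
skipped and logged; the run then reports failure but still emits results for
the neurons that succeeded.  Group statistics are limited to mean +/- SEM;
inferential testing is left to downstream tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cytoquant import (
    bin_by_path_distance,
    classify_syn_positive,
    normalize_cohort,
    pooled_syn_table,
    quantity_by_strahler,
)
from .errors import DendroquantError, ParameterError
from .morphometry import morphometry_summary
from .phenotype import assemble_features, embed, feature_table
from .recon_io import read_swc

HEADER = (
    "# dendroquant run output; units um; bins half-open [k w, (k+1) w);"
    " Strahler order 1 = terminal branches\n"
)


@dataclass
class RunConfig:
    """Configuration for one cohort run."""

    manifest: str | Path
    control_group: str
    channels: tuple = ("MT",)
    bin_width: float = 40.0
    sholl_step: float = 10.0
    coverage_box: float = 10.0
    strahler_mode: str = "per_order_length"
    perplexity: float = 5.0
    seed: int = 0
    out_dir: str | Path = "dendroquant_out"
    syn_channel: str = "SYN"


@dataclass
class RunReport:
    """What a run produced, and everything that went wrong along the way."""

    ok: bool
    outputs: dict = field(default_factory=dict)
    warnings_log: list = field(default_factory=list)
    errors_log: list = field(default_factory=list)
    n_neurons: int = 0
    n_failed: int = 0


def _write_tsv(df: pd.DataFrame, path: Path, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER)
        df.to_csv(fh, sep="\t", index=index)


def run_cohort(config: RunConfig) -> RunReport:
    """Execute the full pipeline over a manifest; returns a report bundle."""
    manifest_path = Path(config.manifest)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path, sep="\t", comment="#")
    required = ["neuron_id", "swc", "channels", "group", "cell_class"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ParameterError(f"manifest missing columns: {missing}")
    if config.control_group not in set(manifest["group"]):
        raise ParameterError(
            f"control group {config.control_group!r} absent from manifest"
        )
    report = RunReport(ok=True, n_neurons=len(manifest))
    base = manifest_path.parent

    arbors: dict[str, object] = {}
    groups: dict[str, str] = {}
    summaries: dict[str, dict] = {}
    for row in manifest.itertuples(index=False):
        nid = str(row.neuron_id)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                arbor = read_swc(base / row.swc, base / row.channels)
                summaries[nid] = morphometry_summary(
                    arbor,
                    sholl_step=config.sholl_step,
                    coverage_box=config.coverage_box,
                )
            for w in caught:
                report.warnings_log.append(f"{nid}: {w.message}")
            arbors[nid] = arbor
            groups[nid] = str(row.group)
        except (DendroquantError, OSError) as exc:
            report.errors_log.append(f"{nid}: {type(exc).__name__}: {exc}")
            report.n_failed += 1
            report.ok = False
    if not arbors:
        report.ok = False
        _write_log(report, config, out)
        return report

    morpho_df = pd.DataFrame.from_dict(summaries, orient="index").sort_index()
    morpho_df.insert(0, "group", pd.Series(groups))
    strahler_cols = [c for c in morpho_df.columns if c.startswith("strahler_n")]
    morpho_df[strahler_cols] = morpho_df[strahler_cols].fillna(0.0)
    p = out / "morphometry.tsv"
    _write_tsv(morpho_df, p, index=True)
    report.outputs["morphometry"] = p

    summary_rows = []
    for channel in config.channels:
        profiles = []
        strahler_frames = []
        for nid, arbor in sorted(arbors.items()):
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    prof = bin_by_path_distance(
                        arbor, channel, config.bin_width, neuron_id=nid,
                        group=groups[nid],
                    )
                    sq = quantity_by_strahler(arbor, channel, config.strahler_mode)
                for w in caught:
                    report.warnings_log.append(f"{nid}/{channel}: {w.message}")
            except DendroquantError as exc:
                report.errors_log.append(f"{nid}/{channel}: {exc}")
                report.ok = False
                continue
            profiles.append(prof)
            sq = sq.reset_index()
            sq.insert(0, "group", groups[nid])
            sq.insert(0, "neuron_id", nid)
            strahler_frames.append(sq)
        if not profiles:
            continue
        normed, factor = normalize_cohort(profiles, config.control_group)
        rows = []
        for prof in normed:
            for start, mid, v in zip(
                prof.bin_edges[:-1], prof.bin_midpoints, prof.values
            ):
                rows.append(
                    {
                        "neuron_id": prof.neuron_id,
                        "group": prof.group,
                        "bin_start_um": start,
                        "bin_mid_um": mid,
                        "quantity_norm": v,
                    }
                )
            rows.append(
                {
                    "neuron_id": prof.neuron_id,
                    "group": prof.group,
                    "bin_start_um": -1.0,  # sentinel row: the profile total
                    "bin_mid_um": -1.0,
                    "quantity_norm": prof.total,
                }
            )
        p = out / f"profile_{_safe(channel)}.tsv"
        _write_tsv(pd.DataFrame(rows), p, index=False)
        report.outputs[f"profile_{channel}"] = p
        p = out / f"strahler_{_safe(channel)}.tsv"
        _write_tsv(pd.concat(strahler_frames, ignore_index=True), p, index=False)
        report.outputs[f"strahler_{channel}"] = p

        totals = pd.DataFrame(
            {"group": [pr.group for pr in normed], "total": [pr.total for pr in normed]}
        )
        for g, grp in totals.groupby("group", sort=True):
            v = grp["total"].to_numpy()
            summary_rows.append(
                {
                    "channel": channel,
                    "group": g,
                    "n": len(v),
                    "mean_total_norm": float(v.mean()),
                    "sem_total_norm": float(v.std(ddof=1) / np.sqrt(len(v)))
                    if len(v) > 1
                    else np.nan,
                    "normalization_factor": factor,
                }
            )
    if summary_rows:
        p = out / "group_summary.tsv"
        _write_tsv(pd.DataFrame(summary_rows), p, index=False)
        report.outputs["group_summary"] = p

    # pooled SYN classification per cell class, when requested and present
    if config.syn_channel in config.channels:
        syn_rows = []
        classes = manifest.set_index("neuron_id")["cell_class"].astype(str).to_dict()
        for cc in sorted(set(classes.values())):
            members = [a for n, a in sorted(arbors.items()) if classes[str(n)] == cc]
            try:
                pooled = pooled_syn_table(members, channel=config.syn_channel)
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    cls = classify_syn_positive(pooled)
                for w in caught:
                    report.warnings_log.append(f"SYN/{cc}: {w.message}")
            except DendroquantError as exc:
                report.errors_log.append(f"SYN/{cc}: {exc}")
                report.ok = False
                continue
            syn_rows.append(
                {
                    "cell_class": cc,
                    "n_compartments": cls.n_total,
                    "n_positive": len(cls.positive_ids),
                    "threshold_syn_i": cls.threshold,
                    "p_dendrite": cls.p_dendrite,
                    "p_axon": cls.p_axon,
                }
            )
        if syn_rows:
            p = out / "syn_classification.tsv"
            _write_tsv(pd.DataFrame(syn_rows), p, index=False)
            report.outputs["syn_classification"] = p

    # phenotype embedding over the morphometric features
    try:
        features, labels = feature_table(summaries, groups)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            X = assemble_features(features)
            emb = embed(X, perplexity=config.perplexity, seed=config.seed, labels=labels)
        for w in caught:
            report.warnings_log.append(f"embedding: {w.message}")
        coords = emb.coordinates.copy()
        coords.insert(0, "group", labels)
        coords["silhouette"] = emb.silhouette
        p = out / "embedding.tsv"
        _write_tsv(coords.sort_index(), p, index=True)
        report.outputs["embedding"] = p
    except DendroquantError as exc:
        report.warnings_log.append(f"embedding skipped: {exc}")

    _write_log(report, config, out)
    return report


def _safe(channel: str) -> str:
    return channel.replace("/", "_").replace(" ", "_")


def _write_log(report: RunReport, config: RunConfig, out: Path) -> None:
    p = out / "run_log.txt"
    with open(p, "w") as fh:
        fh.write(f"dendroquant {__version__}\n")
        # paths are host-specific; log only the analysis-relevant settings
        fh.write(
            "config: "
            f"control_group={config.control_group} channels={config.channels} "
            f"bin_width={config.bin_width} sholl_step={config.sholl_step} "
            f"coverage_box={config.coverage_box} strahler_mode={config.strahler_mode} "
            f"perplexity={config.perplexity} seed={config.seed}\n"
        )
        fh.write(f"neurons: {report.n_neurons}, failed: {report.n_failed}\n")
        fh.write(f"warnings ({len(report.warnings_log)}):\n")
        for w in report.warnings_log:
            fh.write(f"  {w}\n")
        fh.write(f"errors ({len(report.errors_log)}):\n")
        for e in report.errors_log:
            fh.write(f"  {e}\n")
    report.outputs["run_log"] = p
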