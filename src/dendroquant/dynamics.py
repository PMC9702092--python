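"""Time-resolved cytoskeletal dynamics: photoconversion turnover and comet tracks.

Photoconversion (e.g. tdEOS-tagged tubulin or LifeAct) irreversibly switches
a region's fluorophore; the persistence of the converted signal reports
polymer turnover.  The remaining fraction at each timepoint is

    f_t = (FI_converted(t) - FI_neighboring(t)) / (FI_converted(0) - FI_neighboring(0))

where the neighboring non-converted region supplies the background.  A
single-exponential decay rate summarizes each series (percent lost at the
imaged timepoints is emitted alongside).

EB1 comet tables carry one row per plus-end track with a neurite class, a
direction relative to the cell body (anterograde = away from the soma),
speed (um/s) and track length (um); summaries are stratified by class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FitError, ParameterError, ValidationError

logger = logging.getLogger("dendroquant")

NEURITE_CLASSES = ("dendrite_primary", "dendrite_higher_order", "axon")
DIRECTIONS = ("anterograde", "retrograde")


# -- photoconversion --------------------------------------------------------------


@dataclass
class PhotoSeries:
    """One photoconversion time course (times in minutes, first entry 0)."""

    times: np.ndarray
    fi_converted: np.ndarray
    fi_neighboring: np.ndarray
    series_id: str = ""
    channel: str = "tubulin"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fi_converted = np.asarray(self.fi_converted, dtype=float)
        self.fi_neighboring = np.asarray(self.fi_neighboring, dtype=float)
        if len(self.times) == 0 or self.times[0] != 0:
            raise ValidationError("times must start at 0")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if len(self.fi_converted) != len(self.times) or len(
            self.fi_neighboring
        ) != len(self.times):
            raise ValidationError("intensity vectors must match the time vector")
        if self.fi_converted[0] <= self.fi_neighboring[0]:
            raise ValidationError(
                "converted-region intensity at t=0 must exceed the neighboring region"
            )


@dataclass
class TurnoverResult:
    """Remaining fractions and percent lost for one photoconversion series."""

    times: np.ndarray  # minutes
    remaining_fraction: np.ndarray  # f_0 = 1 exactly
    series_id: str = ""
    channel: str = ""

    @property
    def percent_lost(self) -> np.ndarray:
        return 100.0 * (1.0 - self.remaining_fraction)


def remaining_fraction(series: PhotoSeries) -> TurnoverResult:
    """Background-subtracted remaining fraction at each timepoint.

    Fractions above 1 or below 0 are reported as-is with a warning (the
    background exceeded the signal, or the detector drifted upward).
    """
    denom = series.fi_converted[0] - series.fi_neighboring[0]
    if denom == 0:
        raise ParameterError("degenerate series: zero converted signal at t=0")
    frac = (series.fi_converted - series.fi_neighboring) / denom
    if (frac < 0).any():
        warnings.warn("negative remaining fraction(s): background exceeded signal")
    if (frac[1:] > 1).any():
        warnings.warn("remaining fraction(s) above 1 at later timepoints")
    return TurnoverResult(
        times=series.times.copy(),
        remaining_fraction=frac,
        series_id=series.series_id,
        channel=series.channel,
    )


@dataclass
class TurnoverFit:
    """One-parameter exponential summary f(t) = exp(-lambda t)."""

    rate_per_min: float
    residual_rms: float  # RMS of log-residuals over the fitted points
    n_used: int


def fit_turnover_rate(result: TurnoverResult) -> TurnoverFit:
    """Least-squares fit of log(fraction) against time through the origin.

    Non-positive fractions are excluded with a warning; at least two usable
    points (beyond t = 0 the origin constraint makes t = 0 uninformative but
    harmless) are required.  The returned rate is clipped at 0 when the
    fractions trend upward.
    """
    if len(result.times) < 3:
        raise FitError("need at least 3 timepoints to fit a decay rate")
    t = result.times
    f = result.remaining_fraction
    usable = f > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} non-positive fraction(s) excluded from the fit"
        )
    t, f = t[usable], f[usable]
    if len(t) < 2:
        raise FitError("fewer than 2 usable points after excluding non-positive fractions")
    y = np.log(f)
    denom = float(np.sum(t * t))
    if denom == 0:
        raise FitError("no informative (t > 0) points to fit")
    slope = float(np.sum(t * y)) / denom
    lam = -slope
    if lam < 0:
        logger.info("fitted decay rate was negative (%.3g); clipping to 0", lam)
        lam = 0.0
    resid = y + lam * t
    return TurnoverFit(
        rate_per_min=lam,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_used=int(len(t)),
    )


def read_photoseries_tsv(path: str | Path) -> list[PhotoSeries]:
    """Read a TSV (time_min, FI_converted, FI_neighboring, series_id, channel)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["time_min", "FI_converted", "FI_neighboring", "series_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"photoseries table missing columns: {missing}")
    if "channel" not in df.columns:
        df["channel"] = "tubulin"
    out = []
    for (sid, chan), grp in df.groupby(["series_id", "channel"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            PhotoSeries(
                times=grp["time_min"].to_numpy(),
                fi_converted=grp["FI_converted"].to_numpy(),
                fi_neighboring=grp["FI_neighboring"].to_numpy(),
                series_id=str(sid),
                channel=str(chan),
            )
        )
    return out


def turnover_table(series_list: list[PhotoSeries]) -> pd.DataFrame:
    """Long-format per-series turnover: fractions, percent lost, fitted rate."""
    rows = []
    for s in series_list:
        res = remaining_fraction(s)
        try:
            fit = fit_turnover_rate(res)
            rate = fit.rate_per_min
        except FitError:
            rate = np.nan
        for t, f, pl in zip(res.times, res.remaining_fraction, res.percent_lost):
            rows.append(
                {
                    "series_id": s.series_id,
                    "channel": s.channel,
                    "time_min": t,
                    "remaining_fraction": f,
                    "percent_lost": pl,
                    "rate_per_min": rate,
                }
            )
    return pd.DataFrame(rows)


# -- EB1 comet tracks -------------------------------------------------------------


def read_comet_tsv(path: str | Path) -> pd.DataFrame:
    """Read a comet track TSV (track_id, class, direction, speed_um_s, length_um)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["track_id", "class", "direction", "speed_um_s", "length_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"comet table missing columns: {missing}")
    return df


def comet_summary(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-neurite-class comet statistics.

    Returns one row per class present with the comet count, the percentage
    moving anterograde/retrograde (summing to 100), and mean +/- SEM of speed
    and track length (SEM with the n-1 denominator; NaN for a single track).
    Tracks with unknown class or direction labels are rejected with a warning.
    """
    ok_class = tracks["class"].isin(NEURITE_CLASSES)
    ok_dir = tracks["direction"].isin(DIRECTIONS)
    bad = ~(ok_class & ok_dir)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} track(s) with unknown class/direction rejected")
        tracks = tracks[~bad]
    if len(tracks) == 0:
        raise ParameterError("no valid comet tracks")
    rows = []
    for klass, grp in tracks.groupby("class", sort=True):
        n = len(grp)
        n_retro = int((grp["direction"] == "retrograde").sum())
        speed = grp["speed_um_s"].to_numpy(dtype=float)
        length = grp["length_um"].to_numpy(dtype=float)
        sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        rows.append(
            {
                "class": klass,
                "n_comets": n,
                "pct_retrograde": 100.0 * n_retro / n,
                "pct_anterograde": 100.0 * (n - n_retro) / n,
                "speed_mean_um_s": float(speed.mean()),
                "speed_sem_um_s": sem(speed),
                "length_mean_um": float(length.mean()),
                "length_sem_um": sem(length),
            }
        )
    return pd.DataFrame(rows).set_index("class")
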