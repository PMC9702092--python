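"""Phenotype-space embedding of per-neuron morphometric feature vectors.

Feature vectors (total length, branch counts, branch density, field
coverage, Strahler-order counts, Sholl peak statistics) are z-scored per
column and embedded in two dimensions with t-SNE under a fixed seed; a
silhouette score over the genotype/group labels quantifies the separation
that the embedding plots show qualitatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .errors import ParameterError


def assemble_features(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score a neurons x features matrix per column.

    ``features`` has one row per neuron (index = neuron id) and only numeric
    feature columns.  Constant columns carry no phenotype information and are
    dropped with a warning; missing values are a build error because every
    neuron must contribute the same feature set.
    """
    if len(features) < 2:
        raise ParameterError("need at least 2 neurons to assemble a feature matrix")
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise ParameterError(f"missing feature value(s) in columns: {bad}")
    X = features.astype(float)
    sd = X.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature column(s): {constant}")
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    if X.shape[1] == 0:
        warnings.warn("all feature columns were constant; matrix is empty")
        return X
    return (X - X.mean(axis=0)) / sd


def feature_table(
    summaries: dict[str, dict[str, float]], groups: dict[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Build an aligned feature matrix from per-neuron morphometry summaries.

    Neurons may reach different maximal Strahler orders, so order-count
    columns absent from a neuron are filled with 0 (the neuron has no branch
    of that order); any other missing feature is an error downstream.
    """
    df = pd.DataFrame.from_dict(summaries, orient="index")
    strahler_cols = [c for c in df.columns if c.startswith("strahler_n")]
    df[strahler_cols] = df[strahler_cols].fillna(0.0)
    labels = pd.Series(groups).loc[df.index]
    labels.name = "group"
    return df, labels


@dataclass
class EmbeddingResult:
    """A seeded 2-D embedding with its cluster-separation diagnostic."""

    coordinates: pd.DataFrame  # columns tsne1, tsne2, index = neuron id
    perplexity: float
    seed: int
    silhouette: float | None  # None when labels are absent or degenerate


def embed(
    matrix: pd.DataFrame,
    perplexity: float = 5.0,
    seed: int = 0,
    labels: pd.Series | None = None,
) -> EmbeddingResult:
    """Deterministic t-SNE of a z-scored feature matrix.

    ``perplexity`` must be below ``(n - 1) / 3``; runs with the same matrix,
    perplexity, seed and library version reproduce coordinates bit-for-bit.
    When group ``labels`` are supplied (>= 2 groups) the silhouette score of
    the embedding under those labels is reported.
    """
    n = len(matrix)
    if n < 4:
        raise ParameterError("need at least 4 neurons to embed")
    max_perp = (n - 1) / 3
    if perplexity >= max_perp:
        raise ParameterError(
            f"perplexity {perplexity} too large for n={n}; use a value < {max_perp:.1f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        learning_rate="auto",
        random_state=seed,
    )
    coords = tsne.fit_transform(matrix.to_numpy(dtype=float))
    cdf = pd.DataFrame(coords, index=matrix.index, columns=["tsne1", "tsne2"])
    sil = None
    if labels is not None:
        labels = labels.loc[matrix.index]
        if labels.nunique() >= 2:
            sil = float(silhouette_score(coords, labels.to_numpy()))
    return EmbeddingResult(
        coordinates=cdf, perplexity=float(perplexity), seed=int(seed), silhouette=sil
    )
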