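"""Trait standardization, species trait distances and mixture-level trait
summaries.

Leaf-trait variability of a mixture is the mean Euclidean distance between
its species pairs in z-scored trait space; mixture trait means are
mass-weighted averages of the member species' traits.  The z-scoring
convention (sample vs population SD) is configurable and documented rather
than claimed to reproduce any particular software's clustering output.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .records import (
    Composition,
    ConfigurationError,
    DataError,
    TraitTable,
    ValidationError,
)

__all__ = [
    "TraitStandardizer",
    "standardize_traits",
    "pairwise_trait_distance",
    "mean_trait_distance",
    "weighted_mixture_traits",
    "mixture_trait_table",
]


class TraitStandardizer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring of a species x trait matrix.

    Parameters
    ----------
    scale_convention : {"sample_sd", "population_sd"}
        Denominator of the z-score: SD with ddof=1 (default) or ddof=0.

    Attributes
    ----------
    center_ : Series, per-trait mean
    scale_ : Series, per-trait SD under the chosen convention
    """

    def __init__(self, scale_convention: str = "sample_sd"):
        self.scale_convention = scale_convention

    def _frame(self, traits: TraitTable | pd.DataFrame) -> pd.DataFrame:
        return traits.frame if isinstance(traits, TraitTable) else traits.astype(float)

    def fit(self, X: TraitTable | pd.DataFrame, y=None) -> "TraitStandardizer":
        if self.scale_convention not in ("sample_sd", "population_sd"):
            raise ConfigurationError(
                f"unknown scale convention {self.scale_convention!r}"
            )
        frame = self._frame(X)
        if len(frame) < 2:
            raise ValidationError("standardization needs at least two species")
        ddof = 1 if self.scale_convention == "sample_sd" else 0
        center = frame.mean(axis=0)
        scale = frame.std(axis=0, ddof=ddof)
        degenerate = scale[scale <= 0].index.tolist()
        if degenerate:
            raise ValidationError(f"zero spread in trait(s): {degenerate}")
        self.center_ = center
        self.scale_ = scale
        return self

    def transform(self, X: TraitTable | pd.DataFrame) -> pd.DataFrame:
        frame = self._frame(X)
        return (frame - self.center_) / self.scale_


def standardize_traits(
    traits: TraitTable | pd.DataFrame, scale_convention: str = "sample_sd"
) -> pd.DataFrame:
    """z-score each trait across species; returns the z-matrix."""
    return TraitStandardizer(scale_convention).fit_transform(traits)


def pairwise_trait_distance(z: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between species rows of a z-scored trait matrix.

    Returns a symmetric, zero-diagonal square DataFrame.  A single species
    yields an empty matrix with a warning.
    """
    if len(z) < 2:
        warnings.warn("fewer than two species: empty distance matrix", stacklevel=2)
        return pd.DataFrame(index=z.index, columns=z.index, dtype=float)
    d = squareform(pdist(z.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=z.index, columns=z.index)


def mean_trait_distance(dist: pd.DataFrame, mixture: Composition | Sequence[str]) -> float:
    """Mean pairwise distance over the C(N, 2) species pairs of a mixture."""
    species = mixture.species if isinstance(mixture, Composition) else tuple(mixture)
    if len(species) < 2:
        raise ValidationError("trait variability undefined for fewer than two species")
    missing = [s for s in species if s not in dist.index]
    if missing:
        raise DataError(f"species missing from distance matrix: {missing}")
    pairs = list(itertools.combinations(species, 2))
    return float(np.mean([dist.loc[i, j] for i, j in pairs]))


def weighted_mixture_traits(
    traits: TraitTable | pd.DataFrame,
    mixture: Composition | Sequence[str],
    weights: Mapping[str, float],
) -> pd.Series:
    """Mass-weighted mean trait values of a mixture: sum(w_i x_i)/sum(w_i).

    ``weights`` are typically the per-species corrected initial AFDM of the
    mixture; the result is invariant to rescaling all weights.
    """
    frame = traits.frame if isinstance(traits, TraitTable) else traits
    species = mixture.species if isinstance(mixture, Composition) else tuple(mixture)
    missing = [s for s in species if s not in weights]
    if missing:
        raise ConfigurationError(f"missing weight for species: {missing}")
    w = np.array([float(weights[s]) for s in species])
    if np.any(w <= 0):
        raise ConfigurationError("weights must be positive")
    sub = frame.loc[list(species)]
    return pd.Series(
        (sub.to_numpy(dtype=float) * w[:, None]).sum(axis=0) / w.sum(),
        index=sub.columns,
    )


def mixture_trait_table(
    traits: TraitTable,
    mixtures: Sequence[Composition | str],
    weights: Mapping[str, Mapping[str, float]] | None = None,
    scale_convention: str = "sample_sd",
) -> pd.DataFrame:
    """Weighted trait means plus trait variability for a set of mixtures.

    ``weights`` maps mixture label -> per-species weight; when omitted,
    species are weighted equally.  Trait distances are computed on the full
    trait table z-scored across all its species.
    """
    z = standardize_traits(traits, scale_convention)
    dist = pairwise_trait_distance(z)
    rows = []
    for mx in mixtures:
        comp = mx if isinstance(mx, Composition) else Composition.parse(mx)
        if weights is not None and comp.label in weights:
            w = dict(weights[comp.label])
        else:
            w = {s: 1.0 for s in comp.species}
        row = weighted_mixture_traits(traits, comp, w).to_dict()
        row["mixture"] = comp.label
        row["richness"] = comp.richness
        row["mean_trait_distance"] = (
            mean_trait_distance(dist, comp) if comp.richness >= 2 else np.nan
        )
        rows.append(row)
    cols = ["mixture", "richness", *traits.frame.columns, "mean_trait_distance"]
    return pd.DataFrame(rows)[cols]
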