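"""Distributional feature extraction per gene × individual.

Instead of collapsing each individual's cells to a single pseudo-bulk value,
three summaries of the within-individual expression distribution are taken
per gene by default:

``zero_prop``
    fraction of the individual's cells with zero expression,
``nonzero_mean``
    mean of the non-zero normalized values,
``nonzero_sd``
    sample standard deviation (n − 1 denominator) of the non-zero values.

Each summary is then transformed to a scale where a linear model is
reasonable: a logit capped at ±7 for the zero proportion (with the cap taken
exactly at proportions 0 and 1), and a power transform w**rho with rho = 0.5
for the mean and SD of the non-zero part.

Additional features can be registered at run time with
:func:`register_feature`; the omnibus test downstream automatically covers
every registered feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import NormalizedMatrix
from .exceptions import ValidationError

__all__ = [
    "DEFAULT_FEATURE_NAMES",
    "FeatureArray",
    "extract_features",
    "transform_features",
    "register_feature",
    "unregister_feature",
    "reset_features",
    "registered_feature_names",
    "logit_capped",
]

DEFAULT_FEATURE_NAMES = ("zero_prop", "nonzero_mean", "nonzero_sd")

# custom features: name -> (extractor over one individual's value vector,
#                           scalar transformer)
_CUSTOM: dict[str, tuple[Callable, Callable]] = {}


def register_feature(
    name: str,
    extractor: Callable[[np.ndarray], float],
    transformer: Callable[[float], float],
) -> None:
    """Add a feature computed from each individual's vector of normalized
    values (zeros included).

    The extractor maps a 1-D float array to a scalar; the transformer maps
    the raw feature value to the scale used in the linear model.  Subsequent
    :func:`extract_features` / :func:`transform_features` calls include the
    feature and the omnibus F covers it.
    """
    if name in DEFAULT_FEATURE_NAMES or name in _CUSTOM:
        raise ValidationError(f"feature {name!r} already registered")
    _CUSTOM[name] = (extractor, transformer)


def unregister_feature(name: str) -> None:
    if name in DEFAULT_FEATURE_NAMES:
        raise ValidationError(f"cannot remove built-in feature {name!r}")
    _CUSTOM.pop(name, None)


def reset_features() -> None:
    """Remove all custom features, restoring the three defaults."""
    _CUSTOM.clear()


def registered_feature_names() -> list[str]:
    return list(DEFAULT_FEATURE_NAMES) + list(_CUSTOM)


@dataclass
class FeatureArray:
    """Raw (W) and transformed (U) features, genes × individuals × K."""

    W: np.ndarray
    feature_names: list[str]
    gene_ids: np.ndarray
    individuals: np.ndarray
    U: np.ndarray | None = None
    rho: float | None = None
    cap: float | None = None

    @property
    def K(self) -> int:
        return self.W.shape[2]

    def to_long_frame(self, which: str = "W") -> pd.DataFrame:
        """Long-format table (gene, individual, feature, value) for export."""
        arr = self.W if which == "W" else self.U
        if arr is None:
            raise ValidationError("U not filled; call transform_features first")
        m, n, k = arr.shape
        return pd.DataFrame(
            {
                "gene": np.repeat(self.gene_ids, n * k),
                "individual": np.tile(np.repeat(self.individuals, k), m),
                "feature": np.tile(self.feature_names, m * n),
                "value": arr.ravel(),
            }
        )


def _group_indicator(nm: NormalizedMatrix) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    individuals = nm.individuals
    idx = {str(v): j for j, v in enumerate(individuals)}
    cols = np.array([idx[str(v)] for v in nm.individual_of_cell])
    c = len(cols)
    g = sp.csr_matrix(
        (np.ones(c), (np.arange(c), cols)), shape=(c, len(individuals))
    )
    cj = np.asarray(g.sum(axis=0)).ravel()
    return g, cj, individuals


def extract_features(nm: NormalizedMatrix) -> FeatureArray:
    """Compute W[i, j, k] for every gene i, individual j and feature k.

    Degenerate individuals are imputed rather than NaN'd: an all-zero
    individual gets (1, 0, 0), and an individual with a single non-zero cell
    gets SD 0.  Both policies can be overridden by registering replacement
    features.
    """
    g, cj, individuals = _group_indicator(nm)
    if (cj < 1).any():
        raise ValidationError("every individual needs at least one cell")
    x = nm.values
    s1 = np.asarray((x @ g).todense())
    s2 = np.asarray((x.multiply(x) @ g).todense())
    ones = x.copy()
    ones.data = np.ones_like(ones.data)
    nnz = np.asarray((ones @ g).todense())

    zero_prop = (cj[None, :] - nnz) / cj[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(nnz > 0, s1 / np.maximum(nnz, 1), 0.0)
        var = np.where(
            nnz >= 2,
            (s2 - nnz * mean**2) / np.maximum(nnz - 1, 1),
            0.0,
        )
    sd = np.sqrt(np.clip(var, 0.0, None))

    slabs = [zero_prop, mean, sd]
    names = list(DEFAULT_FEATURE_NAMES)

    if _CUSTOM:
        dense = np.asarray(x.todense())
        slices = nm.individual_slices()
        for name, (extractor, _) in _CUSTOM.items():
            slab = np.empty_like(zero_prop)
            for j, ind in enumerate(individuals):
                block = dense[:, slices[str(ind)]]
                for i in range(block.shape[0]):
                    slab[i, j] = extractor(block[i])
            slabs.append(slab)
            names.append(name)

    w = np.stack(slabs, axis=2)
    if np.isnan(w).any():
        raise ValidationError("feature extraction produced NaN")
    return FeatureArray(w, names, nm.gene_ids, individuals)


def logit_capped(w: np.ndarray, cap: float = 7.0) -> np.ndarray:
    """Capped logit: log(w / (1 − w)) clamped to ±cap, exact at w ∈ {0, 1}."""
    w = np.asarray(w, dtype=float)
    out = np.full(w.shape, np.nan)
    interior = (w > 0) & (w < 1)
    with np.errstate(divide="ignore"):
        out[interior] = np.log(w[interior] / (1.0 - w[interior]))
    out[w <= 0] = -cap
    out[w >= 1] = cap
    return np.clip(out, -cap, cap)


def transform_features(
    fa: FeatureArray, rho: float = 0.5, cap: float = 7.0
) -> FeatureArray:
    """Fill U from W: capped logit for zero_prop, w**rho for the non-zero
    mean and SD, and the registered transformer for custom features."""
    if rho <= 0:
        raise ValidationError("power-transform exponent rho must be positive")
    u = np.empty_like(fa.W)
    for k, name in enumerate(fa.feature_names):
        w = fa.W[:, :, k]
        if name == "zero_prop":
            u[:, :, k] = logit_capped(w, cap)
        elif name in ("nonzero_mean", "nonzero_sd"):
            u[:, :, k] = np.power(w, rho)
        else:
            _, transformer = _CUSTOM[name]
            u[:, :, k] = np.vectorize(transformer, otypes=[float])(w)
    if np.isnan(u).any():
        raise ValidationError("feature transform produced NaN")
    fa.U = u
    fa.rho = rho
    fa.cap = cap
    return fa
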