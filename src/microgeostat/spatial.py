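"""Mantel correlograms: per-distance-class permutation tests of autocorrelation.

For each geographic distance class the statistic is the (negated) Pearson
correlation between the class-membership indicator and the attribute
dissimilarity, taken over the lower triangles of the two matrices.  The
negation makes the sign readable as autocorrelation: values that are
*similar* at short range give a *positive* statistic in near classes (the
vegan/ncf plotting convention).  Significance is a two-sided permutation
test that shuffles rows and columns of the attribute-dissimilarity matrix
simultaneously; p = (exceedances + 1) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .transect import _coords_array

__all__ = ["MantelCorrelogram", "mantel_correlogram", "mantel_statistic"]


@dataclass
class MantelCorrelogram:
    """Per-class Mantel statistics with permutation p-values."""

    table: pd.DataFrame  # class_lower, class_upper, n_pairs, statistic, p_value
    n_permutations: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MantelCorrelogram {len(self.table)} classes, "
                f"{self.n_permutations} permutations>")


def _value_dissimilarity(values, n: int) -> np.ndarray:
    """Condensed Euclidean dissimilarity from a vector, or pass a matrix through."""
    arr = np.asarray(values, float)
    if arr.ndim == 1:
        if len(arr) != n:
            raise ValueError("value vector length does not match sample count")
        return pdist(arr[:, None])
    if arr.shape == (n, n):
        if not np.allclose(arr, arr.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        return squareform(arr, checks=False)
    raise ValueError("values must be a length-n vector or an n x n matrix")


def mantel_statistic(indicator: np.ndarray, dvec: np.ndarray) -> float:
    """Negated Pearson correlation between two condensed (pair) vectors."""
    m = indicator - indicator.mean()
    v = dvec - dvec.mean()
    denom = np.sqrt((m ** 2).sum() * (v ** 2).sum())
    if denom == 0:
        return np.nan
    return float(-(m * v).sum() / denom)


def mantel_correlogram(values, samples, n_classes: int = 6,
                       n_perm: int = 1000, seed: int | None = None,
                       max_lag: float | None = None) -> MantelCorrelogram:
    """Mantel autocorrelogram of one attribute over geographic distance classes.

    Parameters
    ----------
    values
        Attribute vector (Euclidean dissimilarity is taken) or a precomputed
        symmetric dissimilarity matrix.
    samples
        Metadata frame or (n, 2) coordinate array.
    n_classes
        Number of equal-width geographic distance classes up to ``max_lag``
        (default: the maximum pairwise distance, so classes are exhaustive).
    n_perm
        Number of permutations (>= 99); p-values are
        (exceedances + 1)/(n_perm + 1), two-sided on |statistic|.
    seed
        Seed for the permutation stream (required for reproducibility).
    """
    coords, _ = _coords_array(samples)
    n = len(coords)
    if n < 5:
        raise ValueError("need at least 5 samples")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    dgeo = pdist(coords)
    dval = _value_dissimilarity(values, n)
    if max_lag is None:
        max_lag = float(dgeo.max())
    edges = np.linspace(0.0, max_lag, n_classes + 1)
    class_idx = np.clip(np.searchsorted(edges, dgeo, side="left") - 1,
                        0, n_classes - 1)
    class_idx[dgeo > max_lag] = -1

    indicators, kept = [], []
    for k in range(n_classes):
        ind = (class_idx == k).astype(float)
        if ind.sum() == 0:
            warnings.warn(f"distance class {k} has no pairs; dropped")
            continue
        indicators.append(ind)
        kept.append(k)
    if not indicators:
        raise ValueError("no distance class contains any pair")
    M = np.column_stack(indicators)            # (n_pairs, n_classes_kept)
    Mc = M - M.mean(axis=0)
    m_norm = np.sqrt((Mc ** 2).sum(axis=0))

    def stats_for(vec: np.ndarray) -> np.ndarray:
        v = vec - vec.mean()
        denom = m_norm * np.sqrt((v ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return -(Mc.T @ v) / denom

    obs = stats_for(dval)

    # permutations: shuffle sample labels of the value-dissimilarity matrix
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    flat = squareform(dval, checks=False).ravel()
    perm_stats = np.empty((n_perm, len(kept)))
    for t in range(n_perm):
        p = rng.permutation(n)
        idx = np.minimum(p[iu[0]], p[iu[1]]) * n + np.maximum(p[iu[0]], p[iu[1]])
        perm_stats[t] = stats_for(flat[idx])

    with np.errstate(invalid="ignore"):
        exceed = (np.abs(perm_stats) >= np.abs(obs)[None, :]).sum(axis=0)
    pvals = (exceed + 1) / (n_perm + 1)

    table = pd.DataFrame({
        "class_lower": edges[kept],
        "class_upper": edges[np.asarray(kept) + 1],
        "n_pairs": M.sum(axis=0).astype(int),
        "statistic": obs,
        "p_value": pvals,
    })
    return MantelCorrelogram(table=table, n_permutations=n_perm)
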