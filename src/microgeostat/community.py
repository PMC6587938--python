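"""Taxa-environment association: Spearman tables, collinearity screening, BIOENV.

``spearman_matrix`` produces the long-format correlation table behind the
usual taxa-vs-soil heatmaps, with two significance tiers (p < 0.05,
p < 0.01).  ``collinearity_filter`` greedily prunes highly correlated
environmental variables.  ``bioenv`` is the exhaustive best-subset search:
for every subset of (internally standardized) environmental variables it
rank-correlates the Euclidean inter-sample distances on that subset with
the community dissimilarities and reports the best subset per size and
overall.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .otu import OtuTable, relative_abundance

__all__ = [
    "spearman_matrix",
    "collinearity_filter",
    "bioenv",
    "BioenvResult",
]


def _tier(p: float, alpha_tiers=(0.05, 0.01)) -> str:
    loose, strict = max(alpha_tiers), min(alpha_tiers)
    if not np.isfinite(p):
        return "ns"
    if p < strict:
        return "highly significant"
    if p < loose:
        return "significant"
    return "ns"


def spearman_matrix(abundances: pd.DataFrame, env: pd.DataFrame,
                    alpha_tiers=(0.05, 0.01)) -> pd.DataFrame:
    """Spearman correlations of each taxon against each soil variable.

    Parameters
    ----------
    abundances
        Taxa × samples proportion (or abundance) frame.
    env
        Samples × variables frame; the shared samples (>= 4) are used.

    Returns a long frame with columns ``taxon, variable, r, p, tier, sign``;
    constant vectors yield ``r = NaN`` and tier ``ns``.
    """
    shared = abundances.columns.intersection(env.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    ab = abundances[shared]
    ev = env.loc[shared]
    rows = []
    for taxon, tvec in ab.iterrows():
        x = tvec.to_numpy(float)
        for var in ev.columns:
            y = ev[var].to_numpy(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rows.append({
                "taxon": taxon, "variable": var, "r": r, "p": p,
                "tier": _tier(p, alpha_tiers),
                "sign": "+" if (np.isfinite(r) and r >= 0) else
                        ("-" if np.isfinite(r) else "na"),
            })
    return pd.DataFrame(rows)


def collinearity_filter(env: pd.DataFrame, pairwise_threshold: float = 0.8
                        ) -> list[str]:
    """Greedy pruning of collinear environmental variables.

    While any pair exceeds ``|r| > pairwise_threshold`` (Pearson), the member
    of the *worst* pair with the larger mean absolute correlation to all other
    remaining variables is dropped; ties break by variable-name order.
    """
    keep = sorted(env.columns)
    while len(keep) > 1:
        corr = env[keep].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= pairwise_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a = corr.loc[a].drop(b).mean() if len(keep) > 2 else 0.0
        mean_b = corr.loc[b].drop(a).mean() if len(keep) > 2 else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # deterministic: keep the lexicographically first
        keep.remove(drop)
    return keep


@dataclass
class BioenvResult:
    """Exhaustive BIOENV search output."""

    results: pd.DataFrame        # size, subset (tuple), r — every subset tried
    best_per_size: pd.DataFrame  # best subset for each size
    best_subset: tuple
    best_r: float
    dissimilarity: str

    def summary(self) -> pd.DataFrame:
        return self.best_per_size


def _community_dissimilarity(community, metric: str) -> np.ndarray:
    """Condensed inter-sample dissimilarity vector, plus sample order."""
    if isinstance(community, OtuTable):
        prof = relative_abundance(community)
        X = prof.T.to_numpy(float)  # samples × taxa
        ids = list(prof.columns)
        if metric == "bray_curtis":
            return pdist(X, metric="braycurtis"), ids
        if metric == "euclidean":
            return pdist(X), ids
        raise ValueError(f"unknown dissimilarity {metric!r}")
    arr = np.asarray(community, float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        return squareform(arr, checks=False), list(range(len(arr)))
    if arr.ndim == 1:
        return arr, None
    raise ValueError("community must be an OtuTable, a square dissimilarity "
                     "matrix, or a condensed dissimilarity vector")


def bioenv(community, env: pd.DataFrame, dissimilarity: str = "bray_curtis",
           max_subset_size: int | None = None) -> BioenvResult:
    """Best subset of environmental variables explaining community structure.

    The community dissimilarity (Bray-Curtis on relative abundances by
    default) is computed once; for every non-empty subset of variables up to
    ``max_subset_size``, Euclidean distances on the standardized (zero mean,
    unit sd) subset are Spearman-rank-correlated with it.
    """
    dvec, ids = _community_dissimilarity(community, dissimilarity)
    if ids is not None and all(i in env.index for i in ids):
        env = env.loc[ids]
    n = env.shape[0]
    if len(dvec) != n * (n - 1) // 2:
        raise ValueError("community and environment sample counts disagree")
    if n < 5:
        raise ValueError("need at least 5 shared samples")
    variables = list(env.columns)
    if max_subset_size is None:
        max_subset_size = len(variables)
    if max_subset_size > len(variables):
        warnings.warn("max_subset_size exceeds variable count; clamped")
        max_subset_size = len(variables)
    scaled = (env - env.mean()) / env.std(ddof=1)
    X = scaled.to_numpy(float)
    comm_ranks = stats.rankdata(dvec)

    rows = []
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(range(len(variables)), size):
            evec = pdist(X[:, subset])
            r = stats.spearmanr(comm_ranks, evec).statistic
            rows.append({"size": size,
                         "subset": tuple(variables[i] for i in subset),
                         "r": float(r)})
    results = pd.DataFrame(rows)
    best_per_size = (results.loc[results.groupby("size")["r"].idxmax()]
                     .reset_index(drop=True))
    best_row = results.loc[results["r"].idxmax()]
    return BioenvResult(results=results, best_per_size=best_per_size,
                        best_subset=tuple(best_row["subset"]),
                        best_r=float(best_row["r"]),
                        dissimilarity=dissimilarity)
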