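"""Alpha-diversity and richness estimators for OTU count vectors.

Implements the indices reported per sample in transect surveys: Shannon
entropy (base 2 by default), the Simpson family (Gini–Simpson 1−D,
reciprocal 1/D, and Simpson evenness (1/D)/S_obs), Good's coverage,
Chao1 (bias-corrected by default), ACE, and Faith's phylogenetic
diversity on a rooted tree.  ``diversity_table`` composes rarefaction with
all metrics, dropping samples shallower than the rarefaction depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .otu import OtuTable, rarefy

__all__ = [
    "alpha_diversity",
    "richness_estimate",
    "faith_pd",
    "diversity_table",
    "domain_ratio",
    "ALPHA_METRICS",
]

ALPHA_METRICS = (
    "shannon", "gini_simpson", "simpson_evenness", "reciprocal_simpson",
    "goods_coverage",
)


def _clean_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, float)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    if arr.sum() == 0:
        raise ValueError("all-zero count vector")
    return arr


def alpha_diversity(counts, metric: str, log_base: float = 2) -> float:
    """One alpha-diversity index of a single sample's count vector.

    Shannon ``H = -sum p_i log_base(p_i)``; Gini–Simpson ``1 - D`` and
    reciprocal Simpson ``1/D`` with ``D = sum p_i^2``; Simpson evenness
    ``(1/D)/S_obs``; Good's coverage ``1 - F1/N`` with ``F1`` the number of
    singleton taxa and ``N`` the read total.
    """
    arr = _clean_counts(counts)
    pos = arr[arr > 0]
    p = pos / pos.sum()
    if metric == "shannon":
        return float(-(p * (np.log(p) / np.log(log_base))).sum())
    d = float((p ** 2).sum())
    if metric == "gini_simpson":
        return 1.0 - d
    if metric == "reciprocal_simpson":
        return 1.0 / d
    if metric == "simpson_evenness":
        return (1.0 / d) / len(pos)
    if metric == "goods_coverage":
        f1 = int((pos == 1).sum())
        return 1.0 - f1 / pos.sum()
    raise ValueError(f"unknown metric {metric!r}; use one of {ALPHA_METRICS}")


def richness_estimate(counts, estimator: str, rare_cutoff: int = 10,
                      bias_corrected: bool = True) -> float:
    """Nonparametric richness estimate (``chao1`` or ``ace``).

    Chao1 (bias-corrected): ``S_obs + F1(F1-1) / (2(F2+1))``; the classic
    form ``S_obs + F1^2/(2 F2)`` is available with ``bias_corrected=False``
    (undefined when F2 = 0).  ACE splits taxa at ``rare_cutoff`` into rare
    and abundant classes and estimates coverage from the rare class.
    """
    arr = _clean_counts(counts)
    pos = arr[arr > 0].astype(int)
    s_obs = len(pos)
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    if estimator == "chao1":
        if bias_corrected:
            return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        if f2 == 0:
            raise ValueError("classic Chao1 undefined when F2 = 0")
        return s_obs + f1 ** 2 / (2.0 * f2)
    if estimator == "ace":
        rare = pos[pos <= rare_cutoff]
        s_rare, s_abund = len(rare), int((pos > rare_cutoff).sum())
        if s_rare == 0:
            return float(s_obs)
        n_rare = int(rare.sum())
        c_ace = 1.0 - f1 / n_rare
        if c_ace == 0:
            raise ValueError("ACE undefined: all rare taxa are singletons")
        ssq = sum(i * (i - 1) * int((rare == i).sum())
                  for i in range(1, rare_cutoff + 1))
        gamma2 = max(
            (s_rare / c_ace) * ssq / (n_rare * (n_rare - 1)) - 1.0, 0.0
        ) if n_rare > 1 else 0.0
        return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    raise ValueError(f"unknown estimator {estimator!r}; use 'chao1' or 'ace'")


def faith_pd(observed_taxa, tree) -> float:
    """Faith's phylogenetic diversity of ``observed_taxa`` on a rooted tree.

    ``tree`` is an ``skbio.TreeNode`` with branch lengths; the result is the
    total branch length of the minimal subtree connecting the observed tips
    to the root (the union of root-to-tip paths).
    """
    observed = {str(t) for t in observed_taxa}
    if not observed:
        raise ValueError("no observed taxa")
    tips = {tip.name: tip for tip in tree.tips()}
    missing = sorted(observed - tips.keys())
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    seen = set()
    total = 0.0
    for name in sorted(observed):
        node = tips[name]
        while node.parent is not None and id(node) not in seen:
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def diversity_table(table: OtuTable, depth: int, seed: int, tree=None,
                    log_base: float = 2, rare_cutoff: int = 10) -> pd.DataFrame:
    """Rarefy to ``depth`` and compute every metric per retained sample.

    Returns a long-format frame with columns ``sample_id, metric, value``;
    samples shallower than ``depth`` are omitted (matching the rarefaction
    drop rule).  When ``tree`` is given, Faith PD rows are included.
    """
    rare, dropped = rarefy(table, depth, seed)
    rows = []
    for sid in rare.sample_ids:
        vec = rare.counts[sid].to_numpy()
        for metric in ALPHA_METRICS:
            rows.append((sid, metric, alpha_diversity(vec, metric,
                                                      log_base=log_base)))
        for est in ("chao1", "ace"):
            rows.append((sid, est, richness_estimate(vec, est,
                                                     rare_cutoff=rare_cutoff)))
        if tree is not None:
            observed = [t for t, c in zip(rare.taxon_ids, vec) if c > 0]
            rows.append((sid, "faith_pd", faith_pd(observed, tree)))
    out = pd.DataFrame(rows, columns=["sample_id", "metric", "value"])
    out.attrs["dropped_samples"] = dropped
    return out


def domain_ratio(div_a: pd.DataFrame, div_b: pd.DataFrame, metric: str,
                 ndigits: int | None = None) -> pd.Series:
    """Per-sample ratio of one metric between two diversity tables.

    ``div_a / div_b`` over the shared samples (e.g. Archaea over Bacteria);
    optionally rounded to ``ndigits`` decimal places.
    """
    a = div_a[div_a["metric"] == metric].set_index("sample_id")["value"]
    b = div_b[div_b["metric"] == metric].set_index("sample_id")["value"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError(f"no shared samples for metric {metric!r}")
    denom = b.loc[shared]
    if (denom <= 0).any():
        bad = list(denom[denom <= 0].index)
        raise ValueError(f"non-positive denominator for samples {bad}")
    ratio = a.loc[shared] / denom
    ratio.name = f"{metric}_ratio"
    if ndigits is not None:
        ratio = ratio.round(ndigits)
    return ratio
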