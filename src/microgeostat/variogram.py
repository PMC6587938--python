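"""Semivariogram estimation, model fitting and spatial-dependence classes.

The empirical semivariogram is the method-of-moments estimator

    gamma(h) = 1 / (2 N(h)) * sum_{pairs at lag h} (z_i - z_j)^2,

computed first as a "cloud" of per-pair values (h_ij, (z_i - z_j)^2 / 2)
and then averaged inside equal-width lag bins.  Five parametric families
(nugget, spherical, exponential, gaussian, periodic/hole-effect cosine)
are fitted by weighted least squares over (nugget c0, partial sill c,
range-or-period a) with a deterministic multi-start grid; the best family
minimises the weighted residual sum of squares.

The nugget/sill ratio c0/(c0+c) classifies spatial dependence:
high < 0.25, medium in [0.25, 0.75], low > 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .transect import _coords_array

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "Variogram",
    "VariogramFitResults",
    "FAMILIES",
    "empirical_variogram",
    "model_curve",
    "fit_variogram",
    "spatial_dependence_class",
]

FAMILIES = ("nugget", "spherical", "exponential", "gaussian", "periodic")


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram: family + (nugget, partial sill, range).

    For the periodic (hole-effect cosine) family ``range_`` is the period —
    the lag at which the curve first returns to the nugget level.  The
    exponential and gaussian families use the practical-range convention
    (95% of the sill reached at ``range_``).
    """

    family: str
    nugget: float
    psill: float
    range_: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; use {FAMILIES}")
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range/period must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    @property
    def nugget_sill_ratio(self) -> float:
        if self.sill == 0:
            raise ValueError("no spatial variance (sill = 0)")
        return self.nugget / self.sill

    def __call__(self, h):
        return model_curve(self, h)


def model_curve(model: VariogramModel, h):
    """Model semivariance at lag(s) ``h``; exactly 0 at h = 0 (all families)."""
    h = np.asarray(h, float)
    if np.any(h < 0):
        raise ValueError("lags must be >= 0")
    c0, c, a = model.nugget, model.psill, model.range_
    fam = model.family
    if fam == "nugget":
        struct = np.zeros_like(h)
    elif fam == "spherical":
        r = np.minimum(h / a, 1.0)
        struct = c * (1.5 * r - 0.5 * r ** 3)
    elif fam == "exponential":
        struct = c * (1.0 - np.exp(-3.0 * h / a))
    elif fam == "gaussian":
        struct = c * (1.0 - np.exp(-3.0 * h ** 2 / a ** 2))
    elif fam == "periodic":
        struct = c * (1.0 - np.cos(2.0 * np.pi * h / a))
    else:  # pragma: no cover - guarded in VariogramModel
        raise ValueError(f"unknown family {fam!r}")
    gamma = np.where(h > 0, c0 + struct, 0.0)
    return float(gamma) if gamma.ndim == 0 else gamma


@dataclass
class EmpiricalVariogram:
    """Binned semivariances plus the underlying cloud of pair values."""

    h: np.ndarray            # bin centres (mean pair distance per bin)
    gamma: np.ndarray        # mean semivariance per bin
    npairs: np.ndarray       # pair count per bin
    bin_edges: np.ndarray
    cloud_h: np.ndarray      # per-pair lag
    cloud_gamma: np.ndarray  # per-pair (z_i - z_j)^2 / 2
    max_lag: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"h": self.h, "gamma": self.gamma,
                             "npairs": self.npairs})


def empirical_variogram(samples, values=None, attribute: str | None = None,
                        n_bins: int = 12, max_lag="half-max") -> EmpiricalVariogram:
    """Empirical (cloud + binned) semivariogram of one attribute.

    ``samples`` is a metadata frame (with ``attribute`` naming a column) or
    an (n, 2) coordinate array with ``values`` given explicitly.
    ``max_lag="half-max"`` uses half the maximum pairwise distance; bins are
    equal-width on (0, max_lag]; empty bins are dropped.
    """
    if values is None:
        if attribute is None:
            raise ValueError("give either values or an attribute name")
        values = samples[attribute].to_numpy(float)
    coords, _ = _coords_array(samples)
    z = np.asarray(values, float)
    if len(z) != len(coords):
        raise ValueError("values and coordinates differ in length")
    if len(z) < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(coords)
    g = pdist(z[:, None], metric="sqeuclidean") / 2.0
    if max_lag == "half-max":
        max_lag = float(d.max()) / 2.0
    max_lag = float(max_lag)
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    mask = (d > 0) & (d <= max_lag)
    idx = np.clip(np.searchsorted(edges, d[mask], side="left") - 1, 0, n_bins - 1)
    hs, gs, ns = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        hs.append(d[mask][sel].mean())
        gs.append(g[mask][sel].mean())
        ns.append(int(sel.sum()))
    return EmpiricalVariogram(
        h=np.asarray(hs), gamma=np.asarray(gs), npairs=np.asarray(ns),
        bin_edges=edges, cloud_h=d, cloud_gamma=g, max_lag=max_lag,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _weights(emp: EmpiricalVariogram, weighting: str, gamma_model=None):
    if weighting == "ols":
        return np.ones_like(emp.h)
    if weighting == "npairs_over_h2":
        return emp.npairs / emp.h ** 2
    if weighting == "cressie":
        gm = np.maximum(np.asarray(gamma_model, float), 1e-12)
        return emp.npairs / gm ** 2
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class _CandidateFit:
    model: VariogramModel
    wrss: float
    converged: bool


@dataclass
class VariogramFitResults:
    """Best fitted variogram model plus per-family diagnostics.

    Attributes
    ----------
    model : VariogramModel
        The winning family's fitted parameters.
    candidates : dict
        family -> ``(model, wrss, converged)`` for every family tried.
    """

    model: VariogramModel
    candidates: dict
    weighting: str
    empirical: EmpiricalVariogram

    @property
    def wrss(self) -> float:
        return self.candidates[self.model.family].wrss

    @property
    def nugget_sill_ratio(self) -> float:
        return self.model.nugget_sill_ratio

    @property
    def dependence_class(self) -> str:
        return spatial_dependence_class(self.model)

    def summary(self) -> pd.DataFrame:
        """Per-family table: parameters, sill, nugget/sill, class, WRSS."""
        rows = []
        for fam, cand in self.candidates.items():
            m = cand.model
            ratio = m.nugget / m.sill if m.sill > 0 else np.nan
            rows.append({
                "family": fam, "nugget": m.nugget, "psill": m.psill,
                "range": m.range_, "sill": m.sill, "nugget_sill_ratio": ratio,
                "class": (spatial_dependence_class(m) if m.sill > 0 else "n/a"),
                "wrss": cand.wrss, "best": fam == self.model.family,
            })
        return pd.DataFrame(rows).sort_values("wrss").reset_index(drop=True)


def _fit_family(emp: EmpiricalVariogram, family: str,
                weighting: str) -> _CandidateFit:
    h, gamma = emp.h, emp.gamma
    gmax = float(gamma.max())
    hmax = float(h.max())
    if family == "nugget":
        w = _weights(emp, weighting if weighting != "cressie" else "ols")
        c0 = float(np.average(gamma, weights=w))
        model = VariogramModel("nugget", max(c0, 0.0), 0.0, hmax)
        if weighting == "cressie":
            w = _weights(emp, "cressie", model_curve(model, h))
        wrss = float((w * (gamma - model_curve(model, h)) ** 2).sum())
        return _CandidateFit(model, wrss, True)

    if gmax == 0:  # constant attribute: flat zero variogram
        model = VariogramModel(family, 0.0, 0.0, hmax)
        return _CandidateFit(model, 0.0, True)

    def residual(theta, w):
        m = VariogramModel(family, theta[0], theta[1], theta[2])
        return np.sqrt(w) * (gamma - model_curve(m, h))

    # deterministic multi-start grid
    c0_starts = (0.0, 0.25 * gmax)
    c_starts = (0.5 * gmax, gmax)
    a_starts = hmax * np.array([0.15, 0.3, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0])
    best = None
    lb = [0.0, 0.0, 1e-8 * hmax]
    ub = [np.inf, np.inf, np.inf]
    for c0_0 in c0_starts:
        for c_0 in c_starts:
            for a_0 in a_starts:
                w = _weights(emp, weighting if weighting != "cressie"
                             else "npairs_over_h2")
                theta = np.array([c0_0, c_0, a_0])
                try:
                    for _ in range(3 if weighting == "cressie" else 1):
                        sol = least_squares(residual, theta, args=(w,),
                                            bounds=(lb, ub), method="trf")
                        theta = sol.x
                        if weighting == "cressie":
                            m = VariogramModel(family, *theta)
                            w = _weights(emp, "cressie", model_curve(m, h))
                except Exception:
                    continue
                cost = float((residual(theta, w) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, theta, sol.success)
    if best is None:
        return _CandidateFit(
            VariogramModel(family, 0.0, gmax, hmax), np.inf, False
        )
    cost, theta, ok = best
    model = VariogramModel(family, float(theta[0]), float(theta[1]),
                           float(theta[2]))
    return _CandidateFit(model, cost, bool(ok))


def fit_variogram(emp: EmpiricalVariogram, families=FAMILIES,
                  weighting: str = "npairs_over_h2") -> VariogramFitResults:
    """WLS fit of candidate families to a binned empirical variogram.

    Default weights are N(h)/h^2 (gstat's default); ``"cressie"``
    (N(h)/gamma_model^2, iterated) and ``"ols"`` are available.  Requires at
    least 3 non-empty bins.  The best family minimises the weighted RSS.
    """
    if len(emp.h) < 3:
        raise ValueError("need at least 3 non-empty lag bins to fit")
    candidates = {fam: _fit_family(emp, fam, weighting) for fam in families}
    converged = {f: c for f, c in candidates.items() if np.isfinite(c.wrss)}
    if not converged:
        raise RuntimeError(
            f"no variogram family converged; diagnostics: {candidates}"
        )
    best_family = min(converged, key=lambda f: converged[f].wrss)
    return VariogramFitResults(model=candidates[best_family].model,
                               candidates=candidates, weighting=weighting,
                               empirical=emp)


class Variogram:
    """Model-style front end: data in, ``fit()`` out.

    Parameters
    ----------
    samples
        Metadata frame (``attribute`` names the column) or (n, 2) coords.
    values, attribute
        Attribute values, given directly or by column name.
    """

    def __init__(self, samples, values=None, attribute=None,
                 n_bins: int = 12, max_lag="half-max"):
        self.empirical = empirical_variogram(samples, values=values,
                                             attribute=attribute,
                                             n_bins=n_bins, max_lag=max_lag)

    def fit(self, families=FAMILIES,
            weighting: str = "npairs_over_h2") -> VariogramFitResults:
        return fit_variogram(self.empirical, families=families,
                             weighting=weighting)


def spatial_dependence_class(model: VariogramModel) -> str:
    """Classify spatial dependence from the nugget/sill ratio.

    high < 0.25, medium in [0.25, 0.75], low > 0.75.
    """
    ratio = model.nugget_sill_ratio
    if ratio < 0.25:
        return "high"
    if ratio <= 0.75:
        return "medium"
    return "low"
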