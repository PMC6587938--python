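"""Ordinary kriging over a rasterized polygon, with leave-one-out validation.

Ordinary kriging predicts Z(s0) = sum_i w_i z(s_i) with weights solving the
(n+1) semivariance system with the unbiasedness constraint sum w_i = 1
enforced through a Lagrange multiplier:

    [ Gamma  1 ] [ w      ]   [ gamma0 ]
    [ 1^T    0 ] [ lambda ] = [ 1      ]

where Gamma_ij = gamma(|s_i - s_j|) and gamma0_i = gamma(|s_i - s0|).  The
kriging variance is w . gamma0 + lambda.  All samples enter every system
(global neighbourhood).

Leave-one-out cross-validation re-predicts each observation from the
remaining ones with the *same* fitted variogram model and summarises:

    ASE    = sqrt( mean( (Z'_j - mean(Z'))^2 ) )   spread of LOO estimates
    RMSE   = sqrt( mean( (Z_j - Z'_j)^2 ) )        prediction error
    RMSE_r = RMSE / S_z                            S_z = sd of observations

A fit is conventionally called accurate when ASE and RMSE agree and RMSE_r
is near 40%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .transect import DuplicateCoordinateWarning, _coords_array
from .variogram import VariogramModel, model_curve

__all__ = [
    "PredictionGrid",
    "KrigingResult",
    "CvReport",
    "OrdinaryKriging",
    "build_prediction_grid",
    "ordinary_kriging",
    "loo_cross_validation",
    "prediction_accuracy_flag",
]


@dataclass
class PredictionGrid:
    """Square-cell raster of prediction points inside a polygon."""

    centers: np.ndarray       # (m, 2) cell centres, row-major from lower-left
    pixel_area: float         # m^2
    side: float               # cell side, m
    polygon: Polygon
    expected_cells: int       # round(polygon area / pixel area)

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.centers, columns=["easting", "northing"])


def build_prediction_grid(polygon, pixel_area: float) -> PredictionGrid:
    """Rasterize ``polygon`` into congruent square cells of ``pixel_area``.

    The lattice is axis-aligned, anchored at the bounding-box lower-left
    corner; a cell is kept iff its centre lies strictly inside the polygon.
    ``expected_cells`` reports the area-ratio estimate
    round(polygon_area / pixel_area).
    """
    if pixel_area <= 0:
        raise ValueError("pixel_area must be > 0")
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon, float))
    if poly.area == 0:
        raise ValueError("degenerate polygon (zero area)")
    if not poly.is_valid:
        raise ValueError("polygon is not simple (self-intersecting?)")
    side = float(np.sqrt(pixel_area))
    minx, miny, maxx, maxy = poly.bounds
    nx = int(np.ceil((maxx - minx) / side))
    ny = int(np.ceil((maxy - miny) / side))
    xs = minx + (np.arange(nx) + 0.5) * side
    ys = miny + (np.arange(ny) + 0.5) * side
    gx, gy = np.meshgrid(xs, ys)          # row-major: y rows, x columns
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    centers = np.column_stack([gx.ravel()[inside], gy.ravel()[inside]])
    return PredictionGrid(
        centers=centers, pixel_area=float(pixel_area), side=side,
        polygon=poly, expected_cells=int(round(poly.area / pixel_area)),
    )


@dataclass
class KrigingResult:
    """Per-target predictions, kriging variances, and (optionally) weights."""

    targets: np.ndarray       # (m, 2)
    predictions: np.ndarray   # (m,)
    variances: np.ndarray     # (m,)
    weights: np.ndarray | None = None     # (m, n)
    lagrange: np.ndarray | None = None    # (m,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "easting": self.targets[:, 0], "northing": self.targets[:, 1],
            "prediction": self.predictions, "variance": self.variances,
        })


@dataclass
class CvReport:
    """Leave-one-out cross-validation summary for one response."""

    observed: np.ndarray
    predicted: np.ndarray
    ase: float
    rmse: float
    rmse_r: float
    s_z: float

    @property
    def n(self) -> int:
        return len(self.observed)

    def accuracy_flags(self, tol: float = 0.2) -> dict:
        return prediction_accuracy_flag(self, ase_rmse_rel_tol=tol)

    def summary(self) -> pd.Series:
        flags = self.accuracy_flags()
        return pd.Series({
            "n": self.n, "ASE": self.ase, "RMSE": self.rmse,
            "RMSE_r": self.rmse_r, "S_z": self.s_z,
            "ase_rmse_similar": flags["ase_rmse_similar"],
            "rmse_r_accurate": flags["rmse_r_accurate"],
        })


class OrdinaryKriging:
    """Ordinary kriging predictor built from samples and a variogram model.

    Parameters
    ----------
    samples
        Metadata frame (with ``attribute`` naming the response column) or
        an (n, 2) coordinate array with ``values`` given directly.
    model
        A fitted :class:`VariogramModel`.

    Duplicated locations with identical values are deduplicated with a
    warning; duplicated locations with conflicting values make the system
    singular and raise.
    """

    def __init__(self, samples, values=None, attribute=None,
                 model: VariogramModel = None):
        if model is None:
            raise ValueError("a VariogramModel is required")
        if values is None:
            if attribute is None:
                raise ValueError("give either values or an attribute name")
            values = samples[attribute].to_numpy(float)
        coords, labels = _coords_array(samples)
        z = np.asarray(values, float)
        if len(z) != len(coords):
            raise ValueError("values and coordinates differ in length")
        coords, z = self._resolve_duplicates(coords, z, labels)
        if len(coords) < 2:
            raise ValueError("need at least 2 distinct sample locations")
        self.coords = coords
        self.values = z
        self.model = model
        self._lhs = self._build_system(coords, model)

    @staticmethod
    def _resolve_duplicates(coords, z, labels):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        n = len(coords)
        drop = set()
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] == 0:
                    if z[i] != z[j]:
                        raise np.linalg.LinAlgError(
                            f"singular system: samples {labels[i]!r} and "
                            f"{labels[j]!r} share a location with different "
                            f"values"
                        )
                    drop.add(j)
        if drop:
            warnings.warn(
                f"deduplicated {len(drop)} co-located sample(s) with "
                f"identical values", DuplicateCoordinateWarning,
            )
            keep = [i for i in range(n) if i not in drop]
            coords, z = coords[keep], z[keep]
        return coords, z

    @staticmethod
    def _build_system(coords, model):
        n = len(coords)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        lhs = np.zeros((n + 1, n + 1))
        lhs[:n, :n] = model_curve(model, dist)
        lhs[:n, n] = 1.0
        lhs[n, :n] = 1.0
        return lhs

    def predict(self, targets, return_weights: bool = False) -> KrigingResult:
        """Solve the OK system at each target point."""
        targets = np.atleast_2d(np.asarray(targets, float))
        n = len(self.coords)
        diff = self.coords[None, :, :] - targets[:, None, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))       # (m, n)
        gamma0 = model_curve(self.model, dist)
        rhs = np.ones((targets.shape[0], n + 1))
        rhs[:, :n] = gamma0
        sol = np.linalg.solve(self._lhs, rhs.T).T      # (m, n+1)
        w, lam = sol[:, :n], sol[:, n]
        preds = w @ self.values
        variances = (w * gamma0).sum(axis=1) + lam
        return KrigingResult(
            targets=targets, predictions=preds, variances=variances,
            weights=w if return_weights else None,
            lagrange=lam if return_weights else None,
        )

    def cross_validate(self) -> CvReport:
        """Leave-one-out CV with the same variogram model (no refit)."""
        n = len(self.coords)
        if n < 3:
            raise ValueError("need at least 3 samples for cross-validation")
        preds = np.empty(n)
        idx = np.arange(n)
        for j in range(n):
            keep = idx != j
            ok = OrdinaryKriging(self.coords[keep], values=self.values[keep],
                                 model=self.model)
            preds[j] = ok.predict(self.coords[j]).predictions[0]
        obs = self.values
        ase = float(np.sqrt(np.mean((preds - preds.mean()) ** 2)))
        rmse = float(np.sqrt(np.mean((obs - preds) ** 2)))
        s_z = float(np.std(obs, ddof=1))
        rmse_r = rmse / s_z if s_z > 0 else np.nan
        return CvReport(observed=obs.copy(), predicted=preds, ase=ase,
                        rmse=rmse, rmse_r=rmse_r, s_z=s_z)


def ordinary_kriging(samples, attribute=None, model: VariogramModel = None,
                     targets=None, values=None,
                     return_weights: bool = False) -> KrigingResult:
    """Functional form: build an :class:`OrdinaryKriging` and predict."""
    ok = OrdinaryKriging(samples, values=values, attribute=attribute,
                         model=model)
    return ok.predict(targets, return_weights=return_weights)


def loo_cross_validation(samples, attribute=None, model: VariogramModel = None,
                         values=None) -> CvReport:
    """Functional form of :meth:`OrdinaryKriging.cross_validate`."""
    ok = OrdinaryKriging(samples, values=values, attribute=attribute,
                         model=model)
    return ok.cross_validate()


def prediction_accuracy_flag(cv: CvReport,
                             ase_rmse_rel_tol: float = 0.2) -> dict:
    """Accuracy flags: ASE ~ RMSE agreement and RMSE_r near-40% rule.

    ``ase_rmse_similar`` iff |ASE - RMSE| / max(ASE, RMSE) <= tol (true when
    both are 0); ``rmse_r_accurate`` iff RMSE_r <= 0.40 * (1 + tol).
    """
    denom = max(cv.ase, cv.rmse)
    similar = True if denom == 0 else abs(cv.ase - cv.rmse) / denom <= ase_rmse_rel_tol
    accurate = bool(cv.rmse_r <= 0.40 * (1 + ase_rmse_rel_tol))
    return {"ase_rmse_similar": bool(similar), "rmse_r_accurate": accurate}
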