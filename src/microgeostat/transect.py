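"""Georeferenced transect samples: metadata I/O, validation and distances.

Samples carry planar UTM coordinates (metres) and the measured soil
properties: pH, electrolytic conductivity (EC, dS/m), water content
(WC, %), organic and inorganic carbon (g/kg dry soil) and the
sand/silt/clay texture fractions (%, closing to 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransectSample",
    "METADATA_COLUMNS",
    "SOIL_PROPERTIES",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "pairwise_distances",
    "DuplicateCoordinateWarning",
]

METADATA_COLUMNS = (
    "sample_id", "easting", "northing", "pH", "EC", "WC",
    "org_C", "inorg_C", "sand", "silt", "clay",
)
SOIL_PROPERTIES = ("pH", "EC", "WC", "org_C", "inorg_C", "sand", "silt", "clay")

#: tolerated deviation of sand+silt+clay from 100 (percentage points)
TEXTURE_TOLERANCE = 1.5


class DuplicateCoordinateWarning(UserWarning):
    """Two samples share an identical location (kriging systems may be singular)."""


@dataclass(frozen=True)
class TransectSample:
    """One georeferenced soil sample with its measured properties."""

    sample_id: str
    easting: float
    northing: float
    pH: float
    EC: float
    WC: float
    org_C: float
    inorg_C: float
    sand: float
    silt: float
    clay: float

    def validate(self) -> None:
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise ValueError(f"{self.sample_id}: non-finite coordinates")
        if self.EC < 0:
            raise ValueError(f"{self.sample_id}: EC must be >= 0")
        if not 0 <= self.WC <= 100:
            raise ValueError(f"{self.sample_id}: WC must be in [0, 100]")
        closure = self.sand + self.silt + self.clay
        if abs(closure - 100.0) > TEXTURE_TOLERANCE:
            raise ValueError(
                f"{self.sample_id}: texture sums to {closure:.2f}, not 100"
            )


def validate_metadata(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame (index = sample_id); returns it unchanged."""
    missing = [c for c in METADATA_COLUMNS[1:] if c not in frame.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    for sid, row in frame.iterrows():
        TransectSample(sample_id=str(sid), **{c: float(row[c])
                       for c in METADATA_COLUMNS[1:]}).validate()
    return frame


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata CSV (header per :data:`METADATA_COLUMNS`)."""
    frame = pd.read_csv(path)
    if "sample_id" not in frame.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    frame = frame.set_index("sample_id")
    frame.index = frame.index.astype(str)
    return validate_metadata(frame)


def write_metadata(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index_label="sample_id")


def _coords_array(samples) -> tuple[np.ndarray, list[str]]:
    """Accept a metadata frame or an (n, 2) array; return coords + labels."""
    if isinstance(samples, pd.DataFrame):
        coords = samples[["easting", "northing"]].to_numpy(float)
        labels = [str(s) for s in samples.index]
    else:
        coords = np.asarray(samples, float)
        labels = [str(i) for i in range(len(coords))]
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coordinates must be an (n, 2) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return coords, labels


def pairwise_distances(samples) -> pd.DataFrame:
    """Symmetric Euclidean distance table (metres) on (easting, northing).

    Duplicate locations are allowed but raise a
    :class:`DuplicateCoordinateWarning`, since they make ordinary-kriging
    systems singular when the duplicated values disagree.
    """
    coords, labels = _coords_array(samples)
    if len(coords) < 2:
        raise ValueError("need at least 2 samples")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    iu = np.triu_indices(len(coords), k=1)
    if np.any(dist[iu] == 0):
        i = int(np.flatnonzero(dist[iu] == 0)[0])
        a, b = iu[0][i], iu[1][i]
        warnings.warn(
            f"samples {labels[a]!r} and {labels[b]!r} share a location",
            DuplicateCoordinateWarning,
        )
    return pd.DataFrame(dist, index=labels, columns=labels)
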