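"""Synthetic transect generator with the spatial structure the analysis assumes.

The generator emulates a 13-site, ~211 m soda-lake transect: soil
properties are drawn as Gaussian random fields whose covariance derives
from a configured variogram model (C(h) = sill - gamma(h)), then shifted,
optionally exponentiated, and clipped to physical ranges.  Defaults mimic
the study system: near-constant alkaline pH (~10.3-10.6), electrolytic
conductivity spanning roughly 7-180 dS/m (log-normal field), patchy
("periodic"/hole-effect) spatial structure in water and carbon content,
and a sand/silt/clay composition closed to 100%.  Taxon abundances follow
a log-linear response to standardized covariates and are sequenced to a
variable multinomial depth so that some samples can fall below a
rarefaction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable
from .transect import validate_metadata
from .variogram import VariogramModel, model_curve

__all__ = [
    "PropertyConfig",
    "SimulationConfig",
    "simulate_gaussian_field",
    "simulate_coords",
    "simulate_transect",
    "simulate_community",
    "transect_polygon",
]


@dataclass(frozen=True)
class PropertyConfig:
    """Marginal + spatial configuration of one simulated soil property.

    The Gaussian field has variance = ``model.sill`` and mean ``mean``; with
    ``log=True`` the field is exponentiated (log-normal property, for
    right-skewed quantities like EC).  ``lower``/``upper`` clip to the
    physical range after transformation.
    """

    model: VariogramModel
    mean: float
    log: bool = False
    lower: float | None = None
    upper: float | None = None


def _default_properties() -> dict:
    per = lambda c0, c, a: VariogramModel("periodic", c0, c, a)
    sph = lambda c0, c, a: VariogramModel("spherical", c0, c, a)
    return {
        # near-constant alkaline pH: tiny sill around 10.45
        "pH": PropertyConfig(per(0.0008, 0.004, 80.0), mean=10.45),
        # EC: log-normal, spanning roughly 7-180 dS/m
        "EC": PropertyConfig(per(0.04, 0.85, 100.0), mean=np.log(40.0),
                             log=True, lower=0.0),
        # water content %: patchy, ~13-56
        "WC": PropertyConfig(per(4.0, 95.0, 90.0), mean=33.0,
                             lower=0.0, upper=100.0),
        # organic C g/kg: ~4.5-26
        "org_C": PropertyConfig(per(1.0, 28.0, 70.0), mean=15.0, lower=0.0),
        # inorganic C g/kg: homogeneous
        "inorg_C": PropertyConfig(per(0.2, 3.0, 60.0), mean=10.0, lower=0.0),
        # texture weights (closed to 100 downstream)
        "_sand_w": PropertyConfig(sph(2.0, 30.0, 60.0), mean=50.0, lower=1.0),
        "_silt_w": PropertyConfig(sph(2.0, 15.0, 60.0), mean=22.0, lower=1.0),
        "_clay_w": PropertyConfig(sph(2.0, 20.0, 60.0), mean=28.0, lower=1.0),
    }


@dataclass
class SimulationConfig:
    """Scenario for a synthetic transect + community.

    Defaults are the emulated study conditions: 13 samples over 211 m,
    ~60 taxa in two domains, log-linear community response dominated by EC
    and WC, and uniform sequencing depth over [100, 1500] reads so that a
    rarefaction threshold in the low hundreds can drop a sample.
    """

    n_samples: int = 13
    transect_length: float = 211.0
    coords: np.ndarray | None = None        # explicit (n, 2) overrides above
    origin: tuple = (501000.0, 2157550.0)   # UTM-like anchor, NW end
    properties: dict = field(default_factory=_default_properties)
    n_taxa: int = 60
    n_archaea: int = 20
    effects: pd.DataFrame | None = None     # taxa × covariates, log-linear
    effect_covariates: tuple = ("EC", "WC", "pH", "org_C")
    effect_scale_major: float = 0.8         # sd of EC/WC effects
    effect_scale_minor: float = 0.2         # sd of the remaining effects
    baseline_scale: float = 1.2             # sd of log-baseline abundances
    depth_range: tuple = (100, 1500)
    seed: int = 0


def simulate_gaussian_field(coords, model: VariogramModel, mean: float,
                            seed) -> np.ndarray:
    """One realization of a Gaussian field with covariance sill - gamma(h).

    ``seed`` may be an int or a ``numpy.random.Generator``.  The periodic
    family's cosine covariance is only conditionally valid off a 1-D line,
    so a small diagonal jitter (1e-8 * sill) is always added for it; other
    families get 1e-10 * sill.  If the covariance still fails to factorize
    after one jitter escalation, an error names the model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    n = len(coords)
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("coordinates must be distinct")
    sill = model.sill
    if sill == 0:
        return np.full(n, float(mean))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    cov = sill - model_curve(model, dist)
    np.fill_diagonal(cov, sill)
    jitter = (1e-8 if model.family == "periodic" else 1e-10) * sill
    for attempt in range(2):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter *= 1e4
    else:
        raise np.linalg.LinAlgError(
            f"covariance of {model.family} model (nugget={model.nugget}, "
            f"psill={model.psill}, range={model.range_}) is not positive "
            f"semi-definite even after jitter"
        )
    return mean + L @ rng.standard_normal(n)


def simulate_coords(config: SimulationConfig, rng) -> np.ndarray:
    """Irregularly spaced points along a NW-SE diagonal transect."""
    if config.coords is not None:
        return np.asarray(config.coords, float)
    n = config.n_samples
    gaps = rng.uniform(0.5, 1.5, n - 1)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    t = t / t[-1] * config.transect_length
    ex, ny = config.origin
    c = 1.0 / np.sqrt(2.0)
    return np.column_stack([ex + t * c, ny - t * c])


def simulate_transect(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the metadata table (soil properties at each transect point).

    Each property is an independent Gaussian field per its
    :class:`PropertyConfig`; sand/silt/clay are produced by closing three
    positive weight fields to sum exactly 100.  Deterministic per
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_coords, *rng_props = [np.random.default_rng(s)
                              for s in ss.spawn(1 + len(config.properties))]
    coords = simulate_coords(config, rng_coords)
    n = len(coords)
    fields = {}
    for (name, pc), rng in zip(config.properties.items(), rng_props):
        x = simulate_gaussian_field(coords, pc.model, pc.mean, rng)
        if pc.log:
            x = np.exp(x)
        if pc.lower is not None or pc.upper is not None:
            x = np.clip(x, pc.lower, pc.upper)
        if np.all(~np.isfinite(x)):
            raise ValueError(f"property {name!r}: no finite values after clipping")
        fields[name] = x
    tex = np.column_stack([fields.pop("_sand_w"), fields.pop("_silt_w"),
                           fields.pop("_clay_w")])
    if np.any(tex.sum(axis=1) <= 0):
        raise ValueError("texture weights collapsed to zero; check clipping")
    tex = 100.0 * tex / tex.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(fields,
                         index=[f"Tx{i + 1:03d}" for i in range(n)])
    frame.index.name = "sample_id"
    frame.insert(0, "easting", coords[:, 0])
    frame.insert(1, "northing", coords[:, 1])
    frame["sand"], frame["silt"], frame["clay"] = tex[:, 0], tex[:, 1], tex[:, 2]
    return validate_metadata(frame)


def _default_effects(config: SimulationConfig, rng) -> pd.DataFrame:
    cov = list(config.effect_covariates)
    E = np.zeros((config.n_taxa, len(cov)))
    for j, c in enumerate(cov):
        scale = (config.effect_scale_major if c in ("EC", "WC")
                 else config.effect_scale_minor)
        E[:, j] = rng.normal(0.0, scale, config.n_taxa)
    return pd.DataFrame(E, columns=cov,
                        index=[f"OTU_{i + 1:04d}" for i in range(config.n_taxa)])


def _taxonomy(config: SimulationConfig, taxon_ids) -> pd.Series:
    arch_phyla = ("Euryarchaeota", "Thaumarchaeota")
    bact_phyla = ("Proteobacteria", "Bacteroidetes", "Actinobacteria",
                  "Gemmatimonadetes", "Firmicutes", "Chlorobi")
    lineages = []
    for i, tid in enumerate(taxon_ids):
        if i < config.n_archaea:
            ph = arch_phyla[i % len(arch_phyla)]
            lineages.append(f"k__Archaea; p__{ph}; c__; o__; f__; g__g{i}")
        else:
            ph = bact_phyla[i % len(bact_phyla)]
            lineages.append(f"k__Bacteria; p__{ph}; c__; o__; f__; g__g{i}")
    return pd.Series(lineages, index=taxon_ids)


def simulate_community(metadata: pd.DataFrame, config: SimulationConfig,
                       seed: int | None = None) -> OtuTable:
    """Multinomial community counts from a log-linear covariate response.

    Per-sample taxon intensities are exp(baseline + effects @ standardized
    covariates); counts are multinomial at a per-sample depth drawn
    uniformly from ``config.depth_range``.  Two-domain taxonomy lineages
    are attached.  Deterministic for a fixed seed (defaults to
    ``config.seed + 1``).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    effects = config.effects
    if effects is None:
        effects = _default_effects(config, rng)
    cov = list(effects.columns)
    X = metadata[cov].to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    baseline = rng.normal(0.0, config.baseline_scale, len(effects))
    log_intensity = baseline[None, :] + Xs @ effects.to_numpy().T  # samples × taxa
    if not np.all(np.isfinite(log_intensity)):
        raise ValueError("non-finite taxon intensity")
    prop = np.exp(log_intensity - log_intensity.max(axis=1, keepdims=True))
    prop /= prop.sum(axis=1, keepdims=True)
    low, high = config.depth_range
    depths = rng.integers(low, high + 1, size=len(metadata))
    counts = np.column_stack([
        rng.multinomial(depths[i], prop[i]) for i in range(len(metadata))
    ])
    taxon_ids = list(effects.index)
    return OtuTable(counts, taxonomy=_taxonomy(config, taxon_ids),
                    taxon_ids=taxon_ids,
                    sample_ids=list(metadata.index))


def transect_polygon(coords, width: float = 34.0) -> np.ndarray:
    """Rectangle ring (buffered bounding box) around the transect points.

    A convenience for building a prediction polygon when none is supplied;
    ``width`` buffers the bounding box on every side by width/2.
    """
    coords = np.asarray(coords, float)
    minx, miny = coords.min(axis=0) - width / 2
    maxx, maxy = coords.max(axis=0) + width / 2
    return np.array([[minx, miny], [maxx, miny], [maxx, maxy], [minx, maxy]])
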