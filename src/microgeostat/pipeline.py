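"""Config-driven end-to-end analysis: diversity -> variograms -> kriging -> BIOENV.

``run_pipeline`` executes the full transect workflow on files referenced by
a :class:`PipelineConfig`:

1. per-domain rarefaction, diversity tables, and inter-domain ratios;
2. per-variable empirical variogram, model fit and spatial-dependence class;
3. polygon rasterization, ordinary-kriging maps (soil variables and
   phylum-level relative abundances) and LOO cross-validation with
   accuracy flags;
4. taxa-environment Spearman correlation table;
5. BIOENV best-subset reports per domain;
6. a manifest listing every artifact with its SHA-256 checksum.

Every stage is deterministic for a fixed config seed; stage failures abort
with the stage name and a partial-manifest note.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as community_mod
from . import diversity as diversity_mod
from .kriging import OrdinaryKriging, build_prediction_grid
from .otu import (OtuTable, collapse_to_rank, rarefy, read_otu_table,
                  relative_abundance, sample_totals)
from .transect import read_metadata
from .variogram import Variogram

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger("microgeostat.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, parameters and the seed for one pipeline run."""

    otu_tables: dict            # domain name -> OTU TSV path
    metadata: str
    polygon: str                # CSV ring of easting,northing vertices
    outdir: str
    seed: int = 0
    tree: str | None = None
    rarefaction_depths: dict = field(default_factory=dict)  # domain -> depth|"min"
    n_bins: int = 12
    max_lag: object = "half-max"
    families: tuple = ("spherical", "exponential", "gaussian", "periodic", "nugget")
    weighting: str = "npairs_over_h2"
    pixel_area: float = 2.38
    krige_variables: tuple = ("pH", "EC", "WC", "org_C", "inorg_C")
    collapse_rank: str = "phylum"
    alpha_tiers: tuple = (0.05, 0.01)
    bioenv_dissimilarity: str = "bray_curtis"
    bioenv_max_subset_size: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["families"] = list(self.families)
        doc["krige_variables"] = list(self.krige_variables)
        doc["alpha_tiers"] = list(self.alpha_tiers)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> Path:
    frame.to_csv(path, float_format="%.10g", **kw)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest_path = outdir / "manifest.json"
    stage = "load_inputs"
    try:
        metadata = read_metadata(config.metadata)
        tables = {dom: read_otu_table(p) for dom, p in config.otu_tables.items()}
        polygon = pd.read_csv(config.polygon).to_numpy(float)
        tree = None
        if config.tree is not None:
            from skbio import TreeNode
            tree = TreeNode.read(str(config.tree))

        stage = "diversity"
        div_tables = {}
        rarefied = {}
        for dom, table in tables.items():
            depth = config.rarefaction_depths.get(dom, "min")
            if depth == "min":
                totals, _ = sample_totals(table)
                depth = int(totals.min())
            div = diversity_mod.diversity_table(table, depth,
                                                seed=config.seed, tree=tree)
            div_tables[dom] = div
            rarefied[dom], _ = rarefy(table, depth, seed=config.seed)
            artifacts.append(_write_csv(div, outdir / f"diversity_{dom}.csv",
                                        index=False))
            log = outdir / f"rarefaction_{dom}.log"
            log.write_text(
                f"depth={depth}\ndropped="
                f"{','.join(div.attrs['dropped_samples']) or '(none)'}\n")
            artifacts.append(log)
            logger.info("diversity[%s]: depth=%d dropped=%s", dom, depth,
                        div.attrs["dropped_samples"])

        stage = "domain_ratios"
        doms = list(tables)
        if len(doms) >= 2:
            a, b = doms[0], doms[1]
            rows = []
            for metric in ("shannon", "chao1", "ace"):
                try:
                    ratio = diversity_mod.domain_ratio(div_tables[a],
                                                       div_tables[b], metric)
                except ValueError:
                    continue
                for sid, val in ratio.items():
                    rows.append({"sample_id": sid, "metric": metric,
                                 "ratio": val})
            if rows:
                artifacts.append(_write_csv(
                    pd.DataFrame(rows),
                    outdir / f"ratios_{a}_over_{b}.csv", index=False))

        stage = "variograms"
        fits = {}
        vario_rows = []
        responses = {v: metadata[v].to_numpy(float)
                     for v in config.krige_variables}
        # phylum-level relative abundances as additional kriging responses;
        # computed on the rarefied table so dropped samples stay excluded
        for dom, table in rarefied.items():
            if table.taxonomy is None:
                continue
            coll = collapse_to_rank(table, config.collapse_rank)
            rel = relative_abundance(coll)
            rel = rel[[s for s in rel.columns if s in metadata.index]]
            for taxon in rel.index[:4]:  # leading phyla only
                responses[f"{dom}:{taxon}"] = (rel.loc[taxon], rel.columns)
        for name, resp in responses.items():
            if isinstance(resp, tuple):
                values, sids = resp
                sub = metadata.loc[sids]
                values = np.asarray(values, float)
            else:
                sub, values = metadata, resp
            if np.std(values) == 0:
                logger.info("variogram[%s]: constant response skipped", name)
                continue
            fit = Variogram(sub, values=values, n_bins=config.n_bins,
                            max_lag=config.max_lag).fit(
                families=config.families, weighting=config.weighting)
            fits[name] = (fit, sub, values)
            m = fit.model
            vario_rows.append({
                "response": name, "family": m.family, "nugget": m.nugget,
                "psill": m.psill, "sill": m.sill, "range": m.range_,
                "nugget_sill_ratio": m.nugget_sill_ratio,
                "class": fit.dependence_class, "wrss": fit.wrss,
            })
        artifacts.append(_write_csv(pd.DataFrame(vario_rows),
                                    outdir / "variogram_fits.csv", index=False))

        stage = "kriging"
        grid = build_prediction_grid(polygon, config.pixel_area)
        cv_rows = []
        for name, (fit, sub, values) in fits.items():
            ok = OrdinaryKriging(sub, values=values, model=fit.model)
            result = ok.predict(grid.centers)
            safe = name.replace(":", "_").replace(";", "_").replace(" ", "")
            artifacts.append(_write_csv(result.to_frame(),
                                        outdir / f"kriging_{safe}.csv",
                                        index=False))
            obs = pd.DataFrame({
                "easting": sub["easting"], "northing": sub["northing"],
                "observed": values,
            })
            artifacts.append(_write_csv(obs, outdir / f"observed_{safe}.csv",
                                        index=False))
            cv = ok.cross_validate()
            flags = cv.accuracy_flags()
            cv_rows.append({"response": name, "n": cv.n, "ASE": cv.ase,
                            "RMSE": cv.rmse, "RMSE_r": cv.rmse_r,
                            "S_z": cv.s_z, **flags})
        artifacts.append(_write_csv(pd.DataFrame(cv_rows),
                                    outdir / "cross_validation.csv",
                                    index=False))

        stage = "correlations"
        corr_frames = []
        for dom, table in tables.items():
            if table.taxonomy is None:
                continue
            coll = collapse_to_rank(table, config.collapse_rank)
            rel = relative_abundance(coll)
            corr = community_mod.spearman_matrix(
                rel, metadata[list(config.krige_variables) +
                              ["sand", "silt", "clay"]],
                alpha_tiers=config.alpha_tiers)
            corr.insert(0, "domain", dom)
            corr_frames.append(corr)
        if corr_frames:
            artifacts.append(_write_csv(pd.concat(corr_frames,
                                                  ignore_index=True),
                                        outdir / "spearman_correlations.csv",
                                        index=False))

        stage = "bioenv"
        env = metadata[["pH", "EC", "WC", "org_C", "inorg_C",
                        "sand", "silt", "clay"]]
        bio_rows = []
        for dom, table in tables.items():
            shared = [s for s in table.sample_ids if s in env.index]
            sub_counts = table.counts[shared]
            sub = OtuTable(sub_counts, taxonomy=table.taxonomy)
            res = community_mod.bioenv(
                sub, env.loc[shared],
                dissimilarity=config.bioenv_dissimilarity,
                max_subset_size=config.bioenv_max_subset_size)
            for _, row in res.best_per_size.iterrows():
                bio_rows.append({"domain": dom, "size": row["size"],
                                 "subset": "+".join(row["subset"]),
                                 "r": row["r"],
                                 "overall_best": row["subset"] == res.best_subset})
        artifacts.append(_write_csv(pd.DataFrame(bio_rows),
                                    outdir / "bioenv.csv", index=False))

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "grid": {"n_cells": grid.n_cells,
                     "expected_cells": grid.expected_cells,
                     "pixel_area": grid.pixel_area},
            "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        if not isinstance(exc, PipelineStageError):
            partial = {"failed_stage": stage,
                       "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)
                                     if p.exists()},
                       "note": "partial manifest written after stage failure"}
            manifest_path.write_text(json.dumps(partial, indent=2,
                                                sort_keys=True))
            raise PipelineStageError(stage, exc) from exc
        raise
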