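"""OTU count tables: container, validation, I/O, rarefaction and taxonomic collapsing.

The central container is :class:`OtuTable`, an integer taxa × samples count
matrix with optional rank-delimited taxonomy lineages (greengenes style,
``"k__Archaea; p__Euryarchaeota; ..."``).  Tables are read from plain TSV
(taxon rows, sample columns, optional trailing ``taxonomy`` column) or from
BIOM 1.0 JSON (dense or sparse).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "OtuTableError",
    "RANKS",
    "read_otu_table",
    "write_otu_table",
    "sample_totals",
    "collapse_to_rank",
    "relative_abundance",
    "rarefy",
]

#: Taxonomic ranks supported by :func:`collapse_to_rank`, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_RANK_INDEX = {rank: i for i, rank in enumerate(RANKS)}


class OtuTableError(ValueError):
    """Raised for malformed OTU tables (parse or validation failure)."""


class OtuTable:
    """Integer count matrix of taxa × samples with optional taxonomy.

    Parameters
    ----------
    counts
        DataFrame (index = taxon ids, columns = sample ids) or array-like.
        Values must be non-negative integers (integral floats are coerced).
    taxonomy
        Optional mapping/Series of taxon id -> lineage string.
    taxon_ids, sample_ids
        Required when ``counts`` is not a DataFrame.
    """

    def __init__(self, counts, taxonomy=None, taxon_ids=None, sample_ids=None):
        if isinstance(counts, pd.DataFrame):
            frame = counts.copy()
        else:
            if taxon_ids is None or sample_ids is None:
                raise OtuTableError(
                    "taxon_ids and sample_ids are required for array input"
                )
            frame = pd.DataFrame(np.asarray(counts), index=list(taxon_ids),
                                 columns=list(sample_ids))
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        self.counts = _coerce_integer_counts(frame)
        _check_unique(self.counts.index, "taxon")
        _check_unique(self.counts.columns, "sample")
        if self.counts.shape[0] == 0:
            raise OtuTableError("no taxa")
        if taxonomy is not None:
            taxonomy = pd.Series(taxonomy).astype(str)
            taxonomy.index = taxonomy.index.astype(str)
            missing = self.counts.index.difference(taxonomy.index)
            if len(missing):
                raise OtuTableError(
                    f"taxonomy missing for taxa: {list(missing)[:5]}"
                )
            taxonomy = taxonomy.reindex(self.counts.index)
        self.taxonomy = taxonomy

    # -- basic introspection -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        t, s = self.shape
        tax = "with" if self.taxonomy is not None else "without"
        return f"<OtuTable {t} taxa x {s} samples, {tax} taxonomy>"

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        same_counts = self.counts.equals(other.counts)
        if self.taxonomy is None and other.taxonomy is None:
            return same_counts
        if (self.taxonomy is None) != (other.taxonomy is None):
            return False
        return same_counts and self.taxonomy.equals(other.taxonomy)

    # -- convenience method forms of the module operations -------------------
    def sample_totals(self):
        return sample_totals(self)

    def collapse_to_rank(self, rank: str) -> "OtuTable":
        return collapse_to_rank(self, rank)

    def relative_abundance(self) -> pd.DataFrame:
        return relative_abundance(self)

    def rarefy(self, depth: int, seed: int):
        return rarefy(self, depth, seed)


def _coerce_integer_counts(frame: pd.DataFrame) -> pd.DataFrame:
    arr = frame.to_numpy()
    try:
        numeric = arr.astype(float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(frame)
        raise OtuTableError(f"non-integer count at {bad}") from exc
    if not np.all(np.isfinite(numeric)):
        bad = _first_bad(frame, ~np.isfinite(numeric))
        raise OtuTableError(f"non-finite count at {bad}")
    if np.any(numeric != np.round(numeric)):
        bad = _first_bad(frame, numeric != np.round(numeric))
        raise OtuTableError(f"non-integer count at {bad}")
    if np.any(numeric < 0):
        bad = _first_bad(frame, numeric < 0)
        raise OtuTableError(f"negative count at {bad}")
    return pd.DataFrame(numeric.astype(np.int64), index=frame.index,
                        columns=frame.columns)


def _first_bad(frame: pd.DataFrame, mask) -> str:
    i, j = np.argwhere(mask)[0]
    return f"row '{frame.index[i]}', column '{frame.columns[j]}'"


def _first_non_numeric(frame: pd.DataFrame) -> str:
    for i, row in enumerate(frame.itertuples(index=False)):
        for j, v in enumerate(row):
            try:
                float(v)
            except (TypeError, ValueError):
                return f"row '{frame.index[i]}', column '{frame.columns[j]}'"
    return "unknown position"


def _check_unique(index: pd.Index, axis: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise OtuTableError(f"duplicate {axis} ids: {dupes[:5]}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv", transposed: bool = False) -> OtuTable:
    """Read an OTU table from ``path``.

    TSV dialect: header row of sample ids, first column taxon ids, optional
    last column named ``taxonomy``.  ``transposed=True`` reads sample rows ×
    taxon columns instead.  ``format="biom-json"`` reads BIOM 1.0 JSON
    (dense or sparse matrix encoding), attaching taxonomy from row metadata.
    """
    if format == "tsv":
        return _read_tsv(path, transposed=transposed)
    if format == "biom-json":
        return _read_biom_json(path)
    raise OtuTableError(f"unknown format {format!r}; use 'tsv' or 'biom-json'")


def _read_tsv(path, transposed: bool = False) -> OtuTable:
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                            comment=None)
    except pd.errors.EmptyDataError as exc:
        raise OtuTableError("no taxa") from exc
    if frame.shape[0] == 0:
        raise OtuTableError("no taxa")
    if transposed:
        frame = frame.T
    taxonomy = None
    if frame.columns.size and str(frame.columns[-1]).lower() == "taxonomy":
        taxonomy = frame.iloc[:, -1]
        frame = frame.iloc[:, :-1]
    if frame.shape[1] == 0:
        raise OtuTableError("malformed header: no sample columns")
    return OtuTable(frame, taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    """Write ``table`` to ``path`` as TSV or BIOM 1.0 JSON (sparse)."""
    if format == "tsv":
        out = table.counts.copy()
        if table.taxonomy is not None:
            out["taxonomy"] = table.taxonomy
        out.to_csv(path, sep="\t", index_label="#OTU ID")
    elif format == "biom-json":
        _write_biom_json(table, path)
    else:
        raise OtuTableError(f"unknown format {format!r}")


def _read_biom_json(path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise OtuTableError(f"BIOM document missing field {key!r}")
    n_rows, n_cols = doc["shape"]
    if n_rows == 0:
        raise OtuTableError("no taxa")
    taxon_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    counts = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "dense":
        counts[:] = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        raise OtuTableError(f"unknown matrix_type {doc['matrix_type']!r}")
    taxonomy = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        lineage = meta.get("taxonomy")
        if lineage is not None:
            if isinstance(lineage, (list, tuple)):
                lineage = "; ".join(str(x) for x in lineage)
            taxonomy[str(r["id"])] = str(lineage)
    taxonomy = taxonomy if len(taxonomy) == n_rows else None
    return OtuTable(counts, taxonomy=taxonomy, taxon_ids=taxon_ids,
                    sample_ids=sample_ids)


def _write_biom_json(table: OtuTable, path) -> None:
    arr = table.counts.to_numpy()
    nz = np.argwhere(arr != 0)
    data = [[int(i), int(j), int(arr[i, j])] for i, j in nz]
    rows = []
    for tid in table.taxon_ids:
        meta = None
        if table.taxonomy is not None:
            meta = {"taxonomy": [s.strip() for s in
                                 str(table.taxonomy.loc[tid]).split(";")]}
        rows.append({"id": tid, "metadata": meta})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microgeostat",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(table.taxon_ids), len(table.sample_ids)],
        "rows": rows,
        "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sample_totals(table: OtuTable) -> tuple[pd.Series, int]:
    """Per-sample read totals (order matching ``sample_ids``) and grand total."""
    totals = table.counts.sum(axis=0)
    totals.name = "total"
    return totals, int(totals.sum())


def _lineage_prefix(lineage: str, rank: str) -> str | None:
    """Lineage string truncated at ``rank``; None when unassigned there."""
    idx = _RANK_INDEX[rank]
    parts = [p.strip() for p in str(lineage).split(";")]
    if len(parts) <= idx:
        return None
    segment = parts[idx]
    # a bare prefix like "p__" (or empty) carries no assignment
    name = segment.split("__", 1)[-1] if "__" in segment else segment
    if not name:
        return None
    return "; ".join(parts[: idx + 1])


def collapse_to_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum taxa sharing the lineage prefix through ``rank``.

    Taxa lacking an assignment at ``rank`` are pooled into a single
    ``unassigned_at_<rank>`` row; the grand total is conserved exactly.
    """
    if table.taxonomy is None:
        raise OtuTableError("collapse_to_rank requires taxonomy")
    if rank not in _RANK_INDEX:
        raise OtuTableError(f"unknown rank {rank!r}; use one of {RANKS}")
    labels = []
    for tid in table.taxon_ids:
        prefix = _lineage_prefix(table.taxonomy.loc[tid], rank)
        labels.append(prefix if prefix is not None else f"unassigned_at_{rank}")
    grouped = table.counts.groupby(pd.Index(labels, name="lineage"), sort=True).sum()
    taxonomy = pd.Series(grouped.index, index=grouped.index)
    return OtuTable(grouped, taxonomy=taxonomy)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Proportion matrix: count / sample total; every column sums to 1."""
    totals, _ = sample_totals(table)
    zero = totals[totals == 0]
    if len(zero):
        raise OtuTableError(f"zero-total sample(s): {list(zero.index)}")
    return table.counts / totals


def rarefy(table: OtuTable, depth: int, seed: int) -> tuple[OtuTable, list[str]]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped; their ids are
    returned as the second element (the rarefaction log).  Deterministic for
    a fixed ``seed`` (one RNG stream, samples processed in column order).
    """
    if depth < 1:
        raise OtuTableError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals, _ = sample_totals(table)
    kept, dropped = [], []
    data = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        total = int(totals[sid])
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            data[sid] = col.copy()
        else:
            data[sid] = rng.multivariate_hypergeometric(col, depth)
        kept.append(sid)
    if not kept:
        raise OtuTableError(
            f"rarefaction depth {depth} drops all {len(dropped)} samples"
        )
    counts = pd.DataFrame(data, index=table.counts.index)[kept]
    return OtuTable(counts, taxonomy=table.taxonomy), dropped
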