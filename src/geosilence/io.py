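"""Readers and writers for the standard formats the pipeline touches.

Count matrices travel as Matrix-Market sparse files with 10x-style
``features.tsv`` / ``barcodes.tsv`` sidecars plus a cell-metadata TSV
(``barcode<TAB>condition<TAB>cluster``). Gene annotation arrives either as an
Ensembl-dialect GTF (only ``gene`` records are used) or as a plain TSV with
``gene_id``, ``chromosome`` and ``start`` columns. Gene sets use the GMT
format. Everything here is deterministic: the same inputs always produce the
same in-memory objects, with cells ordered lexicographically by barcode.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import normalize_chromosome_name

__all__ = [
    "FormatError",
    "CountDataset",
    "read_count_dataset",
    "write_count_dataset",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path: str | Path) -> list[str]:
    with _open_text(path) as handle:
        return [line.rstrip("\n") for line in handle if line.strip()]


# ---------------------------------------------------------------------------
# Count dataset
# ---------------------------------------------------------------------------


@dataclass
class CountDataset:
    """A cells × genes integer count matrix with cell-level metadata.

    Attributes
    ----------
    counts
        Sparse CSR matrix of shape ``(n_cells, n_genes)`` holding raw
        transcript counts (integers; depth scaling never happens at load).
    cell_ids, gene_ids
        Row and column labels, aligned with ``counts``.
    cell_meta
        DataFrame indexed by cell id with at least ``condition`` and
        ``cluster`` columns.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def clusters(self) -> pd.Series:
        return self.cell_meta["cluster"]

    @property
    def conditions(self) -> pd.Series:
        return self.cell_meta["condition"]

    def validate(self) -> None:
        """Check structural invariants; raise :class:`FormatError` on failure."""
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise FormatError("counts shape does not match id lists")
        if list(self.cell_meta.index) != list(self.cell_ids):
            raise FormatError("cell_meta index does not match cell_ids")
        for column in ("condition", "cluster"):
            if column not in self.cell_meta.columns:
                raise FormatError(f"cell_meta lacks required column {column!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts must be non-negative")
        small = self.clusters.value_counts()
        small = small[small < 2]
        if len(small):
            logger.warning(
                "clusters with fewer than 2 cells: %s", list(small.index)
            )

    def to_anndata(self):
        """Return the dataset as an :class:`anndata.AnnData` object."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


def read_count_dataset(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    cell_meta_path: str | Path,
) -> CountDataset:
    """Load a Matrix-Market count matrix with its sidecars and cell metadata.

    The matrix may be stored genes × cells (the 10x convention) or
    cells × genes; the orientation is inferred from the sidecar lengths.
    Cells present in the matrix but absent from the metadata are dropped
    with a warning; an empty intersection is fatal. The returned dataset is
    ordered lexicographically by barcode.
    """
    matrix = sp.coo_matrix(scipy.io.mmread(str(matrix_path)))
    features = [line.split("\t")[0] for line in _read_lines(features_path)]
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]

    shape = matrix.shape
    if shape == (len(barcodes), len(features)):
        cells_by_genes = sp.csr_matrix(matrix)
    elif shape == (len(features), len(barcodes)):
        cells_by_genes = sp.csr_matrix(matrix.T)
    else:
        raise FormatError(
            f"matrix shape {shape} matches neither "
            f"(cells={len(barcodes)}, genes={len(features)}) nor its transpose"
        )
    if cells_by_genes.nnz and cells_by_genes.data.min() < 0:
        raise FormatError("count matrix contains negative entries")
    if cells_by_genes.nnz and np.any(cells_by_genes.data != np.round(cells_by_genes.data)):
        raise FormatError("count matrix contains non-integer entries")
    cells_by_genes = cells_by_genes.astype(np.int64)

    meta = pd.read_csv(cell_meta_path, sep="\t", dtype=str)
    required = {"barcode", "condition", "cluster"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"cell metadata must have columns {sorted(required)}; "
            f"got {list(meta.columns)}"
        )
    meta = meta.set_index("barcode")
    if meta.index.duplicated().any():
        raise FormatError("duplicate barcodes in cell metadata")

    keep = sorted(set(barcodes) & set(meta.index))
    dropped = sorted(set(barcodes) - set(meta.index))
    if dropped:
        logger.warning(
            "%d cells in matrix absent from metadata were dropped: %s",
            len(dropped),
            dropped[:10],
        )
    if not keep:
        raise FormatError("no cells shared between matrix and metadata")

    index_of = {barcode: i for i, barcode in enumerate(barcodes)}
    rows = [index_of[barcode] for barcode in keep]
    dataset = CountDataset(
        counts=sp.csr_matrix(cells_by_genes[rows]),
        cell_ids=list(keep),
        gene_ids=list(features),
        cell_meta=meta.loc[keep, ["condition", "cluster"]].copy(),
    )
    dataset.validate()
    return dataset


def write_count_dataset(dataset: CountDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset as MTX + sidecars + metadata TSV; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "cell_meta": outdir / "cell_meta.tsv",
    }
    # 10x convention: genes in rows, cells in columns.
    scipy.io.mmwrite(
        str(paths["matrix"]), sp.coo_matrix(dataset.counts.T), field="integer"
    )
    paths["features"].write_text("".join(f"{g}\n" for g in dataset.gene_ids))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in dataset.cell_ids))
    dataset.cell_meta.rename_axis("barcode").reset_index().to_csv(
        paths["cell_meta"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(blob: str) -> dict[str, str]:
    attributes: dict[str, str] = {}
    for chunk in blob.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, value = chunk.split(" ", 1)
        attributes[key] = value.strip().strip('"')
    return attributes


def read_gene_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read gene annotation as a table with gene_id, chromosome, start, strand.

    ``format`` is ``"gtf"`` or ``"tsv"``; when omitted it is inferred from
    the file extension. Chromosome names are normalized by stripping a
    leading ``chr``. Duplicate gene_ids keep the record with the smallest
    start (logged). The result has one row per gene, indexed 0..n-1.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        format = "gtf" if stem.endswith((".gtf", ".gff")) else "tsv"
    if format == "gtf":
        table = _read_gtf(path)
    elif format == "tsv":
        table = _read_annotation_tsv(path)
    else:
        raise ValueError(f"format must be 'gtf' or 'tsv', got {format!r}")

    table["chromosome"] = table["chromosome"].map(normalize_chromosome_name)
    if (table["start"] < 1).any():
        bad = table.loc[table["start"] < 1, "gene_id"].tolist()
        raise FormatError(f"start coordinates must be >= 1 (genes {bad[:5]})")

    duplicated = table["gene_id"].duplicated(keep=False)
    if duplicated.any():
        logger.warning(
            "%d duplicated gene_ids resolved to smallest start",
            table.loc[duplicated, "gene_id"].nunique(),
        )
        table = (
            table.sort_values(["gene_id", "start"], kind="mergesort")
            .drop_duplicates("gene_id", keep="first")
        )
    return table.sort_index(kind="mergesort").reset_index(drop=True)


def _read_gtf(path: Path) -> pd.DataFrame:
    records = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            if fields[2] != "gene":
                continue
            attributes = _parse_gtf_attributes(fields[8])
            if "gene_id" not in attributes:
                raise FormatError(f"{path}:{lineno}: gene record lacks gene_id")
            try:
                start = int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer start") from exc
            strand = fields[6] if fields[6] in ("+", "-") else "unknown"
            records.append(
                (attributes["gene_id"], fields[0], start, strand)
            )
    return pd.DataFrame(
        records, columns=["gene_id", "chromosome", "start", "strand"]
    )


def _read_annotation_tsv(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "start"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"annotation TSV must have columns {sorted(required)}; "
            f"got {list(table.columns)}"
        )
    if "strand" not in table.columns:
        table["strand"] = "unknown"
    table = table[["gene_id", "chromosome", "start", "strand"]].copy()
    table["gene_id"] = table["gene_id"].astype(str)
    table["chromosome"] = table["chromosome"].astype(str)
    try:
        table["start"] = table["start"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer start column") from exc
    return table


def write_gene_annotation(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into a name → member-list mapping.

    Duplicate members within a set are dropped (first occurrence kept);
    empty sets are dropped with a warning.
    """
    collection: dict[str, list[str]] = {}
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    f"at least one member"
                )
            name = fields[0]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                logger.warning("dropping empty gene set %r", name)
                continue
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            collection[name] = members
    return collection


def write_gmt(
    collection: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, members in collection.items():
        description = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, description, *members]))
    Path(path).write_text("".join(line + "\n" for line in lines))
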