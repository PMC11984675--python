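"""Cluster-relative silencing calls.

A gene is called silenced in a cell when its transcript count shows at least
a θ (default 50%) reduction relative to the mean of the cells in that cell's
cluster, and genes that are not expressed in the cluster are excluded from
evaluation altogether. The 50% default encodes the hemi-allelic expectation:
losing expression from one of two alleles halves the total transcript count.

Two normalization modes are provided. ``raw`` applies the definition to the
counts exactly as loaded. ``depth_scaled`` first rescales each cell to the
median total count, which prevents shallow cells from appearing globally
silenced; depth is a strong confounder of a 50%-reduction criterion, so the
scaled mode is recommended whenever library sizes vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountDataset

__all__ = [
    "ClusterProfile",
    "SilenceMatrix",
    "normalize_counts",
    "cluster_profiles",
    "call_silenced",
    "call_silenced_dataset",
    "write_silence_matrix",
]


class DegenerateClusterError(ValueError):
    """Raised when a cluster is too small for a meaningful mean."""


def normalize_counts(dataset: CountDataset, method: str = "raw") -> np.ndarray:
    """Return a dense cells × genes expression matrix.

    ``raw`` returns the counts unchanged; ``depth_scaled`` divides each cell
    by its total count and multiplies by the median total, preserving the
    zero pattern and each cell's within-cell rank order.
    """
    counts = np.asarray(dataset.counts.todense(), dtype=float)
    if method == "raw":
        return counts
    if method == "depth_scaled":
        totals = counts.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            names = [dataset.cell_ids[i] for i in zero[:5]]
            raise ValueError(
                f"cells with zero total count cannot be depth-scaled: {names}"
            )
        return counts * (np.median(totals) / totals)[:, None]
    raise ValueError(f"unknown normalization method {method!r}")


@dataclass
class ClusterProfile:
    """Per-cluster mean expression with the expressed-gene masks.

    Attributes
    ----------
    means
        DataFrame (clusters × genes) of arithmetic mean expression.
    expressed
        Boolean DataFrame (clusters × genes); True where the gene is
        evaluated ("expressed") in the cluster.
    cell_counts
        Number of cells per cluster.
    """

    means: pd.DataFrame
    expressed: pd.DataFrame
    cell_counts: pd.Series


def cluster_profiles(
    expr: np.ndarray,
    cluster_labels: pd.Series | np.ndarray,
    gene_ids: list[str],
    expressed_rule: str = "cluster_mean_positive",
    min_cells: int = 3,
) -> ClusterProfile:
    """Compute per-cluster per-gene means and the expressed-gene mask.

    ``cluster_mean_positive`` marks a gene expressed in a cluster when its
    cluster mean is strictly positive; ``min_cells`` requires detection
    (count > 0) in at least ``min_cells`` cells of the cluster.
    """
    labels = pd.Series(np.asarray(cluster_labels).astype(str))
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DegenerateClusterError(
            f"clusters with fewer than 2 cells: {list(small.index)}"
        )
    clusters = sorted(counts.index)
    means = np.empty((len(clusters), expr.shape[1]))
    expressed = np.empty_like(means, dtype=bool)
    for i, cluster in enumerate(clusters):
        block = expr[np.asarray(labels == cluster)]
        means[i] = block.mean(axis=0)
        if expressed_rule == "cluster_mean_positive":
            expressed[i] = means[i] > 0
        elif expressed_rule == "min_cells":
            expressed[i] = (block > 0).sum(axis=0) >= min_cells
        else:
            raise ValueError(f"unknown expressed_rule {expressed_rule!r}")
    gene_index = pd.Index(gene_ids, name="gene_id")
    return ClusterProfile(
        means=pd.DataFrame(means, index=clusters, columns=gene_index),
        expressed=pd.DataFrame(expressed, index=clusters, columns=gene_index),
        cell_counts=pd.Series(
            [int(counts[c]) for c in clusters], index=clusters, name="n_cells"
        ),
    )


@dataclass
class SilenceMatrix:
    """Boolean silencing calls over cells × genes.

    ``silenced[i, g]`` is True when gene ``g`` met the reduction threshold
    in cell ``i``. ``evaluated`` records, per cluster, which genes were
    expressed and therefore eligible for a call: a gene that is not
    evaluated in a cell's cluster is never silenced for that cell —
    "not evaluated" is distinct from "not silenced".
    """

    silenced: np.ndarray
    evaluated: pd.DataFrame
    cell_ids: list[str]
    gene_ids: list[str]
    cluster_labels: pd.Series

    def evaluated_for_cell(self, i: int) -> np.ndarray:
        """Boolean gene mask of the genes evaluated in cell ``i``'s cluster."""
        return self.evaluated.loc[str(self.cluster_labels.iloc[i])].to_numpy()

    def prevalence(self, cells: np.ndarray | None = None) -> pd.Series:
        """Fraction of evaluated cells in which each gene is silenced.

        ``cells`` is an optional boolean or index selector over cells;
        prevalence for a gene is computed over the selected cells whose
        cluster evaluates that gene. Genes evaluated in no selected cell
        get NaN.
        """
        n_cells = len(self.cell_ids)
        selector = np.arange(n_cells) if cells is None else np.arange(n_cells)[cells]
        eval_counts = np.zeros(len(self.gene_ids))
        silent_counts = np.zeros(len(self.gene_ids))
        for i in selector:
            mask = self.evaluated_for_cell(int(i))
            eval_counts += mask
            silent_counts += self.silenced[int(i)] & mask
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions = np.where(eval_counts > 0, silent_counts / np.maximum(eval_counts, 1), np.nan)
        return pd.Series(fractions, index=pd.Index(self.gene_ids, name="gene_id"))


def call_silenced(
    expr: np.ndarray,
    profiles: ClusterProfile,
    cluster_labels: pd.Series | np.ndarray,
    cell_ids: list[str],
    gene_ids: list[str],
    silencing_fraction: float = 0.5,
    leave_one_out: bool = False,
) -> SilenceMatrix:
    """Call silenced genes per cell relative to its cluster mean.

    A gene evaluated in cluster ``c`` is silenced in cell ``i`` exactly when
    ``expr[i, g] <= (1 - θ) * mean_c[g]`` — the boundary counts as silenced
    because the definition is "at least a θ reduction". With
    ``leave_one_out`` the cell's own contribution is removed from the
    cluster mean before comparison.
    """
    if not 0.0 < silencing_fraction < 1.0:
        raise ValueError("silencing_fraction must lie in (0, 1)")
    labels = pd.Series(np.asarray(cluster_labels).astype(str))
    silenced = np.zeros(expr.shape, dtype=bool)
    keep = 1.0 - silencing_fraction
    for cluster in profiles.means.index:
        rows = np.flatnonzero(np.asarray(labels == cluster))
        if rows.size == 0:
            continue
        block = expr[rows]
        mean = profiles.means.loc[cluster].to_numpy()
        expressed = profiles.expressed.loc[cluster].to_numpy()
        if leave_one_out:
            n = rows.size
            loo_mean = (mean[None, :] * n - block) / (n - 1)
            calls = block <= keep * loo_mean
        else:
            calls = block <= keep * mean[None, :]
        silenced[rows] = calls & expressed[None, :]
    return SilenceMatrix(
        silenced=silenced,
        evaluated=profiles.expressed.copy(),
        cell_ids=list(cell_ids),
        gene_ids=list(gene_ids),
        cluster_labels=labels,
    )


def call_silenced_dataset(dataset: CountDataset, config) -> SilenceMatrix:
    """Convenience wrapper: normalize, profile and call in one step."""
    expr = normalize_counts(dataset, config.normalization)
    profiles = cluster_profiles(
        expr,
        dataset.clusters,
        dataset.gene_ids,
        expressed_rule=config.expressed_rule,
        min_cells=config.min_cells,
    )
    return call_silenced(
        expr,
        profiles,
        dataset.clusters,
        dataset.cell_ids,
        dataset.gene_ids,
        silencing_fraction=config.silencing_fraction,
        leave_one_out=config.leave_one_out,
    )


def write_silence_matrix(matrix: SilenceMatrix, outdir) -> None:
    """Serialize calls as a sparse triplet TSV plus the evaluated-gene table."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(matrix.silenced)
    with open(outdir / "silenced.tsv", "w") as handle:
        handle.write("cell\tgene\tsilenced\n")
        for r, c in zip(rows, cols):
            handle.write(f"{matrix.cell_ids[r]}\t{matrix.gene_ids[c]}\t1\n")
    matrix.evaluated.rename_axis("cluster").reset_index().to_csv(
        outdir / "evaluated_genes.tsv", sep="\t", index=False
    )
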