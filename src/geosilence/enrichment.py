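"""Gene-set enrichment of recurrently silenced genes and burden contrasts.

Two flavors are provided. For an unranked list of recurrently silenced
genes (prevalence above a threshold across cells), over-representation is
tested with a one-sided hypergeometric p-value per gene set and
Benjamini–Hochberg adjustment across sets. For the contrast between
high-burden and low-burden cells, genes are ranked by a signed
log fold-change and gene sets are scored with a weighted Kolmogorov–
Smirnov running-sum enrichment statistic whose significance comes from
seeded gene-label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "recurrent_silenced_genes",
    "ora_test",
    "enrichment_score",
    "burden_contrast_enrichment",
    "family_loss_frequency",
]


def recurrent_silenced_genes(
    silence_matrix,
    cells_subset: np.ndarray | None = None,
    prevalence_threshold: float = 0.2,
) -> pd.DataFrame:
    """Genes silenced in strictly more than a fraction π of evaluated cells.

    Prevalence for each gene is the silenced fraction among the selected
    cells whose cluster evaluates that gene. The result is sorted by
    prevalence descending (ties by gene id) and has columns gene_id and
    prevalence.
    """
    if not 0.0 < prevalence_threshold < 1.0:
        raise ValueError("prevalence_threshold must lie in (0, 1)")
    if cells_subset is not None:
        selected = np.arange(len(silence_matrix.cell_ids))[cells_subset]
        if selected.size == 0:
            raise ValueError("cells_subset selects no cells")
    prevalence = silence_matrix.prevalence(cells_subset)
    table = prevalence.dropna().rename("prevalence").reset_index()
    table = table[table["prevalence"] > prevalence_threshold]
    return table.sort_values(
        ["prevalence", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class EnrichmentResult:
    """Over-representation of one gene set in a query list."""

    name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float


def ora_test(
    query_genes,
    universe_genes,
    gene_sets: dict[str, list[str]],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    Sets are intersected with the universe before testing; the p-value is
    the upper tail P(X >= overlap) for drawing ``len(query)`` genes from a
    universe containing ``set_size`` set members. Benjamini–Hochberg
    q-values are computed across all tested sets. Sets whose universe
    overlap is below ``min_overlap`` with the query are still tested
    (p = 1 when the overlap is 0) unless they vanish from the universe.
    """
    universe = sorted(set(universe_genes))
    if not universe:
        raise ValueError("empty gene universe")
    universe_set = set(universe)
    query = set(query_genes) & universe_set
    records = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe_set
        if not in_universe:
            continue
        overlap = len(query & in_universe)
        if overlap < min_overlap:
            continue
        p = float(
            scipy.stats.hypergeom.sf(
                overlap - 1, len(universe), len(in_universe), len(query)
            )
        )
        records.append((name, overlap, len(in_universe), len(query), len(universe), p))
    table = pd.DataFrame(
        records,
        columns=["name", "overlap", "set_size", "query_size", "universe_size", "p_value"],
    )
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(
            ["p_value", "name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["q_value"] = []
    return table


def enrichment_score(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> float:
    """Weighted Kolmogorov–Smirnov running-sum enrichment score.

    Genes must be ordered by decreasing ranking statistic. Hits advance
    the running sum proportionally to |score|^weight, misses retreat it by
    1/(N - N_hits); the score is the extreme deviation from zero (signed).
    """
    is_hit = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool)
    n_hits = int(is_hit.sum())
    n = len(ranked_genes)
    if n_hits == 0 or n_hits == n:
        return 0.0
    weights = np.abs(np.asarray(scores, dtype=float)) ** weight
    hit_weights = np.where(is_hit, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:
        # All hit genes carry zero statistic; fall back to unweighted steps.
        hit_weights = is_hit.astype(float)
        total = float(n_hits)
    step_hit = hit_weights / total
    step_miss = np.where(is_hit, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(step_hit - step_miss)
    extreme = running[np.argmax(np.abs(running))]
    return float(extreme)


def burden_contrast_enrichment(
    expr: np.ndarray,
    gene_ids: list[str],
    burden_records: pd.DataFrame,
    cell_ids: list[str],
    gene_sets: dict[str, list[str]],
    n_permutations: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    top_k: int = 10,
) -> pd.DataFrame:
    """Ranked gene-set enrichment between high- and low-burden cells.

    Genes are ranked by the log fold-change (pseudocount 1) of mean
    expression in high-burden versus low-burden cells; each set's
    enrichment score is tested by gene-label permutation (two-sided,
    add-one smoothed). The result is sorted by |ES| descending with a
    ``rank`` column; ``low_confidence`` flags contrasts where either class
    had fewer than 5 cells.
    """
    classes = burden_records.loc[cell_ids, "burden_class"]
    high = np.asarray(classes == "high")
    low = np.asarray(classes == "low")
    if high.sum() == 0 or low.sum() == 0:
        raise ValueError("both high- and low-burden classes must be non-empty")
    low_confidence = bool(high.sum() < 5 or low.sum() < 5)

    stat = np.log2(expr[high].mean(axis=0) + 1.0) - np.log2(
        expr[low].mean(axis=0) + 1.0
    )
    order = np.argsort(-stat, kind="mergesort")
    ranked = [gene_ids[j] for j in order]
    ranked_scores = stat[order]

    rng = np.random.default_rng(seed)
    records = []
    for name, members in gene_sets.items():
        gene_set = set(members) & set(gene_ids)
        if not gene_set:
            continue
        es = enrichment_score(ranked, ranked_scores, gene_set, weight)
        exceed = 0
        size = len(gene_set)
        positions = np.arange(len(ranked))
        for _ in range(n_permutations):
            perm = rng.choice(positions, size=size, replace=False)
            perm_set = {ranked[j] for j in perm}
            es_perm = enrichment_score(ranked, ranked_scores, perm_set, weight)
            if abs(es_perm) >= abs(es):
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        records.append((name, size, es, np.sign(es), p))
    table = pd.DataFrame(
        records, columns=["name", "set_size", "es", "direction", "p_value"]
    )
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.reindex(
            table["es"].abs().sort_values(ascending=False, kind="mergesort").index
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        table = table.head(top_k) if top_k else table
    table.attrs["low_confidence"] = low_confidence
    return table


def family_loss_frequency(
    expr: np.ndarray,
    gene_ids: list[str],
    family_genes: list[str],
    cluster_labels: pd.Series,
) -> pd.DataFrame:
    """Per-cluster fraction of cells with zero expression of family members.

    Designed for the HMGB family (Hmgb1/2/3), whose loss accompanies
    senescence-associated chromatin reorganization, but usable with any
    gene list. Family genes absent from the matrix appear with NaN.
    """
    if not family_genes:
        raise ValueError("family gene list is empty")
    labels = pd.Series(np.asarray(cluster_labels).astype(str))
    clusters = sorted(labels.unique())
    column_of = {g: j for j, g in enumerate(gene_ids)}
    table = pd.DataFrame(index=clusters, columns=family_genes, dtype=float)
    table.index.name = "cluster"
    for gene in family_genes:
        if gene not in column_of:
            continue
        values = expr[:, column_of[gene]]
        for cluster in clusters:
            rows = np.asarray(labels == cluster)
            table.loc[cluster, gene] = float((values[rows] == 0).mean())
    return table
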