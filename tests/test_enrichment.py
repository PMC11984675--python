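import itertools
import math

import numpy as np
import pandas as pd
import pytest

import geosilence as gs
from geosilence.enrichment import (
    burden_contrast_enrichment,
    enrichment_score,
    family_loss_frequency,
    ora_test,
    recurrent_silenced_genes,
)


def exact_overrepresentation_p(universe, gene_set, query, overlap):
    """Oracle: enumerate all query-sized draws and count >= overlap hits."""
    hits = 0
    total = 0
    members = set(gene_set)
    for draw in itertools.combinations(universe, len(query)):
        total += 1
        if len(members & set(draw)) >= overlap:
            hits += 1
    return hits / total


class TestRecurrentGenes:
    def _silence(self, silenced_cells, n_cells=100):
        import scipy.sparse as sp
        from geosilence.silencing import SilenceMatrix

        silenced = np.zeros((n_cells, 2), dtype=bool)
        silenced[:silenced_cells, 0] = True
        return SilenceMatrix(
            silenced=silenced,
            evaluated=pd.DataFrame(
                [[True, True]], index=["k"], columns=["gA", "gB"]
            ),
            cell_ids=[f"c{i}" for i in range(n_cells)],
            gene_ids=["gA", "gB"],
            cluster_labels=pd.Series(["k"] * n_cells),
        )

    def test_strictly_more_than_threshold_included(self):
        table = recurrent_silenced_genes(self._silence(21), prevalence_threshold=0.2)
        assert list(table["gene_id"]) == ["gA"]
        assert table["prevalence"].iloc[0] == pytest.approx(0.21)

    def test_exactly_at_threshold_excluded(self):
        table = recurrent_silenced_genes(self._silence(20), prevalence_threshold=0.2)
        assert len(table) == 0

    def test_prevalence_over_evaluated_cells(self):
        silence = self._silence(3, n_cells=10)
        table = recurrent_silenced_genes(silence, prevalence_threshold=0.2)
        assert table["prevalence"].iloc[0] == pytest.approx(0.3)

    def test_empty_subset_is_fatal(self):
        with pytest.raises(ValueError):
            recurrent_silenced_genes(
                self._silence(5), cells_subset=np.zeros(100, dtype=bool)
            )


class TestORA:
    def test_full_overlap_closed_form(self):
        universe = [f"u{i}" for i in range(20)]
        gene_set = universe[:5]
        result = ora_test(gene_set, universe, {"s": gene_set})
        expected = 1.0 / math.comb(20, 5)
        assert result["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_matches_exact_enumeration_on_small_universes(self):
        rng = np.random.default_rng(4)
        for trial in range(12):
            n_universe = int(rng.integers(8, 16))
            universe = [f"u{i}" for i in range(n_universe)]
            gene_set = list(rng.choice(universe, rng.integers(2, 6), replace=False))
            query = list(rng.choice(universe, rng.integers(2, 6), replace=False))
            overlap = len(set(gene_set) & set(query))
            if overlap == 0:
                continue
            result = ora_test(query, universe, {"s": gene_set})
            oracle = exact_overrepresentation_p(universe, gene_set, query, overlap)
            assert result["p_value"].iloc[0] == pytest.approx(oracle, rel=1e-9)

    def test_expected_overlap_is_not_significant(self):
        universe = [f"u{i}" for i in range(100)]
        # query 20, set 50: expected overlap 10; give exactly 10
        gene_set = universe[:50]
        query = universe[40:60]
        result = ora_test(query, universe, {"s": gene_set})
        assert result["p_value"].iloc[0] > 0.3

    def test_bh_adjustment_hand_computed(self):
        universe = [f"u{i}" for i in range(30)]
        # build three sets with p-values in known order, then check the
        # BH staircase on the actual values
        from statsmodels.stats.multitest import multipletests

        sets = {
            "tight": universe[:5],
            "loose": universe[:15],
            "null": universe[15:20],
        }
        result = ora_test(universe[:5], universe, sets)
        manual = multipletests(result["p_value"], method="fdr_bh")[1]
        assert np.allclose(result["q_value"], manual)
        assert (result["q_value"] >= result["p_value"] - 1e-12).all()

    def test_bh_formula_reference_case(self):
        # q of (0.01, 0.02, 0.9) is (0.03, 0.03, 0.9) by the BH step-up rule
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.9], method="fdr_bh")[1]
        assert np.allclose(q, [0.03, 0.03, 0.9])

    def test_empty_universe_is_fatal(self):
        with pytest.raises(ValueError):
            ora_test(["a"], [], {"s": ["a"]})


class TestRankedEnrichment:
    def test_top_ranked_set_reaches_extreme_score(self):
        ranked = [f"g{i}" for i in range(50)]
        scores = np.linspace(5, -5, 50)
        es = enrichment_score(ranked, scores, set(ranked[:5]))
        assert es > 0.9

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(0)
        expr = rng.poisson(3.0, size=(40, 30)).astype(float)
        genes = [f"g{i}" for i in range(30)]
        cells = [f"c{i}" for i in range(40)]
        records = pd.DataFrame(
            {
                "condition": "x",
                "cluster": "k",
                "n_events": [200] * 10 + [0] * 30,
            },
            index=cells,
        )
        from geosilence.burden import classify_burden

        records = classify_burden(records)
        sets = {"s1": genes[:8], "s2": genes[8:20]}
        first = burden_contrast_enrichment(
            expr, genes, records, cells, sets, n_permutations=200, seed=42
        )
        second = burden_contrast_enrichment(
            expr, genes, records, cells, sets, n_permutations=200, seed=42
        )
        pd.testing.assert_frame_equal(first, second)

    def test_segment_embedded_set_ranks_first(self, small_config):
        """A gene set placed entirely inside injected segments tops the list."""
        spec = gs.SimulationSpec(
            n_chromosomes=2,
            genes_per_chromosome=100,
            n_cells_control=60,
            n_cells_senescent=60,
            lambda_control=0.0,
            lambda_senescent=0.0,
            tail_fraction=0.5,
            lambda_tail=6.0,
            tail_depth_factor=1.0,
            segment_reduction=0.9,
            seed=21,
        )
        dataset, truth = gs.generate_cohort(spec)
        from geosilence.silencing import normalize_counts
        from geosilence.burden import classify_burden, per_cell_burden

        expr = normalize_counts(dataset, "raw")
        burden = truth.segment_counts.rename("n_events").to_frame()
        burden["condition"] = dataset.conditions
        burden["cluster"] = dataset.clusters
        records = classify_burden(burden, high_threshold=2, low_threshold=1)
        # the set of genes most often covered by injected segments
        coverage = truth.silenced_flags.sum(axis=0)
        top = np.argsort(-coverage)[:15]
        inside = [dataset.gene_ids[j] for j in top]
        rng = np.random.default_rng(3)
        low = np.argsort(coverage, kind="stable")[:100]
        outside_pool = [dataset.gene_ids[j] for j in low]
        decoys = {
            f"decoy{k}": list(rng.choice(outside_pool, 15, replace=False))
            for k in range(5)
        }
        result = burden_contrast_enrichment(
            expr,
            dataset.gene_ids,
            records,
            dataset.cell_ids,
            {"inside_segments": inside, **decoys},
            n_permutations=200,
            seed=0,
            top_k=0,
        )
        assert result.loc[result["rank"] == 1, "name"].iloc[0] == "inside_segments"
        assert result.loc[result["name"] == "inside_segments", "direction"].iloc[0] == -1

    def test_permutation_p_roughly_uniform_under_null(self):
        rng = np.random.default_rng(7)
        expr = rng.poisson(3.0, size=(30, 40)).astype(float)
        genes = [f"g{i}" for i in range(40)]
        cells = [f"c{i}" for i in range(30)]
        from geosilence.burden import classify_burden

        inside = [0, 0]
        for rep in range(40):
            records = classify_burden(
                pd.DataFrame(
                    {
                        "condition": "x",
                        "cluster": "k",
                        "n_events": rng.permutation([200] * 10 + [0] * 20),
                    },
                    index=cells,
                )
            )
            result = burden_contrast_enrichment(
                expr,
                genes,
                records,
                cells,
                {"s": list(rng.choice(genes, 10, replace=False))},
                n_permutations=99,
                seed=int(rng.integers(1 << 30)),
            )
            p = result["p_value"].iloc[0]
            inside[0] += 1
            inside[1] += int(0.01 <= p <= 0.99)
        assert inside[1] / inside[0] >= 0.9


class TestFamilyLoss:
    def test_fractions_of_zero_expression(self):
        expr = np.array([[0.0, 5.0], [0.0, 0.0], [1.0, 2.0], [3.0, 0.0]])
        table = family_loss_frequency(
            expr, ["Hmgb1", "Hmgb2"], ["Hmgb1", "Hmgb2", "Hmgb3"], ["a", "a", "b", "b"]
        )
        assert table.loc["a", "Hmgb1"] == 1.0
        assert table.loc["b", "Hmgb1"] == 0.0
        assert table.loc["a", "Hmgb2"] == 0.5
        assert np.isnan(table.loc["a", "Hmgb3"])  # absent gene reported missing

    def test_family_inside_segments_lost_more_in_senescent(self, small_config):
        spec = gs.SimulationSpec(
            n_chromosomes=2,
            genes_per_chromosome=60,
            n_cells_control=80,
            n_cells_senescent=80,
            lambda_control=0.0,
            lambda_senescent=8.0,
            tail_fraction=0.0,
            segment_reduction=1.0,
            seed=13,
        )
        dataset, truth = gs.generate_cohort(spec)
        from geosilence.silencing import normalize_counts

        expr = normalize_counts(dataset, "raw")
        coverage = truth.silenced_flags.sum(axis=0)
        family = [dataset.gene_ids[j] for j in np.argsort(-coverage)[:3]]
        table = family_loss_frequency(
            expr, dataset.gene_ids, family, dataset.clusters
        )
        assert (table.loc["senescent"] > table.loc["control"]).all()
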