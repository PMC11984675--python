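import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import geosilence as gs

logging.getLogger("geosilence").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort: 4 chromosomes x 80 genes, 40 cells per arm."""
    return gs.SimulationSpec(
        n_chromosomes=4,
        genes_per_chromosome=80,
        n_cells_control=40,
        n_cells_senescent=40,
        lambda_senescent=4.0,
        tail_fraction=0.1,
        lambda_tail=20.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    dataset, truth = gs.generate_cohort(small_spec)
    annotation = gs.generate_annotation(small_spec)
    return dataset, truth, annotation


@pytest.fixture(scope="session")
def small_config():
    return gs.AnalysisConfig(somatic_chromosomes=("1", "2", "3", "4"))


@pytest.fixture()
def toy_dataset():
    """4 cells x 6 genes, two clusters, with hand-checkable counts.

    Cluster A = cells c1, c2; cluster B = cells c3, c4. Gene g6 is silent
    in cluster A (mean 0) and expressed in cluster B.
    """
    counts = np.array(
        [
            #  g1  g2  g3  g4  g5  g6
            [10, 4, 0, 8, 2, 0],  # c1 (A)
            [10, 8, 6, 0, 2, 0],  # c2 (A)
            [5, 4, 3, 2, 1, 9],  # c3 (B)
            [15, 0, 3, 6, 1, 1],  # c4 (B)
        ]
    )
    meta = pd.DataFrame(
        {
            "condition": ["control", "control", "senescent", "senescent"],
            "cluster": ["A", "A", "B", "B"],
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="barcode"),
    )
    return gs.CountDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=["c1", "c2", "c3", "c4"],
        gene_ids=[f"g{i}" for i in range(1, 7)],
        cell_meta=meta,
    )


def brute_force_runs(vector):
    """Independent oracle: enumerate maximal True-runs by walking the list."""
    runs, start = [], None
    for i, value in enumerate(list(vector) + [False]):
        if value and start is None:
            start = i
        elif not value and start is not None:
            runs.append((start, i - start))
            start = None
    return runs
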