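import numpy as np
import pandas as pd
import pytest

import tsapool as tp


@pytest.fixture(scope="session")
def table1_cohort():
    """Low-noise synthetic cohort with planted top-target antigens."""
    return tp.fixture_table1_like(seed=7)


@pytest.fixture(scope="session")
def table1_result(table1_cohort):
    counts, meta, annot, _ = table1_cohort
    return tp.run_all(counts, meta, annot)


@pytest.fixture(scope="session")
def small_cohort():
    """Quick noisy cohort for filter/recovery property tests."""
    cfg = tp.SimulationConfig(
        n_tumor=20,
        tissue_sizes={
            t: 5
            for t in (
                "colon", "testis", "kidney", "liver", "spleen",
                "skin", "breast", "stomach", "brain", "heart", "lung",
            )
        },
        n_background_genes=60,
        n_tissue_specific_genes=8,
        planted_antigens=[
            tp.PlantedAntigen("AG1", 0.6, 300.0, (("colon", "low"),)),
            tp.PlantedAntigen("AG2", 0.3, 250.0, (("testis", "high"),)),
        ],
        dispersion=0.05,
        rng_seed=11,
    )
    return tp.simulate_cohort(cfg)


def make_counts(arr, genes=None, samples=None, normalized=False):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return tp.CountMatrix(
        pd.DataFrame(arr, index=genes, columns=samples), normalized=normalized
    )


@pytest.fixture
def counts_factory():
    return make_counts
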