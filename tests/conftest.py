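import pandas as pd
import pytest

import cx3sig as cx
from cx3sig import PopulationLabel

POPS = list(cx.io_formats.ALL_POPULATIONS)


def five_group_labels(reps: int = 2) -> dict[str, PopulationLabel]:
    """Sample -> population map with ``reps`` replicates per population."""
    return {
        f"{pop.value}_r{r + 1}": pop for pop in POPS for r in range(reps)
    }


def make_expression(rows: dict[str, list[float]], reps: int = 2,
                    scale: str = "normalized_counts") -> cx.ExpressionMatrix:
    """Expression matrix from per-gene lists of five group means.

    Each gene's five values are repeated ``reps`` times (exactly, so the
    group means are the given values).
    """
    labels = five_group_labels(reps)
    samples = list(labels)
    data = {}
    for gene, means in rows.items():
        per_pop = dict(zip(POPS, means))
        data[gene] = [per_pop[labels[s]] for s in samples]
    df = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return cx.ExpressionMatrix(df.astype(float), labels, scale=scale)


@pytest.fixture(scope="session")
def small_synth():
    """Moderate synthetic dataset reused across read-only tests."""
    return cx.generate_rna(n_genes=1200, n_sig=100, n_modules=3,
                           reps_per_group=5, seed=1)


@pytest.fixture(scope="session")
def small_normalized(small_synth):
    cm, _ = small_synth
    return cx.normalize_counts(cm, cx.size_factors(cm))


@pytest.fixture(scope="session")
def small_present(small_normalized):
    return cx.filter_present_rna(small_normalized)


@pytest.fixture(scope="session")
def small_protein(small_synth):
    cm, truth = small_synth
    return cx.generate_protein(cm, truth, seed=2)
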