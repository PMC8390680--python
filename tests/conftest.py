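import numpy as np
import pandas as pd
import pytest

from icbstrat.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One shared mid-size synthetic cohort (trial-like defaults)."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=24, seed=3, n_genes=120, paired_fraction=1.0)
    return generate_cohort(cfg)


def make_mutations(counts: dict[str, list[str]]) -> pd.DataFrame:
    """Mutation table from gene -> carrier sample ids (somatic missense)."""
    rows = [
        (sid, gene, "missense", "somatic")
        for gene, samples in counts.items()
        for sid in samples
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "variant_classification", "origin"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
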