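import numpy as np
import pandas as pd
import pytest

from cttwas import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest null cohort (no planted effects) shared across read-only tests."""
    config = SimulationConfig(n_samples=200, n_cases=100, n_transcripts=300, seed=11)
    return simulate_cohort(config)


@pytest.fixture()
def toy_expression():
    """Tiny hand-built expression matrix for QC-filter tests.

    Six transcripts, one per removal rule plus one clean survivor.
    """
    from cttwas import ExpressionMatrix

    n = 100
    rng = np.random.default_rng(0)
    samples = [f"S{i}" for i in range(n)]
    rows = {
        "t_rrna": rng.uniform(5, 10, n),
        "t_globin": rng.uniform(5, 10, n),
        "t_unannot": rng.uniform(5, 10, n),
        "t_lowexpr": np.full(n, 0.5),
        "t_highexpr": np.full(n, 30_000.0),
        "t_clean": rng.uniform(5, 10, n),
    }
    ab = pd.DataFrame(rows, index=samples).T
    ann = pd.DataFrame(
        {
            "gene_id": ["gA", "HBB", "", "gD", "gE", "gF"],
            "chrom": "chr1",
            "start": range(0, 60_000, 10_000),
            "end": range(5_000, 65_000, 10_000),
            "strand": "+",
            "biotype": ["rRNA"] + ["protein_coding"] * 5,
        },
        index=ab.index,
    )
    return ExpressionMatrix(ab, ann)
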