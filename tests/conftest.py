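import numpy as np
import pandas as pd
import pytest

from gcresponse.simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_paired_expression,
)


@pytest.fixture(scope="session")
def recovery_config():
    """Cohort at the planted-truth recovery regime (beta/sigma = 5, n = 50)."""
    return SimulationConfig(
        n_individuals=50,
        n_genes=200,
        n_snps=200,
        effect_size=1.0,
        noise_sd=0.2,
        eqtl_class_fractions={
            "null": 0.4,
            "no_interaction": 0.1,
            "gc_only": 0.2,
            "control_only": 0.2,
            "general": 0.1,
        },
        seed=123,
    )


@pytest.fixture(scope="session")
def recovery_cohort(recovery_config):
    genotypes = simulate_genotypes(recovery_config)
    expression, truth = simulate_paired_expression(genotypes, recovery_config)
    return genotypes, expression, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_peaks(rng, n, span=1_000_000, chrom="chrS"):
    """Possibly-overlapping random intervals with tag counts (test helper)."""
    starts = rng.integers(0, span, size=n)
    widths = rng.integers(50, 400, size=n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + widths,
            "name": [f"p{i}" for i in range(n)],
            "tags": rng.integers(1, 200, size=n),
        }
    )
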