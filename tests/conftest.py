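import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from tzsig import ExpressionMatrix, SimConfig, simulate_bundle

settings.register_profile(
    "fixed", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


def make_expression(genes, samples):
    """Build a small ExpressionMatrix.

    genes: {gene_id: (biotype, [fpkm per sample])}
    samples: [(name, dataset, condition, pair_id-or-None)]
    """
    names = [s[0] for s in samples]
    values = pd.DataFrame(
        {name: [genes[g][1][i] for g in genes] for i, name in enumerate(names)},
        index=pd.Index(list(genes), name="gene_id"),
    )
    biotype = pd.Series({g: genes[g][0] for g in genes}, name="biotype")
    biotype.index.name = "gene_id"
    sheet = pd.DataFrame(
        {
            "dataset": [s[1] for s in samples],
            "condition": [s[2] for s in samples],
            "pair_id": [s[3] if s[3] is not None else pd.NA for s in samples],
        },
        index=pd.Index(names, name="sample"),
    )
    return ExpressionMatrix(values=values, biotype=biotype, sample_sheet=sheet)


@pytest.fixture(scope="session")
def default_bundle():
    """The full synthetic study at its default design (2,000 genes,
    11-vs-2 tumor cohort, 3 cell-line pairs, planted truth), seed 1."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_simconfig():
    """A reduced design for fast I/O and CLI round trips."""
    return SimConfig(n_genes=300, n_concordant=10, n_invivo_only=5,
                     n_invitro_only=5, n_shortterm=5,
                     n_enhancer_background_genes=10, n_background_peaks=10,
                     seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_simconfig):
    return simulate_bundle(small_simconfig)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
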