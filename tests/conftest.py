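import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gwasroc as g

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_panel() -> g.GenotypePanel:
    """80 lines x 300 SNPs, fully inbred, imputed and MAF-filtered."""
    panel = g.simulate_panel(80, 300, seed=11, missing_rate=0.01)
    return g.filter_maf(g.impute_missing_mean(panel), 0.02)


@pytest.fixture(scope="session")
def mid_panel() -> g.GenotypePanel:
    """200 lines x 1,500 SNPs for mixed-model tests."""
    panel = g.simulate_panel(200, 1500, seed=13)
    return g.filter_maf(panel, 0.02)


@pytest.fixture(scope="session")
def mid_kinship(mid_panel) -> g.KinshipMatrix:
    return g.vanraden_kinship(mid_panel, n_snps_sample=1500, seed=17)


def make_panel_from_matrix(geno) -> g.GenotypePanel:
    """Wrap a raw dosage matrix (lists allowed, NaN = missing)."""
    geno = np.asarray(geno, dtype=float)
    n_ind, n_snp = geno.shape
    return g.GenotypePanel(
        individuals=[f"i{k}" for k in range(n_ind)],
        genotypes=geno,
        snp_ids=[f"s{k}" for k in range(n_snp)],
    )
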