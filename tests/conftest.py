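import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pathperm.formats_io import GenotypePanel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_panel(genotypes, phenotypes, clusters, pos=None, chrom="1") -> GenotypePanel:
    """Assemble a panel from raw arrays (tests' workhorse constructor)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j + 1:03d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "minor_allele": "A",
            "major_allele": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"i{i + 1:03d}" for i in range(n)],
            "phenotype": phenotypes,
            "cluster": clusters,
        }
    )
    return GenotypePanel(genotypes=g, snps=snps, samples=samples)


@pytest.fixture(scope="session")
def small_null_panel():
    """A 2-cluster, 200-sample, 12-SNP null panel shared across tests."""
    from pathperm.synthetic_data import generate_panel, study_config

    cfg = study_config(
        n_clusters=2, cases_per_cluster=50, controls_per_cluster=50,
        n_genes=6, snps_per_gene=2, seed=11,
    )
    return generate_panel(cfg), cfg
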