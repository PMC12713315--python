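import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from snpwrap.containers import GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genotype_matrix(geno, sex=None) -> GenotypeMatrix:
    """Wrap a raw genotype array in a GenotypeMatrix with stub metadata."""
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "allele1": "A",
            "allele2": "G",
        }
    )
    return GenotypeMatrix(geno, [f"S{i}" for i in range(n)], variants, sex=sex)


@pytest.fixture
def small_cohort():
    """60 samples x 40 SNPs drawn at HWE, balanced labels."""
    rng = np.random.default_rng(7)
    geno = rng.binomial(2, 0.3, size=(60, 40)).astype(float)
    y = np.repeat([0, 1], 30)
    return make_genotype_matrix(geno, sex=rng.integers(0, 2, 60).astype(float)), y
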