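import numpy as np
import pytest

from gwescan.genotypes import GenotypeMatrix, Variant
from gwescan.synthetic import LandscapeConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A modest geo-referenced panel shared by read-only tests."""
    cfg = LandscapeConfig(n_accessions=120, n_snps=600, n_adaptive=20, seed=3)
    return simulate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genotypes(rng, n=40, p=60, missing=0.0, chrom="1D", spacing=1000):
    """Helper: random sorted GenotypeMatrix for unit tests."""
    dosage = rng.integers(0, 3, size=(n, p)).astype(float)
    if missing > 0:
        mask = rng.random((n, p)) < missing
        dosage[mask] = np.nan
    pos = np.cumsum(rng.integers(1, spacing, size=p))
    variants = [Variant(chrom=chrom, pos=int(x), id=f"{chrom}_{x}") for x in pos]
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
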