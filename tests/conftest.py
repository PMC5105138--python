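import numpy as np
import pytest

from peachgwas.core import GenotypeMatrix
from peachgwas.simdata import (
    QualitativeTraitSpec,
    QuantitativeTraitSpec,
    SimConfig,
    SweepSpec,
    simulate,
)


def make_genotype_matrix(genotypes, pos=None, chrom=None, subpop=None, gq=None):
    """Small helper: wrap a raw genotype array in a GenotypeMatrix."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if pos is None:
        pos = np.arange(m) * 1000
    if chrom is None:
        chrom = np.repeat("scaffold_1", m)
    return GenotypeMatrix(
        genotypes=g,
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        ref=np.repeat("A", m),
        alt=np.repeat("T", m),
        samples=np.array([f"s{i}" for i in range(n)]),
        subpop=None if subpop is None else np.asarray(subpop),
        gq=gq,
    )


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config: 2 chromosomes x 1 Mb, the default 129-sample panel."""
    return SimConfig(
        seed=11,
        n_chrom=2,
        chrom_length=1_000_000,
        snp_spacing_mean=800,
        sweep_specs=[
            SweepSpec("scaffold_1", 300_000, 400_000, "domestication", 0.9),
            SweepSpec("scaffold_2", 600_000, 700_000, "improvement", 0.9),
        ],
        qualitative_traits=[QualitativeTraitSpec("fruit_shape", misclassification_rate=0.0)],
        quantitative_traits=[QuantitativeTraitSpec("fruit_weight", heritability=0.6)],
    )


@pytest.fixture(scope="session")
def sim_result(small_config):
    return simulate(small_config)
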