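import numpy as np
import pytest

from labstrain import GeneratorConfig, StrainGenotype


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120725)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced generator configuration for fast end-to-end tests."""
    return GeneratorConfig(seed=11, genome_length=12_000,
                           planted_repeats=((27, 6, 1.0), (9, 3, 1.0), (1, 11, 1.0)),
                           ssr_loci=3, n_samples=16)


def make_table2_genotypes(allele_counts=(5, 7, 5, 10, 2, 7, 3, 6, 3, 4, 5), n_strains=47):
    """Genotype set realizing a given per-locus allele-count profile."""
    loci = [f"L{i}" for i in range(len(allele_counts))]
    gts = []
    for j in range(n_strains):
        calls = {}
        for locus, k in zip(loci, allele_counts):
            a = j % k
            calls[locus] = None if a == k - 1 and k > 1 else 100 + 3 * a
        gts.append(StrainGenotype(f"S{j:02d}", calls))
    return gts


@pytest.fixture(scope="session")
def table2_genotypes():
    return make_table2_genotypes()
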