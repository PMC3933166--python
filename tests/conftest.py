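import numpy as np
import pytest

from spidroin.synthetic_data import SimParams, evolve_loci, simulate_gene


@pytest.fixture
def rng():
    return np.random.default_rng(20140220)


@pytest.fixture
def small_sim():
    """A small evolved spidroin-like gene with ground truth."""
    p = SimParams(seed=11, repeat_len_nt=300, n_repeats=8, n_term_len=120,
                  c_term_len=90, n_loci=2, ploidy=2, mutation_rate=2e-4,
                  terminal_rate_multiplier=5.0, conversion_rate=1.0,
                  n_generations=100)
    gene, truth = simulate_gene(p)
    evolve_loci(gene, truth)
    return gene, truth


def random_nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
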