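import numpy as np
import pytest

from wolfped.fixtures import load_fixture
from wolfped.genodata import MicrosatGenotype
from wolfped.simulate import SimConfig, simulate_recolonization, simulate_sampling


@pytest.fixture(scope="session")
def ref_fixture():
    return load_fixture()


@pytest.fixture(scope="session")
def small_truth():
    """A compact noisy simulation reused across tests."""
    cfg = SimConfig(seed=11, n_years=8, n_founder_immigrants_per_year=2,
                    breeder_mortality=0.2)
    return simulate_recolonization(cfg)


@pytest.fixture(scope="session")
def small_samples(small_truth):
    return simulate_sampling(small_truth)


def genotypes_from_freqs(freqs, n, rng, prefix="G", sexes=None):
    """Draw HWE genotypes from per-locus allele frequency dicts."""
    out = []
    for i in range(n):
        loci = {}
        for locus, f in freqs.items():
            alleles = np.array(list(f))
            p = np.array([f[a] for a in alleles])
            a, b = rng.choice(alleles, size=2, p=p)
            loci[locus] = (int(min(a, b)), int(max(a, b)))
        g = MicrosatGenotype(f"{prefix}{i:03d}", loci)
        if sexes is not None:
            g.sex = sexes[i]
        out.append(g)
    return out
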