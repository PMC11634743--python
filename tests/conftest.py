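import numpy as np
import pytest
from scipy import stats

from senesurf import simulate


def fisher_enumeration_p(a: int, b: int, c: int, d: int, guard: float = 1e-7) -> float:
    """Independent Fisher two-sided oracle: full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (relative tie guard
    absorbs floating-point noise on exact rational ties).
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(min(pmf[pmf <= obs * (1.0 + guard)].sum(), 1.0))


@pytest.fixture(scope="session")
def small_prot_config():
    return simulate.ProteomicsSimConfig(seed=11, n_proteins=400)


@pytest.fixture(scope="session")
def small_psm(small_prot_config):
    return simulate.generate_psm_dataset(small_prot_config)


@pytest.fixture(scope="session")
def small_bundle(small_prot_config):
    return simulate.generate_annotation_bundle(small_prot_config)
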