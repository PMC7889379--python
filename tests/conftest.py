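import numpy as np
import pytest

from pleiofam import FamilyData
from pleiofam.simulate import TRIO_OMEGA


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_unrelated_families(rng, n_fam=60, n=3, K=2, p=5, kind="continuous",
                            rho=0.2, gamma=0.3):
    """Independent-genotype families with exchangeable phenotype correlation."""
    from pleiofam.simulate import PhenotypeModel, assemble_error_correlation

    model = PhenotypeModel(kind=kind, K=K, rho_within=rho, rho_cross_same=gamma,
                           rho_cross_diff=0.1)
    maf = rng.uniform(0.1, 0.5, p)
    fams = []
    L = np.linalg.cholesky(assemble_error_correlation(model, n))
    for i in range(n_fam):
        g = rng.binomial(2, maf, size=(n, p)).astype(float)
        x = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(0.5, 1.0, n)])
        eta = np.tile(x @ model.alpha, K)
        if kind == "continuous":
            y = eta + L @ rng.standard_normal(n * K)
        else:
            from scipy.special import expit
            from scipy.stats import norm
            pr = expit(eta)
            z = L @ rng.standard_normal(n * K)
            y = (z <= norm.ppf(pr)).astype(float)
        fams.append(FamilyData(fid=f"F{i}", y=y, x=x, g=g))
    return fams


@pytest.fixture
def unrelated_families(rng):
    return make_unrelated_families(rng)


@pytest.fixture
def identity_omegas():
    def _make(fams):
        return [np.eye(f.n) for f in fams]
    return _make


@pytest.fixture
def trio_omega():
    return TRIO_OMEGA
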