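"""Independent numerical oracles used by the test suite only."""

import warnings

import numpy as np
from scipy import integrate


def imhof_sf(lam, q):
    """P(sum lam_l chisq_1 > q) by Imhof's characteristic-function inversion.

    Direct adaptive quadrature of the inversion integral; accurate to well
    below 1e-6 for the small mixtures used in the tests.  Kept outside the
    package: the implementation under test uses the saddlepoint approximation.
    """
    lam = np.asarray(lam, dtype=float)

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        # the integrand oscillates; quad converges but reports the
        # subdivision cap — accuracy is separately validated against MC
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, np.inf, limit=2000)
    return 0.5 + val / np.pi
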