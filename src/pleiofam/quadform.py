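"""Tail probabilities of positive mixtures of one-degree chi-squares.

Region-based score statistics (SKAT-type kernels) are asymptotically
distributed as Q = sum_l lambda_l * chisq_{1,l} under the null, where the
lambda_l are eigenvalues of the null covariance of the per-variant scores.
This module computes P(Q > q) with Kuonen's saddlepoint approximation
(Lugannani-Rice form on the cumulant generating function), falling back to
Satterthwaite moment matching when the root search fails.  When all weights
are equal the mixture is an exact scaled chi-square and we use the exact
survival function instead of the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm

__all__ = ["MixtureSpec", "eigen_weights", "mixture_chisq_sf"]

# p-values are floored here to avoid exact zeros downstream (Cauchy inverse).
_P_FLOOR = 1e-300


@dataclass
class MixtureSpec:
    """A mixture sum_l lam[l] * chisq_1 evaluated at the observed value q."""

    lam: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.size == 0 or not np.any(self.lam > 0):
            raise ValueError("mixture needs at least one positive weight")
        if np.any(self.lam < 0):
            raise ValueError("mixture weights must be non-negative")
        if not np.isfinite(self.q):
            raise ValueError("observed value must be finite")


def eigen_weights(M: np.ndarray, *, rel_tol: float = 1e-10, neg_tol: float = 1e-8) -> np.ndarray:
    """Eigenvalue weights of a symmetric PSD matrix, sorted descending.

    The matrix is symmetrized as (M + M.T)/2.  Eigenvalues below
    ``rel_tol * max`` are dropped; small negatives (within ``-neg_tol * max``,
    numerical noise from the eigensolver) are clipped to zero and dropped;
    anything more negative indicates an upstream bug and raises.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    M = (M + M.T) / 2.0
    lam = np.linalg.eigvalsh(M)[::-1]
    top = lam[0] if lam.size else 0.0
    if top <= 0:
        raise ValueError("matrix has no positive eigenvalue")
    if lam[-1] < -neg_tol * top:
        raise ValueError(f"matrix is not PSD (min eigenvalue {lam[-1]:.3e})")
    lam = np.clip(lam, 0.0, None)
    return lam[lam > rel_tol * top]


def _cgf(t: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return -0.5 * np.sum(np.log1p(-2.0 * lam[:, None] * np.atleast_1d(t)), axis=0)


def _cgf1(t: float, lam: np.ndarray) -> float:
    return float(np.sum(lam / (1.0 - 2.0 * lam * t)))


def _cgf2(t: float, lam: np.ndarray) -> float:
    return float(np.sum(2.0 * lam**2 / (1.0 - 2.0 * lam * t) ** 2))


def _saddlepoint_sf(lam: np.ndarray, q: float) -> float:
    """Lugannani-Rice survival probability for sum lam_l chi2_1 at q."""
    mean = float(lam.sum())
    # At q == mean the saddlepoint is t=0 and the r* formula is numerically
    # singular; interpolate linearly across a narrow bracket around the mean.
    if abs(q - mean) < 1e-4 * mean:
        lo, hi = mean * (1.0 - 2e-4), mean * (1.0 + 2e-4)
        plo, phi_ = _saddlepoint_sf(lam, lo), _saddlepoint_sf(lam, hi)
        return float(plo + (phi_ - plo) * (q - lo) / (hi - lo))
    tmax = 1.0 / (2.0 * lam.max())

    def f(t: float) -> float:
        return _cgf1(t, lam) - q

    if q > mean:
        lo, hi = 0.0, tmax * (1.0 - 1e-12)
        # K'(t) -> inf as t -> tmax, so the bracket is guaranteed, but guard
        # against overflow at the upper end by shrinking if needed.
        while f(hi) < 0:
            hi = (hi + tmax) / 2.0
            if tmax - hi < 1e-300:
                raise RuntimeError("saddlepoint bracket failed")
    else:
        hi = 0.0
        lo = -1.0 / (2.0 * lam.max())
        while f(lo) > 0:
            lo *= 2.0
            if not np.isfinite(lo):
                raise RuntimeError("saddlepoint bracket failed")
    t_hat = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    K = float(_cgf(np.array([t_hat]), lam)[0])
    w = np.sign(t_hat) * np.sqrt(max(2.0 * (t_hat * q - K), 0.0))
    v = t_hat * np.sqrt(_cgf2(t_hat, lam))
    if w == 0.0 or v == 0.0:
        raise RuntimeError("degenerate saddlepoint")
    return float(norm.sf(w + np.log(v / w) / w))


def _satterthwaite_sf(lam: np.ndarray, q: float) -> float:
    s1, s2 = float(lam.sum()), float(np.sum(lam**2))
    a = s2 / s1
    d = s1**2 / s2
    return float(chi2.sf(q / a, d))


@dataclass
class MixturePValue:
    p: float
    method: str
    flags: list = field(default_factory=list)


def mixture_chisq_sf(spec: MixtureSpec, *, full: bool = False):
    """Survival probability P(sum lam_l chisq_1 > q).

    Exact for a single weight or all-equal weights (scaled chi-square);
    otherwise the Kuonen saddlepoint approximation, with a Satterthwaite
    moment-matching fallback (flagged) if the root search fails.

    With ``full=True`` returns a :class:`MixturePValue` carrying the method
    label and flags; otherwise just the float p-value.
    """
    lam, q = spec.lam, float(spec.q)
    lam = lam[lam > 0]
    if q <= 0:
        out = MixturePValue(1.0, "exact")
        return out if full else out.p
    if np.ptp(lam) <= 1e-12 * lam.max():
        # equal weights: exact scaled chi-square with len(lam) df
        p = float(chi2.sf(q / lam.mean(), lam.size))
        out = MixturePValue(max(p, _P_FLOOR), "exact")
        return out if full else out.p
    try:
        p = _saddlepoint_sf(lam, q)
        out = MixturePValue(min(max(p, _P_FLOOR), 1.0), "saddlepoint")
    except RuntimeError:
        p = _satterthwaite_sf(lam, q)
        out = MixturePValue(min(max(p, _P_FLOOR), 1.0), "satterthwaite", ["fallback"])
    return out if full else out.p
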