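"""Synthetic-data factory: haplotype pools, trio gene drop, phenotypes.

Emulates a two-subpopulation sequencing study of nuclear families:

* two haplotype pools (a European-like and an admixed African-American-like
  stand-in) sharing variant sites but with drifted allele frequencies;
* trios (father, mother, one child) drawn by Mendelian gene drop, no
  recombination within the short region;
* two covariates (a Bernoulli(1/2) indicator and a correlated Gaussian)
  plus an intercept;
* K = 2 phenotypes, continuous (linear model with structured multivariate
  normal errors) or binary (logit marginals joined by a dichotomized
  multivariate normal whose latent correlations are solved so the realized
  *binary* correlations hit the targets), with within-cluster correlation
  0.2, same-subject cross-trait 0.3 and cross-subject cross-trait 0.1.

Effect sizes under the alternative follow |beta_l| = c |log10 m_l| with
c = 0.095, applied to a random 35% of variants rarer than MAF 0.03, signs
all positive or an 80/20 risk/protective mix; heterogeneous scenarios zero
out the second trait's effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit as sp_logit
from scipy.stats import norm

from .jgee import FamilyData

__all__ = [
    "HaplotypePool",
    "EffectModel",
    "PhenotypeModel",
    "make_pools",
    "draw_trios",
    "draw_covariates",
    "effect_sizes",
    "assemble_error_correlation",
    "simulate_continuous",
    "simulate_binary",
    "to_family_data",
    "bvn_cdf",
]

TRIO_OMEGA = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5], [0.5, 0.5, 1.0]])

ALPHA_CONTINUOUS = np.array([0.01, 0.1, 0.1])
ALPHA_BINARY = np.array([-1.4, 0.1, 0.1])


@dataclass
class HaplotypePool:
    label: str
    haplotypes: np.ndarray   # (n_hap, p) in {0,1}

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def p(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        f = self.haplotypes.mean(axis=0)
        return np.minimum(f, 1.0 - f)

    def window(self, start: int, width: int) -> "HaplotypePool":
        return HaplotypePool(self.label, self.haplotypes[:, start:start + width])


@dataclass
class EffectModel:
    causal_fraction: float = 0.35
    maf_threshold: float = 0.03
    positive_fraction: float = 1.0
    scale: float = 0.095
    heterogeneous: bool = False
    K: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must be in [0, 1]")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")


@dataclass
class PhenotypeModel:
    kind: str = "continuous"
    alpha: np.ndarray | None = None
    rho_within: float = 0.2       # Cor(e_ijk, e_ij'k), same trait, j != j'
    rho_cross_same: float = 0.3   # Cor(e_ijk, e_ijk'), same subject
    rho_cross_diff: float = 0.1   # Cor(e_ijk, e_ij'k'), different subject & trait
    K: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError("kind must be 'continuous' or 'binary'")
        if self.alpha is None:
            self.alpha = ALPHA_CONTINUOUS if self.kind == "continuous" else ALPHA_BINARY
        self.alpha = np.asarray(self.alpha, dtype=float)


def make_pools(p: int, rng: np.random.Generator, *, n_hap: int = 10_000,
               rare_fraction: float = 0.6, rare_range: tuple[float, float] = (1e-3, 0.03),
               common_range: tuple[float, float] = (0.03, 0.5),
               drift_sd: float = 0.45) -> tuple[HaplotypePool, HaplotypePool]:
    """Two haplotype pools over shared sites with drifted frequencies.

    Site frequencies for pool A mix a log-uniform rare spectrum (fraction
    ``rare_fraction`` below MAF 0.03) with a uniform common spectrum; pool
    B perturbs them on the logit scale with sd ``drift_sd`` (~Fst 0.05,
    a modest continental differentiation).  Haplotypes are i.i.d. Bernoulli
    per site (no LD); sites monomorphic in the combined pool are redrawn.
    """
    if p < 10:
        raise ValueError("need at least 10 variant sites")
    lo, hi = rare_range
    if not (0 < lo < hi) or not (common_range[0] < common_range[1] <= 0.5):
        raise ValueError("degenerate MAF spectrum")
    rare = rng.random(p) < rare_fraction
    fA = np.where(
        rare,
        np.exp(rng.uniform(np.log(lo), np.log(hi), p)),
        rng.uniform(common_range[0], common_range[1], p),
    )
    fB = expit(sp_logit(fA) + rng.normal(0.0, drift_sd, p))
    fB = np.clip(fB, lo / 2.0, 0.95)
    hapA = (rng.random((n_hap, p)) < fA).astype(np.int8)
    hapB = (rng.random((n_hap, p)) < fB).astype(np.int8)
    # redraw sites monomorphic in the combined pool
    for _ in range(20):
        tot = hapA.sum(axis=0) + hapB.sum(axis=0)
        bad = (tot == 0) | (tot == 2 * n_hap)
        if not bad.any():
            break
        k = int(bad.sum())
        hapA[:, bad] = rng.random((n_hap, k)) < fA[bad]
        hapB[:, bad] = rng.random((n_hap, k)) < fB[bad]
    return HaplotypePool("A", hapA), HaplotypePool("B", hapB)


def draw_trios(pool: HaplotypePool, n_fam: int, rng: np.random.Generator) -> np.ndarray:
    """Gene-drop ``n_fam`` trios from a pool: (n_fam, 3, p) dosages.

    Rows per family: father, mother, child.  Parents are two random pool
    haplotypes each (distinct within the family); the child receives one
    uniformly chosen haplotype from each parent, no recombination.
    """
    if pool.n_hap < 4:
        raise ValueError("pool must contain at least 4 haplotypes")
    idx = rng.integers(0, pool.n_hap, size=(n_fam, 4))
    # enforce distinct founder haplotypes within each family
    for _ in range(50):
        dup = np.array([len(set(row)) < 4 for row in idx])
        if not dup.any():
            break
        idx[dup] = rng.integers(0, pool.n_hap, size=(int(dup.sum()), 4))
    H = pool.haplotypes[idx]                      # (F, 4, p)
    father = H[:, 0] + H[:, 1]
    mother = H[:, 2] + H[:, 3]
    fpick = rng.integers(0, 2, size=n_fam)
    mpick = rng.integers(0, 2, size=n_fam)
    child = H[np.arange(n_fam), fpick] + H[np.arange(n_fam), 2 + mpick]
    return np.stack([father, mother, child], axis=1).astype(np.float64)


_X2_CORR = 0.9 * np.eye(3) + 0.1


def draw_covariates(n_fam: int, rng: np.random.Generator, n: int = 3) -> np.ndarray:
    """Covariate array (n_fam, n, 3): intercept, Bernoulli(1/2), Gaussian.

    The Gaussian covariate has mean 0.5, unit variances and covariance 0.1
    between family members.
    """
    X = np.ones((n_fam, n, 3))
    X[:, :, 1] = rng.integers(0, 2, size=(n_fam, n))
    if n == 3:
        L = np.linalg.cholesky(_X2_CORR)
    else:
        L = np.linalg.cholesky(0.9 * np.eye(n) + 0.1)
    X[:, :, 2] = 0.5 + rng.standard_normal((n_fam, n)) @ L.T
    return X


def effect_sizes(m: np.ndarray, model: EffectModel, rng: np.random.Generator) -> np.ndarray:
    """Per-variant, per-trait effects beta (p x K).

    A random ``causal_fraction`` of variants with MAF strictly below the
    threshold get |beta| = scale * |log10 m|, sign positive with
    probability ``positive_fraction``.  Heterogeneous models zero the
    second and later traits.
    """
    m = np.asarray(m, dtype=float)
    p = m.size
    beta1 = np.zeros(p)
    low = np.flatnonzero(m < model.maf_threshold)
    n_causal = int(round(model.causal_fraction * low.size))
    if n_causal > 0 and model.scale > 0:
        causal = rng.choice(low, size=n_causal, replace=False)
        sign = np.where(rng.random(n_causal) < model.positive_fraction, 1.0, -1.0)
        beta1[causal] = sign * model.scale * np.abs(np.log10(m[causal]))
    beta = np.tile(beta1[:, None], (1, model.K))
    if model.heterogeneous:
        beta[:, 1:] = 0.0
    return beta


def assemble_error_correlation(model: PhenotypeModel, n: int = 3) -> np.ndarray:
    """The (n*K) x (n*K) trait-major correlation matrix of the errors."""
    K = model.K
    Rn = (1.0 - model.rho_within) * np.eye(n) + model.rho_within
    C = (model.rho_cross_same - model.rho_cross_diff) * np.eye(n) + model.rho_cross_diff
    S = np.empty((n * K, n * K))
    for k in range(K):
        for kp in range(K):
            S[k * n:(k + 1) * n, kp * n:(kp + 1) * n] = Rn if k == kp else C
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("phenotype correlation targets are not positive definite")
    return S


def _linear_predictors(G: np.ndarray, X: np.ndarray, beta: np.ndarray,
                       alpha: np.ndarray, K: int) -> np.ndarray:
    """Eta (F, n*K), trait-major; alpha shared across traits."""
    F, n, _ = X.shape
    eta = np.empty((F, n * K))
    base = X @ alpha
    for k in range(K):
        eta[:, k * n:(k + 1) * n] = base + G @ beta[:, k]
    return eta


def simulate_continuous(G: np.ndarray, X: np.ndarray, beta: np.ndarray,
                        model: PhenotypeModel, rng: np.random.Generator) -> np.ndarray:
    """y = X alpha + G beta + eps with structured multivariate normal eps.

    Returns (F, n*K) trait-major responses.
    """
    F, n, _ = X.shape
    S = assemble_error_correlation(model, n)
    L = np.linalg.cholesky(S)
    eps = rng.standard_normal((F, n * model.K)) @ L.T
    return _linear_predictors(G, X, beta, model.alpha, model.K) + eps


# ---------------------------------------------------------------------------
# correlated binary responses via a dichotomized multivariate normal


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normals, vectorized.

    Gauss-Legendre quadrature of the correlation-integral representation
    Phi2 = Phi(h)Phi(k) + (1/2pi) int_0^rho exp(...)/sqrt(1-r^2) dr,
    accurate to ~1e-10 for |rho| <= 0.95.
    """
    h, k, rho = np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float),
                                    np.asarray(rho, float))
    r = 0.5 * rho[..., None] * (_GL_NODES + 1.0)       # nodes on [0, rho]
    wt = 0.5 * rho[..., None] * _GL_WEIGHTS
    om = 1.0 - r**2
    hh, kk = h[..., None], k[..., None]
    f = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * om)) / np.sqrt(om)
    return norm.cdf(h) * norm.cdf(k) + np.sum(wt * f, axis=-1) / (2.0 * np.pi)


def latent_correlation(p1: np.ndarray, p2: np.ndarray, r: np.ndarray,
                       *, tol: float = 1e-8, max_iter: int = 60) -> np.ndarray:
    """Latent normal correlation giving binary correlation ``r``.

    Solves Phi2(z1, z2; rho) = p1 p2 + r sqrt(p1 q1 p2 q2) with
    z_i = Phi^{-1}(p_i) (Y_i = 1 iff L_i <= z_i), by vectorized bisection.
    Raises if the target joint probability violates the Frechet bounds.
    """
    p1, p2, r = np.broadcast_arrays(np.asarray(p1, float), np.asarray(p2, float),
                                    np.asarray(r, float))
    q1, q2 = 1.0 - p1, 1.0 - p2
    target = p1 * p2 + r * np.sqrt(p1 * q1 * p2 * q2)
    lower = np.maximum(0.0, p1 + p2 - 1.0)
    upper = np.minimum(p1, p2)
    if np.any(target < lower - 1e-12) or np.any(target > upper + 1e-12):
        raise ValueError("binary correlation target outside the Frechet bounds")
    z1, z2 = norm.ppf(p1), norm.ppf(p2)
    lo = np.full(r.shape, -0.999)
    hi = np.full(r.shape, 0.999)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        too_low = bvn_cdf(z1, z2, mid) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


def simulate_binary(G: np.ndarray, X: np.ndarray, beta: np.ndarray,
                    model: PhenotypeModel, rng: np.random.Generator) -> np.ndarray:
    """Correlated binary responses with logit marginals.

    Marginal probabilities follow logit P(y=1) = X alpha + G beta; the
    joint distribution is a dichotomized multivariate normal whose latent
    correlations are solved per family so that the realized *binary*
    correlations match the 0.2 / 0.3 / 0.1 targets at those marginals.
    """
    F, n, _ = X.shape
    nK = n * model.K
    eta = _linear_predictors(G, X, beta, model.alpha, model.K)
    pr = expit(eta)
    if np.any(pr <= 1e-10) or np.any(pr >= 1.0 - 1e-10):
        raise ValueError("degenerate marginal prevalence (0 or 1) from the linear predictor")
    Rt = assemble_error_correlation(model, n)
    iu, ju = np.triu_indices(nK, 1)
    rho = latent_correlation(pr[:, iu], pr[:, ju], Rt[iu, ju])   # (F, npairs)
    Sig = np.tile(np.eye(nK), (F, 1, 1))
    Sig[:, iu, ju] = rho
    Sig[:, ju, iu] = rho
    # pairwise-solved latent matrices can be slightly non-PD jointly
    w, U = np.linalg.eigh(Sig)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        Sig = U @ (w[..., None] * np.swapaxes(U, 1, 2))
        d = np.sqrt(np.einsum("fii->fi", Sig))
        Sig /= d[:, :, None] * d[:, None, :]
    L = np.linalg.cholesky(Sig)
    z = np.einsum("fij,fj->fi", L, rng.standard_normal((F, nK)))
    return (z <= norm.ppf(pr)).astype(float)


def to_family_data(Y: np.ndarray, X: np.ndarray, G: np.ndarray,
                   fids: list[str] | None = None) -> list[FamilyData]:
    """Wrap array output (F, n*K), (F, n, q+1), (F, n, p) as FamilyData."""
    F = Y.shape[0]
    if fids is None:
        fids = [f"F{i:05d}" for i in range(F)]
    return [FamilyData(fid=fids[i], y=Y[i], x=X[i], g=G[i]) for i in range(F)]
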