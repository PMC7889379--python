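"""Joint-GEE null model for K correlated traits across families.

Fits the marginal model mu_i = g^{-1}(X_i alpha) under the no-genetic-effect
null, with a Kronecker working covariance

    V_i = A_i^{1/2} (R_K(gamma) x R_{n_i}(phi-params)) A_i^{1/2} * phi

combining a K x K multivariate-response correlation R_K with an n_i x n_i
within-cluster correlation R_n.  The fit alternates one Fisher-scoring step
on alpha with moment re-estimation of the scale and correlation parameters
from Pearson residuals, until the alpha update stabilizes.  The quantities
every downstream test consumes (mu_i, A_ik, Delta_ik, V_i and standardized
residuals S_i = V_i^{-1}(y_i - mu_i)) are produced here.

Responses are stacked trait-major: y_i holds K contiguous blocks of n_i,
block k being trait k — matching the Kronecker order R_K x R_n.

Links are canonical (identity for Gaussian traits, logit for Bernoulli),
so Delta_ik = d theta / d eta = I and d mu / d eta equals the unit variance
function (1 for Gaussian, mu(1-mu) for Bernoulli).  Traits must all be of
one kind; mixing continuous and binary responses in one model is not
supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "FamilyData",
    "WorkingCorrelation",
    "NullModelFit",
    "fit_null",
    "build_working_covariance",
    "standardized_residuals",
]

_STRUCTURES = ("independence", "exchangeable", "unstructured")
_KINDS = ("continuous", "binary")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FamilyData:
    """Per-family stacked data block.

    y: response vector of length n*K, trait-major (K blocks of n);
    x: n x (q+1) covariates, first column all ones;
    g: n x p genotype dosages in {0,1,2}.
    """

    fid: str
    y: np.ndarray
    x: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.g = np.atleast_2d(np.asarray(self.g, dtype=float))
        n = self.x.shape[0]
        if self.y.size % n != 0:
            raise ValueError(f"family {self.fid}: len(y) not a multiple of n")
        if self.g.shape[0] != n:
            raise ValueError(f"family {self.fid}: genotype rows != n")
        if not np.allclose(self.x[:, 0], 1.0):
            raise ValueError(f"family {self.fid}: first covariate column must be the intercept")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.x)):
            raise ValueError(f"family {self.fid}: missing values are not supported")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def K(self) -> int:
        return self.y.size // self.n


@dataclass
class WorkingCorrelation:
    """Specification + estimates of the working correlation structures."""

    rn_structure: str = "exchangeable"
    rk_structure: str = "exchangeable"
    rho: float = 0.0          # exchangeable within-cluster parameter
    gamma: float = 0.0        # exchangeable cross-trait parameter
    R_n: dict = field(default_factory=dict)   # keyed by cluster size n
    R_K: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rn_structure not in _STRUCTURES or self.rk_structure not in _STRUCTURES:
            raise ValueError(f"structures must be one of {_STRUCTURES}")


@dataclass
class NullModelFit:
    alpha: np.ndarray
    phi: float
    wc: WorkingCorrelation
    trait_kind: str
    K: int
    q: int
    families: list
    mu: list            # per family, length n*K
    A: list             # per family, diagonal of A_i (length n*K)
    Delta: list         # per family, diagonal of Delta_i (ones, canonical links)
    V: list             # per family, (n*K) x (n*K) working covariance
    S: list             # per family, V^{-1}(y - mu)
    converged: bool
    n_iter: int
    update_norm: float
    esteq_norm: float
    flags: list = field(default_factory=list)


def _kron_working(R_K: np.ndarray, R_n: np.ndarray) -> np.ndarray:
    return np.kron(R_K, R_n)


def build_working_covariance(A_diag: np.ndarray, R_K: np.ndarray, R_n: np.ndarray,
                             phi: float) -> np.ndarray:
    """V = A^{1/2} (R_K x R_n) A^{1/2} phi for one family.

    ``A_diag`` is the length n*K diagonal of A in trait-major block order.
    """
    sa = np.sqrt(np.asarray(A_diag, dtype=float))
    return _kron_working(R_K, R_n) * np.outer(sa, sa) * phi


def _exchangeable(n: int, r: float) -> np.ndarray:
    return np.full((n, n), r) + (1.0 - r) * np.eye(n)


def _pd_correlation(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix."""
    C = (C + C.T) / 2.0
    d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    w, U = np.linalg.eigh(R)
    if w.min() < floor:
        R = (U * np.clip(w, floor, None)) @ U.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


class _Group:
    """Families sharing a cluster size n, stacked for vectorized updates."""

    def __init__(self, idx: list[int], fams: list[FamilyData], K: int):
        self.idx = idx
        self.n = fams[0].n
        self.K = K
        q1 = fams[0].x.shape[1]
        self.Y = np.stack([f.y for f in fams])                      # (M, nK)
        X = np.stack([f.x for f in fams])                           # (M, n, q1)
        M, n = X.shape[0], self.n
        self.Xbig = np.zeros((M, n * K, q1 * K))
        for k in range(K):
            self.Xbig[:, k * n:(k + 1) * n, k * q1:(k + 1) * q1] = X
        self.M = M


def _init_alpha(groups: list[_Group], kind: str, K: int, q1: int) -> np.ndarray:
    """Warm start from trait-wise independence GLM fits on pooled data."""
    X = np.concatenate([g.Xbig[:, :g.n, :q1].reshape(-1, q1) for g in groups])
    alpha = np.empty(q1 * K)
    for k in range(K):
        y = np.concatenate([g.Y[:, k * g.n:(k + 1) * g.n].ravel() for g in groups])
        if kind == "continuous":
            a, *_ = np.linalg.lstsq(X, y, rcond=None)
        else:
            a = np.zeros(q1)
            for _ in range(25):
                mu = expit(X @ a)
                w = np.clip(mu * (1.0 - mu), 1e-10, None)
                delta = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - mu))
                a += delta
                if np.max(np.abs(delta)) < 1e-10:
                    break
        alpha[k * q1:(k + 1) * q1] = a
    return alpha


def fit_null(families: list[FamilyData], trait_kind: str, *,
             rn_structure: str = "exchangeable", rk_structure: str = "exchangeable",
             max_iter: int = 50, tol: float = 1e-6,
             fix_phi: float | None = None, ridge: float = 1e-8) -> NullModelFit:
    """Fit the joint-GEE null model (genetic effects identically zero).

    alpha solves sum_i D_i' V_i^{-1} (y_i - mu_i) = 0 by Fisher scoring;
    the scale phi (continuous traits; fixed at 1 for binary) and the
    correlation parameters come from moment estimators on Pearson
    residuals, iterated with alpha until the alpha update max-norm drops
    below ``tol``.  Non-convergence is flagged, not silent.
    """
    if trait_kind not in _KINDS:
        raise ValueError(f"trait_kind must be one of {_KINDS}")
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    K = families[0].K
    q1 = families[0].x.shape[1]
    for f in families:
        if f.K != K or f.x.shape[1] != q1:
            raise ValueError("all families must share K and the covariate count")

    by_n: dict[int, list[int]] = {}
    for i, f in enumerate(families):
        by_n.setdefault(f.n, []).append(i)
    groups = [_Group(idx, [families[i] for i in idx], K) for idx in by_n.values()]
    if rn_structure == "unstructured" and len(groups) > 1:
        raise ValueError("unstructured within-cluster correlation requires equal cluster sizes")

    wc = WorkingCorrelation(rn_structure, rk_structure)
    alpha = _init_alpha(groups, trait_kind, K, q1)
    binary = trait_kind == "binary"
    flags: list[str] = []
    phi = 1.0
    R_K = np.eye(K)
    Rn_by_n = {g.n: np.eye(g.n) for g in groups}

    n_subj = sum(g.M * g.n for g in groups)

    converged = False
    update_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # --- moments at the current alpha ---
        etas, mus, Avecs, resids, es = [], [], [], [], []
        for g in groups:
            eta = np.einsum("mij,j->mi", g.Xbig, alpha)
            if binary:
                mu = expit(eta)
                A = mu * (1.0 - mu)
            else:
                mu = eta
                A = np.ones_like(eta)
            r = g.Y - mu
            etas.append(eta); mus.append(mu); Avecs.append(A); resids.append(r)
            es.append(r / np.sqrt(np.clip(A, 1e-12, None)))
        if binary and any(np.max(np.abs(e)) > 30 for e in etas):
            flags.append("separation")

        # scale
        if fix_phi is not None:
            phi = fix_phi
        elif binary:
            phi = 1.0
        else:
            ss = sum(float(np.sum(e**2)) for e in es)
            df = n_subj * K - alpha.size
            phi = ss / max(df, 1)
        scl = np.sqrt(phi)
        eh = [e / scl for e in es]

        # working correlations from standardized residual cross-products
        if rk_structure == "exchangeable" and K > 1:
            num = den = 0.0
            for g, e in zip(groups, eh):
                e3 = e.reshape(g.M, K, g.n)
                s = e3.sum(axis=1)
                num += float(np.sum(s**2 - np.sum(e3**2, axis=1)))
                den += g.M * g.n * K * (K - 1)
            gam = num / max(den, 1)
            wc.gamma = float(np.clip(gam, -1.0 / max(K - 1, 1) + 1e-6, 1.0 - 1e-6))
            R_K = _exchangeable(K, wc.gamma)
        elif rk_structure == "unstructured" and K > 1:
            C = np.zeros((K, K)); cnt = 0
            for g, e in zip(groups, eh):
                e3 = e.reshape(g.M, K, g.n)
                C += np.einsum("mkj,mlj->kl", e3, e3)
                cnt += g.M * g.n
            R_K = _pd_correlation(C / cnt)
            wc.gamma = float(np.mean(R_K[np.triu_indices(K, 1)])) if K > 1 else 0.0
        else:
            R_K = np.eye(K)

        if rn_structure == "exchangeable":
            num = den = 0.0
            for g, e in zip(groups, eh):
                if g.n < 2:
                    continue
                e3 = e.reshape(g.M, K, g.n)
                s = e3.sum(axis=2)
                num += float(np.sum(s**2 - np.sum(e3**2, axis=2)))
                den += g.M * K * g.n * (g.n - 1)
            if den > 0:
                nmax = max(g.n for g in groups)
                rho = num / den
                wc.rho = float(np.clip(rho, -1.0 / max(nmax - 1, 1) + 1e-6, 1.0 - 1e-6))
            Rn_by_n = {g.n: _exchangeable(g.n, wc.rho) for g in groups}
        elif rn_structure == "unstructured":
            g, e = groups[0], eh[0]
            e3 = e.reshape(g.M, K, g.n)
            C = np.einsum("mkj,mkl->jl", e3, e3) / (g.M * K)
            Rn_by_n = {g.n: _pd_correlation(C)}
        else:
            Rn_by_n = {g.n: np.eye(g.n) for g in groups}

        # --- one Fisher-scoring step on alpha ---
        LHS = np.zeros((alpha.size, alpha.size))
        RHS = np.zeros(alpha.size)
        for g, A, r in zip(groups, Avecs, resids):
            R = _kron_working(R_K, Rn_by_n[g.n])
            sa = np.sqrt(np.clip(A, 1e-12, None))
            V = R[None, :, :] * (sa[:, :, None] * sa[:, None, :]) * phi
            D = A[:, :, None] * g.Xbig          # d mu / d alpha (canonical link)
            try:
                sol = np.linalg.solve(V, np.concatenate([D, r[:, :, None]], axis=2))
            except np.linalg.LinAlgError:
                V += ridge * np.trace(V, axis1=1, axis2=2)[:, None, None] / V.shape[1] * np.eye(V.shape[1])
                sol = np.linalg.solve(V, np.concatenate([D, r[:, :, None]], axis=2))
            ViD, Vir = sol[:, :, :-1], sol[:, :, -1]
            LHS += np.einsum("mij,mik->jk", D, ViD)
            RHS += np.einsum("mij,mi->j", D, Vir)
        delta = np.linalg.solve(LHS, RHS)
        alpha = alpha + delta
        update_norm = float(np.max(np.abs(delta)))
        if update_norm < tol:
            converged = True
            break
    if not converged:
        flags.append("non-convergence")
    flags = list(dict.fromkeys(flags))

    # --- final per-family quantities at the converged alpha ---
    mu_l = [None] * len(families)
    A_l = [None] * len(families)
    D_l = [None] * len(families)
    V_l = [None] * len(families)
    S_l = [None] * len(families)
    esteq = np.zeros(alpha.size)
    for g in groups:
        eta = np.einsum("mij,j->mi", g.Xbig, alpha)
        if binary:
            mu = expit(eta)
            A = mu * (1.0 - mu)
        else:
            mu = eta
            A = np.ones_like(eta)
        r = g.Y - mu
        R = _kron_working(R_K, Rn_by_n[g.n])
        sa = np.sqrt(np.clip(A, 1e-12, None))
        V = R[None, :, :] * (sa[:, :, None] * sa[:, None, :]) * phi
        D = A[:, :, None] * g.Xbig
        try:
            S = np.linalg.solve(V, r[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular working covariance") from exc
        esteq += np.einsum("mij,mi->j", D, S)
        for row, i in enumerate(g.idx):
            mu_l[i] = mu[row]
            A_l[i] = A[row]
            D_l[i] = np.ones_like(A[row])
            V_l[i] = V[row]
            S_l[i] = S[row]

    wc.R_K = R_K
    wc.R_n = dict(Rn_by_n)
    return NullModelFit(
        alpha=alpha, phi=phi, wc=wc, trait_kind=trait_kind, K=K, q=q1 - 1,
        families=families, mu=mu_l, A=A_l, Delta=D_l, V=V_l, S=S_l,
        converged=converged, n_iter=it, update_norm=update_norm,
        esteq_norm=float(np.max(np.abs(esteq))), flags=flags,
    )


def standardized_residuals(fit: NullModelFit) -> list[np.ndarray]:
    """S_i solving V_i S_i = y_i - mu_i, recomputed from the stored fit."""
    out = []
    for fam, mu, V in zip(fit.families, fit.mu, fit.V):
        out.append(np.linalg.solve(V, fam.y - mu))
    return out
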