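"""Region association statistics on the joint-GEE null fit.

Five retrospective tests of a variant region against K correlated traits:

* HoK — homogeneous kernel statistic, kappa = sum_l w_l (sum_k Z_lk)^2,
  powered when the variant effects agree across traits;
* HeK — heterogeneous kernel statistic, kappa = sum_{l,k} w_lk Z_lk^2,
  powered when effects differ between traits;
* BT  — burden test collapsing the region into a weighted dosage sum,
  1-df chi-square;
* HoO / HeO — Cauchy-combination omnibus tests pairing each kernel
  p-value with the burden p-value.

"Retrospective" means genotypes are treated as random given phenotypes:
the null covariance of the scores is built from genotype moments — minor
allele frequencies m_l, the dosage correlation matrix H, and the family
relatedness matrices Omega_i — scaled by the phenotype-side quadratic
forms C_Ho (scalar) and C_He (K x K).  Kernel p-values come from the
mixture-chi-square machinery in :mod:`pleiofam.quadform`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .jgee import FamilyData, NullModelFit
from .quadform import MixtureSpec, eigen_weights, mixture_chisq_sf

__all__ = [
    "GenotypeSummary",
    "ScoreComponents",
    "TestResult",
    "genotype_summary",
    "score_components",
    "hok_test",
    "hek_test",
    "burden_test",
    "cauchy_omnibus",
    "run_all",
]

_CLIP = 1e-15  # p-value clipping for the Cauchy inverse (tan overflow guard)


@dataclass
class GenotypeSummary:
    """Genotype moments and weights for the retained variants of a region.

    Variants are folded to the minor allele (dosage flipped where the
    estimated allele frequency exceeds 1/2) and monomorphic ones dropped;
    ``kept``/``flip`` record the mapping back to the input columns.
    """

    m: np.ndarray            # MAF per retained variant, in (0, 0.5]
    H: np.ndarray            # p x p dosage correlation over all individuals
    w: np.ndarray            # homogeneous per-variant weights
    w_het: np.ndarray        # p x K heterogeneous weights (default tiled w)
    kept: np.ndarray         # indices of retained variants in the input order
    flip: np.ndarray         # bool, retained variants folded to the minor allele

    @property
    def p(self) -> int:
        return self.m.size

    def fold(self, g: np.ndarray) -> np.ndarray:
        """Apply variant filtering + minor-allele folding to a dosage matrix."""
        gk = np.asarray(g, dtype=float)[:, self.kept]
        return np.where(self.flip, 2.0 - gk, gk)


@dataclass
class ScoreComponents:
    Z: np.ndarray       # p x K score matrix
    C_Ho: float
    C_He: np.ndarray    # K x K


@dataclass
class TestResult:
    method: str
    statistic: float
    p: float
    lam: np.ndarray | None = None   # eigen-weights (kernel tests) or None
    df: int | None = None           # 1 for BT
    flags: list = field(default_factory=list)


def beta_weights(m: np.ndarray, shape: tuple[float, float]) -> np.ndarray:
    """Marker weights w_l = Beta-density(m_l; a, b); (1,1) is unweighted."""
    a, b = shape
    return beta_dist.pdf(np.asarray(m, dtype=float), a, b)


def genotype_summary(G: np.ndarray, *, founder_mask: np.ndarray | None = None,
                     weights: tuple[float, float] = (1.0, 1.0),
                     het_weights: np.ndarray | None = None,
                     K: int = 1, maf_min: float = 0.0) -> GenotypeSummary:
    """Summarize a pooled dosage matrix (individuals x variants).

    Allele frequencies are estimated on ``founder_mask`` individuals
    (default: everyone) to avoid double-counting transmitted alleles in
    pedigrees; the dosage correlation H uses all individuals.  Variants
    monomorphic in the frequency sample, or below ``maf_min`` after
    folding, are dropped.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] < 2:
        raise ValueError("need at least two individuals for the dosage correlation H")
    sub = G if founder_mask is None else G[np.asarray(founder_mask, dtype=bool)]
    freq = sub.mean(axis=0) / 2.0
    folded = np.minimum(freq, 1.0 - freq)
    kept = np.flatnonzero((folded > 0.0) & (folded >= maf_min))
    if kept.size == 0:
        raise ValueError("all variants are monomorphic (or below the MAF threshold)")
    flip = freq[kept] > 0.5
    m = folded[kept]
    Gf = np.where(flip, 2.0 - G[:, kept], G[:, kept])
    sd = Gf.std(axis=0)
    if np.any(sd == 0):
        # polymorphic in the frequency sample but constant overall cannot
        # happen when founders are a subset; guard anyway
        raise ValueError("retained variant with zero dosage variance")
    H = np.corrcoef(Gf, rowvar=False).reshape(kept.size, kept.size)
    w = beta_weights(m, weights)
    w_het = np.tile(w[:, None], (1, K)) if het_weights is None else np.asarray(het_weights, float)
    return GenotypeSummary(m=m, H=H, w=w, w_het=w_het, kept=kept, flip=flip)


def score_components(fit: NullModelFit, omegas: list[np.ndarray],
                     gs: GenotypeSummary) -> ScoreComponents:
    """Score matrix Z and phenotype-side null-variance factors.

    Z_lk = sum_i g_il' Delta_ik A_ik S_ik;
    C_Ho = sum_i u_i' Omega_i u_i with u_i = sum_k Delta_ik A_ik S_ik;
    C_He[k,k'] = sum_i (Delta_ik A_ik S_ik)' Omega_i (Delta_ik' A_ik' S_ik').
    The identity C_Ho = sum over entries of C_He is asserted.
    """
    K = fit.K
    p = gs.p
    Z = np.zeros((p, K))
    C_He = np.zeros((K, K))
    C_Ho = 0.0
    if len(omegas) != len(fit.families):
        raise ValueError("one Omega per family required")
    for fam, A, D, S, Om in zip(fit.families, fit.A, fit.Delta, fit.S, omegas):
        n = fam.n
        Om = np.asarray(Om, dtype=float)
        if Om.shape != (n, n):
            raise ValueError(f"family {fam.fid}: Omega shape {Om.shape} != ({n},{n})")
        B = (D * A * S).reshape(K, n)            # rows: Delta_ik A_ik S_ik
        g = gs.fold(fam.g)                       # n x p
        Z += g.T @ B.T
        OmB = B @ Om                             # K x n
        C_He += OmB @ B.T
        u = B.sum(axis=0)
        C_Ho += float(u @ Om @ u)
    if abs(C_Ho - C_He.sum()) > 1e-6 * max(abs(C_Ho), 1.0):
        raise AssertionError("C_Ho != sum(C_He): internal inconsistency")
    return ScoreComponents(Z=Z, C_Ho=C_Ho, C_He=(C_He + C_He.T) / 2.0)


def _hm(gs: GenotypeSummary) -> np.ndarray:
    v = np.sqrt(gs.m * (1.0 - gs.m))
    return gs.H * np.outer(v, v)


def hok_test(sc: ScoreComponents, gs: GenotypeSummary) -> TestResult:
    """Homogeneous kernel test: kappa_Ho = sum_l w_l (sum_k Z_lk)^2.

    Null covariance of the weighted scores:
    Cov0 = 2 C_Ho sqrt(w_l w_l') H_ll' sqrt(m_l(1-m_l) m_l'(1-m_l')).
    """
    if sc.C_Ho <= 0:
        raise ValueError("C_Ho must be positive")
    Zl = sc.Z.sum(axis=1)
    kappa = float(np.sum(gs.w * Zl**2))
    sw = np.sqrt(gs.w)
    M = 2.0 * sc.C_Ho * np.outer(sw, sw) * _hm(gs)
    lam = eigen_weights(M)
    res = mixture_chisq_sf(MixtureSpec(lam, kappa), full=True)
    return TestResult("HoK", kappa, res.p, lam=lam, flags=list(res.flags))


def hek_test(sc: ScoreComponents, gs: GenotypeSummary) -> TestResult:
    """Heterogeneous kernel test: kappa_He = sum_{l,k} w_lk Z_lk^2.

    Null covariance over (l,k) pairs couples variants through H/MAF and
    traits through C_He; eigen-weights come from the (pK) x (pK) matrix
    2 sqrt(w_lk w_l'k') Hm_ll' C_He[k,k'].
    """
    if sc.C_Ho <= 0:
        raise ValueError("C_Ho must be positive")
    W = gs.w_het
    kappa = float(np.sum(W * sc.Z**2))
    sw = np.sqrt(W).ravel()                       # (l,k) index = l*K + k
    M = 2.0 * np.outer(sw, sw) * np.kron(_hm(gs), sc.C_He)
    lam = eigen_weights(M)
    res = mixture_chisq_sf(MixtureSpec(lam, kappa), full=True)
    return TestResult("HeK", kappa, res.p, lam=lam, flags=list(res.flags))


def burden_test(sc: ScoreComponents, gs: GenotypeSummary) -> TestResult:
    """Burden test: collapse the region to g~ = sum_l w_l g_l, 1-df chi-square.

    Numerator (sum_i sum_k S_ik' A_ik Delta_ik g~_i)^2 reduces to
    (sum_l w_l sum_k Z_lk)^2; denominator 2 (w' Hm w) C_Ho.
    """
    Zl = sc.Z.sum(axis=1)
    num = float(np.sum(gs.w * Zl)) ** 2
    den = 2.0 * float(gs.w @ _hm(gs) @ gs.w) * sc.C_Ho
    if den <= 0:
        raise ValueError("burden denominator must be positive")
    stat = num / den
    return TestResult("BT", stat, float(chi2.sf(stat, 1)), df=1)


def cauchy_omnibus(p_a: float, p_b: float, method: str = "omnibus") -> TestResult:
    """Cauchy combination of two p-values.

    O = -(1/2)(F_C^{-1}(p_a) + F_C^{-1}(p_b)) with F_C^{-1}(p) = tan(pi(p - 1/2));
    under the null O is approximately standard Cauchy whatever the dependence,
    so p = 1/2 - arctan(O)/pi.
    """
    flags = []
    for p in (p_a, p_b):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    pa = float(np.clip(p_a, _CLIP, 1.0 - _CLIP))
    pb = float(np.clip(p_b, _CLIP, 1.0 - _CLIP))
    if pa != p_a or pb != p_b:
        flags.append("clipped")
    O = -0.5 * (np.tan(np.pi * (pa - 0.5)) + np.tan(np.pi * (pb - 0.5)))
    p = 0.5 - np.arctan(O) / np.pi
    return TestResult(method, float(O), float(min(max(p, _CLIP), 1.0)), flags=flags)


def run_all(fit: NullModelFit, omegas: list[np.ndarray], gs: GenotypeSummary,
            sc: ScoreComponents | None = None) -> dict[str, TestResult]:
    """All five tests on shared score components.

    HoO combines (p_HoK, p_BT); HeO combines (p_HeK, p_BT).
    """
    if sc is None:
        sc = score_components(fit, omegas, gs)
    hok = hok_test(sc, gs)
    hek = hek_test(sc, gs)
    bt = burden_test(sc, gs)
    hoo = cauchy_omnibus(hok.p, bt.p, "HoO")
    heo = cauchy_omnibus(hek.p, bt.p, "HeO")
    return {"HoK": hok, "HeK": hek, "BT": bt, "HoO": hoo, "HeO": heo}
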