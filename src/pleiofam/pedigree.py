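"""Pedigree structure and genetic-correlation (2x kinship) matrices.

The retrospective region tests need, for every family i, the matrix
Omega_i of expected genotype correlations between its members: twice the
kinship coefficient, with diagonal 1 for non-inbred individuals.  Omega
can come from the pedigree graph (standard kinship recursion) or be
estimated from genomic data when the true relationships are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Family",
    "PedigreeSet",
    "read_fam",
    "kinship_matrix",
    "genetic_correlation_from_pedigree",
    "genetic_correlation_genomic",
]

_SEX_CODES = {"1": "male", "2": "female"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent link, ...)."""


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Family:
    fid: str
    members: list[Individual] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.iid for m in self.members]

    def founder_mask(self) -> np.ndarray:
        return np.array([m.is_founder for m in self.members], dtype=bool)

    def _validate(self) -> None:
        if self.n < 1:
            raise PedigreeError(f"family {self.fid!r} has no members")
        ids = set(self.ids)
        if len(ids) != self.n:
            raise PedigreeError(f"duplicate individual ids in family {self.fid!r}")
        for m in self.members:
            for par in (m.father, m.mother):
                if par is not None and par not in ids:
                    raise PedigreeError(
                        f"family {self.fid!r}: parent {par!r} of {m.iid!r} not in family"
                    )

    def topological_order(self) -> list[int]:
        """Member indices with every parent before its children.

        Raises :class:`PedigreeError` on a parent-link cycle.
        """
        self._validate()
        pos = {m.iid: j for j, m in enumerate(self.members)}
        order: list[int] = []
        state = [0] * self.n  # 0 unvisited, 1 in progress, 2 done

        def visit(j: int) -> None:
            if state[j] == 2:
                return
            if state[j] == 1:
                raise PedigreeError(
                    f"cycle in parent links of family {self.fid!r} at {self.members[j].iid!r}"
                )
            state[j] = 1
            m = self.members[j]
            for par in (m.father, m.mother):
                if par is not None:
                    visit(pos[par])
            state[j] = 2
            order.append(j)

        for j in range(self.n):
            visit(j)
        return order


@dataclass
class PedigreeSet:
    families: list[Family]

    def __post_init__(self) -> None:
        for fam in self.families:
            fam._validate()

    def family(self, fid: str) -> Family:
        for fam in self.families:
            if fam.fid == fid:
                return fam
        raise KeyError(fid)

    @property
    def sample_ids(self) -> list[tuple[str, str]]:
        return [(f.fid, m.iid) for f in self.families for m in f.members]


def read_fam(path: str | Path) -> PedigreeSet:
    """Read a PLINK-style FAM file (FID IID PAT MAT SEX PHENO, whitespace).

    "0" denotes a missing parent; the phenotype column is ignored.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise PedigreeError(f"{path}: expected 6 whitespace-delimited columns")
    families: dict[str, Family] = {}
    for fid, iid, pat, mat, sex, _ in df.itertuples(index=False):
        fam = families.setdefault(str(fid), Family(str(fid)))
        fam.members.append(
            Individual(
                iid=str(iid),
                father=None if str(pat) == "0" else str(pat),
                mother=None if str(mat) == "0" else str(mat),
                sex=_SEX_CODES.get(str(sex), "unknown"),
            )
        )
    return PedigreeSet(list(families.values()))


def kinship_matrix(family: Family) -> np.ndarray:
    """Kinship coefficients Phi for one family by the standard recursion.

    Founders: Phi_jj = 1/2 and Phi_jj' = 0.  A child c of parents (f, m):
    Phi_cj = (Phi_fj + Phi_mj)/2 for j != c and Phi_cc = 1/2 + Phi_fm/2,
    a missing parent contributing kinship 0.  Handles inbreeding (diagonal
    may exceed 1/2); rows/columns follow the family's member order.
    """
    n = family.n
    pos = {m.iid: j for j, m in enumerate(family.members)}
    phi = np.zeros((n, n))
    done: list[int] = []
    for j in family.topological_order():
        m = family.members[j]
        f = pos[m.father] if m.father is not None else None
        g = pos[m.mother] if m.mother is not None else None
        for k in done:
            pf = phi[f, k] if f is not None else 0.0
            pm = phi[g, k] if g is not None else 0.0
            phi[j, k] = phi[k, j] = 0.5 * (pf + pm)
        pfm = phi[f, g] if (f is not None and g is not None) else 0.0
        phi[j, j] = 0.5 + 0.5 * pfm
        done.append(j)
    return phi


def genetic_correlation_from_pedigree(ped: PedigreeSet | Family) -> np.ndarray | dict[str, np.ndarray]:
    """Omega = 2 * Phi per family: expected genotype correlations.

    For a single :class:`Family` returns the matrix; for a
    :class:`PedigreeSet` a dict keyed by family id.
    """
    if isinstance(ped, Family):
        return 2.0 * kinship_matrix(ped)
    return {fam.fid: 2.0 * kinship_matrix(fam) for fam in ped.families}


def genetic_correlation_genomic(G: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Genomic estimate of Omega from dosages and allele frequencies.

    Omega[j,j'] = (1/p) sum_l (g_jl - 2 m_l)(g_j'l - 2 m_l) / (2 m_l (1 - m_l)),
    the diagonal included.  Monomorphic variants (m in {0,1}) must be
    filtered upstream and are rejected here.
    """
    G = np.asarray(G, dtype=float)
    m = np.asarray(m, dtype=float)
    if G.ndim != 2 or G.shape[1] != m.size or m.size < 1:
        raise ValueError("G must be n x p with p matching len(m), p >= 1")
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("monomorphic variants (m in {0,1}) must be filtered upstream")
    C = (G - 2.0 * m) / np.sqrt(2.0 * m * (1.0 - m))
    return (C @ C.T) / m.size
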