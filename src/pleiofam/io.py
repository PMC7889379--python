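"""Readers and writers for the standard file formats.

Genotypes travel as VCF (read through cyvcf2, written as plain text),
pedigrees as PLINK FAM, phenotypes/covariates and results as TSV.  The
phenotype table layout is: FID, IID, then K trait columns, then q
covariate columns; the intercept is added internally.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import PedigreeSet

__all__ = [
    "write_vcf",
    "read_vcf_dosages",
    "write_fam",
    "write_phenotypes",
    "read_phenotypes",
    "write_results",
]


def write_vcf(path: str | Path, G: np.ndarray, sample_ids: list[str], *,
              chrom: str = "1", positions: np.ndarray | None = None) -> None:
    """Write a dosage matrix (individuals x variants) as an unphased VCF."""
    G = np.asarray(G)
    n, p = G.shape
    if len(sample_ids) != n:
        raise ValueError("sample_ids length must match genotype rows")
    if positions is None:
        positions = np.arange(1, p + 1) * 100
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for l in range(p):
            calls = "\t".join(gt_map[int(G[j, l])] for j in range(n))
            fh.write(f"{chrom}\t{int(positions[l])}\tv{l}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf_dosages(path: str | Path, region: str | None = None
                     ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read alt-allele dosages from a VCF: (individuals x variants, ids, positions)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    cols, pos = [], []
    it = vcf(region) if region else vcf
    for var in it:
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.array(var.gt_types, dtype=float)
        if np.any(d == 2):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        d[d == 3] = 2.0
        cols.append(d)
        pos.append(var.POS)
    if not cols:
        raise ValueError(f"no variants found in {path} ({region or 'whole file'})")
    return np.column_stack(cols), ids, np.asarray(pos)


def write_fam(path: str | Path, ped: PedigreeSet) -> None:
    with open(path, "w") as fh:
        for fam in ped.families:
            for m in fam.members:
                sex = {"male": "1", "female": "2"}.get(m.sex, "0")
                fh.write(f"{fam.fid}\t{m.iid}\t{m.father or 0}\t{m.mother or 0}\t{sex}\t-9\n")


def write_phenotypes(path: str | Path, fids: list[str], iids: list[str],
                     traits: np.ndarray, covariates: np.ndarray,
                     trait_names: list[str] | None = None,
                     covariate_names: list[str] | None = None) -> None:
    """Phenotype/covariate TSV: FID IID traits... covariates... (no intercept)."""
    traits = np.atleast_2d(np.asarray(traits))
    covariates = np.atleast_2d(np.asarray(covariates))
    K, q = traits.shape[1], covariates.shape[1]
    tn = trait_names or [f"trait{k+1}" for k in range(K)]
    cn = covariate_names or [f"cov{j+1}" for j in range(q)]
    df = pd.DataFrame({"FID": fids, "IID": iids})
    for k, name in enumerate(tn):
        df[name] = traits[:, k]
    for j, name in enumerate(cn):
        df[name] = covariates[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, n_traits: int
                    ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Read the phenotype TSV; returns (frame, trait columns, covariate columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    if df.columns[0] != "FID" or df.columns[1] != "IID":
        raise ValueError(f"{path}: first two columns must be FID and IID")
    cols = list(df.columns[2:])
    if len(cols) < n_traits:
        raise ValueError(f"{path}: fewer than {n_traits} trait columns")
    return df, cols[:n_traits], cols[n_traits:]


def write_results(path: str | Path, rows: list[dict], header_comment: str = "") -> None:
    """Results TSV: region, method, statistic, p, n_eigen, flags."""
    df = pd.DataFrame(rows, columns=["region", "method", "statistic", "p", "n_eigen", "flags"])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
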