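"""Readers for individual-level inputs: PLINK binary, dosage TSV, VCF,
and phenotype/covariate tables.

Genotypes are returned as an n x L float matrix of effect-allele (A1) counts
with NaN for missing calls, plus sample ids and a locus metadata table; the
encoder joins phenotype/covariate tables to genotypes by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: PLINK .bed magic bytes + SNP-major flag.
_BED_MAGIC = b"\x6c\x1b\x01"

#: 2-bit .bed codes -> A1 allele count (01 = missing).
_BED_CODE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass(frozen=True)
class GenotypeData:
    """Individual-level genotypes: A1 counts (NaN = missing) plus metadata."""

    genotypes: np.ndarray  # n x L, float, NaN missing
    sample_ids: list[str]
    loci: pd.DataFrame  # SNP CHR BP A1 A2 [BIALLELIC]


def read_plink(prefix: str | Path) -> GenotypeData:
    """Read a PLINK .bed/.bim/.fam fileset (SNP-major .bed only).

    The returned genotype matrix counts copies of the .bim A1 allele.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["FID", "IID", "PAT", "MAT", "SEX", "PHENO"],
        dtype={"FID": str, "IID": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["CHR", "SNP", "CM", "BP", "A1", "A2"],
        dtype={"CHR": str, "SNP": str, "A1": str, "A2": str},
    )
    n, L = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic or not SNP-major")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * L:
        raise ValueError(
            f"{prefix}.bed: size {body.size} != {bytes_per_snp} bytes x {L} SNPs"
        )
    body = body.reshape(L, bytes_per_snp)
    # unpack the four 2-bit genotypes per byte, samples fastest
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(L, -1)[:, :n]
    G = _BED_CODE[codes].T  # n x L
    loci = bim[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    return GenotypeData(genotypes=G, sample_ids=list(fam["IID"]), loci=loci)


def read_dosage_tsv(path: str | Path) -> GenotypeData:
    """Read a plain dosage matrix: rows = samples, header = SNP ids.

    The first column is the sample id; remaining columns hold dosages in
    [0, 2] with "NA" for missing.  Allele labels are not carried by this
    format and default to A1="A", A2="B".
    """
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={0: str})
    sample_ids = df.iloc[:, 0].tolist()
    G = df.iloc[:, 1:].to_numpy(dtype=float)
    snps = list(df.columns[1:])
    loci = pd.DataFrame(
        {"SNP": snps, "CHR": "0", "BP": np.arange(1, len(snps) + 1),
         "A1": "A", "A2": "B"}
    )
    return GenotypeData(genotypes=G, sample_ids=sample_ids, loci=loci)


def write_dosage_tsv(path: str | Path, data: GenotypeData) -> None:
    """Write genotypes in the dosage TSV layout accepted by read_dosage_tsv."""
    df = pd.DataFrame(data.genotypes, columns=data.loci["SNP"])
    df.insert(0, "IID", data.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_vcf(path: str | Path) -> GenotypeData:
    """Read GT genotypes from a VCF via cyvcf2 (biallelic records only).

    Multi-allelic records are kept with BIALLELIC=False so downstream QC can
    remove them with reason "non-biallelic"; their genotypes are NaN.  The
    ALT allele is counted as A1.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, gts, flags = [], [], []
    for var in vcf:
        biallelic = len(var.ALT) == 1
        if biallelic:
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            g = np.array([0.0, 1.0, np.nan, 2.0])[var.gt_types]
        else:
            g = np.full(len(sample_ids), np.nan)
        rows.append(
            {
                "SNP": var.ID or f"{var.CHROM}:{var.POS}",
                "CHR": str(var.CHROM),
                "BP": var.POS,
                "A1": var.ALT[0] if biallelic else ",".join(var.ALT),
                "A2": var.REF,
            }
        )
        flags.append(biallelic)
        gts.append(g)
    loci = pd.DataFrame(rows)
    loci["BIALLELIC"] = flags
    return GenotypeData(
        genotypes=np.array(gts).T, sample_ids=sample_ids, loci=loci
    )


def read_table(path: str | Path, id_col: str | None = None) -> pd.DataFrame:
    """Read a phenotype/covariate TSV keyed by sample id (missing code "NA")."""
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if id_col is None:
        id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    return df.set_index(id_col)


def join_samples(
    data: GenotypeData, pheno: pd.Series, covar: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Align genotypes, phenotype and covariates on shared sample ids.

    Returns arrays in the genotype sample order, restricted to ids present in
    every table.  Missing values inside the tables are preserved as NaN for
    the encoder's own row-dropping policy.
    """
    ids = [sid for sid in data.sample_ids if sid in pheno.index]
    if covar is not None:
        ids = [sid for sid in ids if sid in covar.index]
    if not ids:
        raise ValueError("no overlapping sample ids between genotypes and tables")
    pos = {sid: i for i, sid in enumerate(data.sample_ids)}
    rows = [pos[sid] for sid in ids]
    G = data.genotypes[rows, :]
    y = pheno.loc[ids].to_numpy(dtype=float)
    Z = covar.loc[ids].to_numpy(dtype=float) if covar is not None else None
    return G, y, Z
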