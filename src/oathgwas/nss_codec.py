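"""Naive summary statistics (NSS): encoding, QC and the exchange format.

NSS are the plain variance--covariance entries of phenotype, genotype and
covariates (plus the sample size n) -- sufficient statistics from which any
least-squares GWAS model over those variables can be rebuilt without touching
individual-level data.  They split into a *generic* block shared genome-wide
(phenotype/covariate covariances, :class:`GenericNSS`) and a per-locus record
(:class:`LocusNSS`); stitching the two together yields the per-locus
sufficient-statistic matrix Phi (:class:`PhiMatrix`) ordered [y, x, z1..zm].

All covariances use denominator ``n - 1``.  The downstream estimator is
invariant to this choice because the denominator cancels between the predictor
covariance block and the residual-variance term, but encoder, reader and
writer must agree -- and here they do.

Variables are never pre-centered in storage; covariances are taken about
sample means, which is equivalent to working with centered variables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Relative symmetry tolerance for covariance blocks.
SYM_RTOL = 1e-12


class EncodeError(ValueError):
    """Raised when individual-level data cannot be encoded into NSS."""


class NSSFormatError(ValueError):
    """Raised on malformed NSS exchange files (carries a line number)."""


@dataclass(frozen=True)
class GenericNSS:
    """Generic NSS block: sample size and the covariance of [y, z1..zm].

    ``C`` is the symmetric (m+1) x (m+1) sample covariance matrix of the
    phenotype (index 0) and the m covariates, denominator n - 1.
    """

    n: int
    covariate_names: tuple[str, ...]
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        m = len(self.covariate_names)
        if C.shape != (m + 1, m + 1):
            raise ValueError(f"C has shape {C.shape}, expected {(m + 1, m + 1)}")
        scale = np.abs(C).max() or 1.0
        if np.abs(C - C.T).max() > SYM_RTOL * scale:
            raise ValueError("covariance block C is not symmetric")
        if np.any(np.diag(C) <= 0):
            raise ValueError("zero-variance phenotype or covariate in C")
        if self.n < m + 3:
            raise ValueError(
                f"n={self.n} leaves no residual degree of freedom for m={m} covariates"
            )

    @property
    def m(self) -> int:
        return len(self.covariate_names)

    @property
    def var_y(self) -> float:
        return float(self.C[0, 0])

    @property
    def cov_yz(self) -> np.ndarray:
        """Covariances of the phenotype with each covariate (length m)."""
        return self.C[0, 1:].copy()

    @property
    def C_zz(self) -> np.ndarray:
        """Covariate covariance block (m x m)."""
        return self.C[1:, 1:].copy()


@dataclass(frozen=True)
class LocusNSS:
    """Locus-specific NSS row: one SNP's covariances with y and the covariates.

    ``var_x == 0`` flags a monomorphic locus; such records are carried through
    QC and IO but are never fitted.  ``hom_rate`` is the fraction of observed
    calls that are homozygous (used by the inbred-line homozygosity filter);
    ``biallelic`` is False for loci with more than two observed alleles.
    """

    snp_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    freq_a1: float
    call_rate: float
    var_x: float
    cov_xy: float
    cov_xz: np.ndarray
    hom_rate: float | None = None
    biallelic: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "cov_xz", np.asarray(self.cov_xz, dtype=float))
        if not 0.0 <= self.freq_a1 <= 1.0:
            raise ValueError(f"{self.snp_id}: freq_a1={self.freq_a1} outside [0, 1]")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"{self.snp_id}: call_rate={self.call_rate} outside [0, 1]")
        if self.var_x < 0:
            raise ValueError(f"{self.snp_id}: negative genotype variance")

    @property
    def monomorphic(self) -> bool:
        return self.var_x == 0.0

    @property
    def maf(self) -> float:
        return min(self.freq_a1, 1.0 - self.freq_a1)

    def check_cauchy_schwarz(self, generic: GenericNSS, tol: float = 1e-9) -> None:
        """Validate |cov(x, .)| <= sqrt(var_x * var_.) for y and every z."""
        bound = np.sqrt(self.var_x * generic.var_y) + tol
        if abs(self.cov_xy) > bound:
            raise ValueError(f"{self.snp_id}: cov_xy violates Cauchy-Schwarz")
        bounds = np.sqrt(self.var_x * np.diag(generic.C_zz)) + tol
        if np.any(np.abs(self.cov_xz) > bounds):
            raise ValueError(f"{self.snp_id}: cov_xz violates Cauchy-Schwarz")


@dataclass(frozen=True)
class PhiMatrix:
    """Assembled (m+2) x (m+2) sufficient-statistic matrix, order [y, x, z1..zm]."""

    M: np.ndarray
    n: int

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 2:
            raise ValueError(f"Phi must be square of size >= 2, got {M.shape}")
        scale = np.abs(M).max() or 1.0
        if np.abs(M - M.T).max() > 1e-8 * scale:
            raise ValueError("Phi is not symmetric")
        if np.any(np.diag(M) < 0):
            raise ValueError("Phi has a negative diagonal entry")
        w = np.linalg.eigvalsh(M)
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError("Phi is not positive semi-definite within tolerance")

    @property
    def m(self) -> int:
        """Number of candidate covariates."""
        return self.M.shape[0] - 2


def _drop_incomplete_rows(
    phenotype: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop rows with a missing phenotype or covariate; return the kept mask."""
    keep = np.isfinite(phenotype)
    if covariates.size:
        keep &= np.all(np.isfinite(covariates), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with missing phenotype/covariates", dropped)
    return phenotype[keep], covariates[keep], keep


def encode_generic(
    phenotype: Sequence[float] | np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
) -> GenericNSS:
    """Encode the generic NSS block from individual-level phenotype/covariates.

    Rows with a missing (NaN) phenotype or covariate are dropped (logged)
    before encoding.  Covariances use denominator n - 1 and preserve covariate
    order.

    Raises
    ------
    EncodeError
        If any variable has zero variance (the offender is named) or if
        ``n <= m + 2`` after dropping incomplete rows.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    Z = (
        np.empty((y.size, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if Z.shape[0] != y.size:
        raise EncodeError(
            f"phenotype length {y.size} != covariate rows {Z.shape[0]}"
        )
    m = Z.shape[1]
    names = (
        tuple(covariate_names)
        if covariate_names is not None
        else tuple(f"Z{j + 1}" for j in range(m))
    )
    if len(names) != m:
        raise EncodeError(f"{len(names)} covariate names for {m} covariates")
    y, Z, _ = _drop_incomplete_rows(y, Z)
    n = y.size
    if n <= m + 2:
        raise EncodeError(f"insufficient sample size n={n} for m={m} covariates")
    V = np.column_stack([y, Z]) if m else y[:, None]
    C = np.cov(V, rowvar=False, ddof=1).reshape(m + 1, m + 1)
    diag = np.diag(C)
    if diag[0] <= 0:
        raise EncodeError("phenotype has zero variance")
    for j in range(m):
        if diag[j + 1] <= 0:
            raise EncodeError(f"covariate {names[j]!r} has zero variance")
    return GenericNSS(n=n, covariate_names=names, C=C)


def encode_locus(
    genotype: Sequence[float] | np.ndarray,
    phenotype: Sequence[float] | np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    snp_id: str,
    chrom: str = "0",
    pos: int = 0,
    a1: str = "A",
    a2: str = "B",
    dosage: bool = False,
    biallelic: bool = True,
) -> LocusNSS:
    """Encode one locus into its NSS row.

    The genotype codes counts of the effect allele a1 in {0, 1, 2} (or any
    dosage in [0, 2] when ``dosage=True``); NaN marks a missing call.  Missing
    genotypes are mean-imputed before the covariance computation so a single n
    is shared with :func:`encode_generic`; rows with a missing phenotype or
    covariate must have been dropped consistently (pass the same arrays).
    """
    g = np.asarray(genotype, dtype=float).ravel()
    y = np.asarray(phenotype, dtype=float).ravel()
    Z = (
        np.empty((y.size, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    y, Z, keep = _drop_incomplete_rows(y, Z)
    g = g[keep]
    obs = np.isfinite(g)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise EncodeError(f"{snp_id}: all genotype calls missing")
    lo, hi = np.nanmin(g), np.nanmax(g)
    if lo < 0 or hi > 2:
        raise EncodeError(f"{snp_id}: genotype value outside [0, 2]")
    if not dosage and not np.all(np.isin(g[obs], (0.0, 1.0, 2.0))):
        raise EncodeError(
            f"{snp_id}: non-integer genotype; pass dosage=True for dosages"
        )
    mean_g = float(g[obs].mean())
    freq_a1 = mean_g / 2.0
    call_rate = n_obs / g.size
    # homozygosity over observed hard calls; fractional dosages count as het
    hom_rate = float(np.mean((g[obs] == 0.0) | (g[obs] == 2.0)))
    g = np.where(obs, g, mean_g)
    n = g.size
    gc = g - g.mean()
    var_x = float(gc @ gc) / (n - 1)
    cov_xy = float(gc @ (y - y.mean())) / (n - 1)
    cov_xz = (gc @ (Z - Z.mean(axis=0))) / (n - 1) if Z.size else np.empty(0)
    return LocusNSS(
        snp_id=snp_id,
        chrom=str(chrom),
        pos=int(pos),
        a1=a1,
        a2=a2,
        freq_a1=freq_a1,
        call_rate=call_rate,
        var_x=var_x,
        cov_xy=cov_xy,
        cov_xz=np.asarray(cov_xz, dtype=float),
        hom_rate=hom_rate,
        biallelic=biallelic,
    )


def assemble_phi(generic: GenericNSS, locus: LocusNSS) -> PhiMatrix:
    """Stitch the generic block and one locus row into the Phi matrix.

    Ordering is [y, x, z1..zm]: entry (0,0) is the phenotype variance, row and
    column 1 carry the locus variance and its covariances, the trailing block
    is the generic covariate block.
    """
    m = generic.m
    if locus.cov_xz.size != m:
        raise ValueError(
            f"{locus.snp_id}: locus has {locus.cov_xz.size} covariate "
            f"covariances but generic block has m={m}"
        )
    M = np.zeros((m + 2, m + 2))
    M[0, 0] = generic.var_y
    M[0, 2:] = M[2:, 0] = generic.cov_yz
    M[2:, 2:] = generic.C_zz
    M[1, 1] = locus.var_x
    M[0, 1] = M[1, 0] = locus.cov_xy
    M[1, 2:] = M[2:, 1] = locus.cov_xz
    return PhiMatrix(M=M, n=generic.n)


def flip_allele(locus: LocusNSS) -> LocusNSS:
    """Recode the locus on the other allele: x -> 2 - x.

    Negates every genotype covariance, maps freq_a1 to 1 - freq_a1, swaps the
    allele labels and leaves the genotype variance unchanged.
    """
    return replace(
        locus,
        a1=locus.a2,
        a2=locus.a1,
        freq_a1=1.0 - locus.freq_a1,
        cov_xy=-locus.cov_xy,
        cov_xz=-locus.cov_xz,
    )


@dataclass(frozen=True)
class QCResult:
    kept: list[LocusNSS]
    removed: list[tuple[LocusNSS, str]] = field(default_factory=list)

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removed:
            out[reason] = out.get(reason, 0) + 1
        return out


def qc_filter(
    loci: Sequence[LocusNSS],
    maf_min: float = 0.05,
    callrate_min: float = 0.998,
    hom_min: float | None = None,
) -> QCResult:
    """Marker QC: drop non-biallelic, rare, badly called or heterozygous loci.

    A locus is removed iff it is non-biallelic, or min(freq, 1-freq) <
    ``maf_min`` (strict), or call_rate < ``callrate_min``, or -- when
    ``hom_min`` is given -- its homozygote fraction < ``hom_min``.  The
    homozygosity filter targets inbred-line panels, where residual
    heterozygosity indicates genotyping error; it is off by default.  Each
    removed locus carries its first failing reason; the filter is idempotent.
    """
    for name, t in (("maf_min", maf_min), ("callrate_min", callrate_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name}={t} outside [0, 1]")
    if hom_min is not None and not 0.0 <= hom_min <= 1.0:
        raise ValueError(f"hom_min={hom_min} outside [0, 1]")
    kept: list[LocusNSS] = []
    removed: list[tuple[LocusNSS, str]] = []
    for locus in loci:
        if not locus.biallelic:
            removed.append((locus, "non-biallelic"))
        elif locus.maf < maf_min:
            removed.append((locus, "maf"))
        elif locus.call_rate < callrate_min:
            removed.append((locus, "callrate"))
        elif (
            hom_min is not None
            and locus.hom_rate is not None
            and locus.hom_rate < hom_min
        ):
            removed.append((locus, "homozygosity"))
        else:
            kept.append(locus)
    return QCResult(kept=kept, removed=removed)


# ---------------------------------------------------------------------------
# Exchange format: <prefix>.gnss (JSON generic block) + <prefix>.lnss (TSV).
# Human-auditable and diff-able, mirroring the generic/locus split.

_LNSS_FIXED = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "CALLRATE", "HOM_RATE", "BIALLELIC", "VAR_X", "COV_XY"]
_FMT = "%.10g"


def write_nss(generic: GenericNSS, loci: Sequence[LocusNSS], path_prefix: str | Path) -> tuple[Path, Path]:
    """Write the NSS pair ``<prefix>.gnss`` / ``<prefix>.lnss``; %.10g precision."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gpath = prefix.with_suffix(prefix.suffix + ".gnss")
    lpath = prefix.with_suffix(prefix.suffix + ".lnss")
    gpath.write_text(
        json.dumps(
            {
                "n": generic.n,
                "covariate_names": list(generic.covariate_names),
                "C": [[float(_FMT % v) for v in row] for row in generic.C],
            },
            indent=1,
        )
        + "\n"
    )
    m = generic.m
    header = _LNSS_FIXED + [f"COV_XZ{j + 1}" for j in range(m)]
    lines = ["\t".join(header)]
    for locus in loci:
        if locus.cov_xz.size != m:
            raise ValueError(f"{locus.snp_id}: covariate count mismatch with generic block")
        row = [
            locus.snp_id,
            locus.chrom,
            str(locus.pos),
            locus.a1,
            locus.a2,
            _FMT % locus.freq_a1,
            _FMT % locus.call_rate,
            "NA" if locus.hom_rate is None else _FMT % locus.hom_rate,
            "1" if locus.biallelic else "0",
            _FMT % locus.var_x,
            _FMT % locus.cov_xy,
        ] + [_FMT % v for v in locus.cov_xz]
        lines.append("\t".join(row))
    lpath.write_text("\n".join(lines) + "\n")
    return gpath, lpath


def read_nss(path_prefix: str | Path) -> tuple[GenericNSS, list[LocusNSS]]:
    """Read an NSS pair written by :func:`write_nss`.

    Raises :class:`NSSFormatError` (with line numbers) on malformed headers,
    covariate-count mismatches between the two files, or duplicate SNP ids.
    """
    prefix = Path(path_prefix)
    gpath = prefix.with_suffix(prefix.suffix + ".gnss")
    lpath = prefix.with_suffix(prefix.suffix + ".lnss")
    try:
        blob = json.loads(gpath.read_text())
        generic = GenericNSS(
            n=int(blob["n"]),
            covariate_names=tuple(blob["covariate_names"]),
            C=np.asarray(blob["C"], dtype=float),
        )
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise NSSFormatError(f"{gpath}: malformed generic NSS ({exc})") from exc
    m = generic.m
    expected = _LNSS_FIXED + [f"COV_XZ{j + 1}" for j in range(m)]
    loci: list[LocusNSS] = []
    seen: set[str] = set()
    with open(lpath) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected:
            raise NSSFormatError(
                f"{lpath}:1: header mismatch (expected {len(expected)} columns "
                f"for m={m} covariates, got {len(header)}: {header[:4]}...)"
            )
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(expected):
                raise NSSFormatError(
                    f"{lpath}:{lineno}: expected {len(expected)} fields, got {len(fields)}"
                )
            try:
                locus = LocusNSS(
                    snp_id=fields[0],
                    chrom=fields[1],
                    pos=int(fields[2]),
                    a1=fields[3],
                    a2=fields[4],
                    freq_a1=float(fields[5]),
                    call_rate=float(fields[6]),
                    hom_rate=None if fields[7] == "NA" else float(fields[7]),
                    biallelic=fields[8] == "1",
                    var_x=float(fields[9]),
                    cov_xy=float(fields[10]),
                    cov_xz=np.array([float(v) for v in fields[11:]]),
                )
            except ValueError as exc:
                raise NSSFormatError(f"{lpath}:{lineno}: {exc}") from exc
            if locus.snp_id in seen:
                raise NSSFormatError(f"{lpath}:{lineno}: duplicate snp_id {locus.snp_id!r}")
            seen.add(locus.snp_id)
            loci.append(locus)
    return generic, loci
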