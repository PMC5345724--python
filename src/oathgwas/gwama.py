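"""Consortium-style fixed-effects meta-analysis on per-cohort NSS.

Each cohort exports one NSS file pair; the central hub aligns shared loci on
common effect alleles, reconstructs the per-cohort effect under any covariate
subset it chooses, and pools the estimates by inverse-variance weighting.
Because the reconstruction needs only the cohorts' covariance blocks,
switching the covariate model at the hub requires no re-export from the
cohorts -- the same files serve every analysis.

Covariate semantics are cohort-local (typically each cohort's own GRM
eigenvectors), so subset index j means "the cohort's j-th covariate" in every
cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kernel import LN10, DfConvention, SubsetSpec
from .nss_codec import GenericNSS, LocusNSS, flip_allele
from .scan import bonferroni_threshold, scan

logger = logging.getLogger(__name__)

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


class AlleleMismatchError(ValueError):
    """Allele pairs cannot be reconciled by swapping (strand flips not inferred)."""


@dataclass(frozen=True)
class CohortNSS:
    """One cohort's exported NSS: generic block plus loci keyed by snp_id."""

    cohort_id: str
    generic: GenericNSS
    loci: dict[str, LocusNSS]

    @classmethod
    def from_lists(
        cls, cohort_id: str, generic: GenericNSS, loci: list[LocusNSS]
    ) -> "CohortNSS":
        keyed: dict[str, LocusNSS] = {}
        for locus in loci:
            if locus.snp_id in keyed:
                raise ValueError(f"{cohort_id}: duplicate snp_id {locus.snp_id!r}")
            keyed[locus.snp_id] = locus
        return cls(cohort_id=cohort_id, generic=generic, loci=keyed)


def align_alleles(reference: tuple[str, str], cohort_locus: LocusNSS) -> LocusNSS:
    """Re-express a cohort locus on the reference effect allele.

    An identical allele pair passes through unchanged; a swapped pair flips
    the genotype coding x -> 2 - x (negating every genotype covariance and
    complementing the frequency).  Any other pair raises: strand flips are
    deliberately not inferred.
    """
    ref_a1, ref_a2 = reference
    if (cohort_locus.a1, cohort_locus.a2) == (ref_a1, ref_a2):
        return cohort_locus
    if (cohort_locus.a1, cohort_locus.a2) == (ref_a2, ref_a1):
        return flip_allele(cohort_locus)
    raise AlleleMismatchError(
        f"{cohort_locus.snp_id}: alleles {cohort_locus.a1}/{cohort_locus.a2} "
        f"incompatible with reference {ref_a1}/{ref_a2}"
    )


def meta_fixed(
    betas: np.ndarray, ses: np.ndarray
) -> tuple[float, float, float, float]:
    """Inverse-variance fixed-effects pooling of one locus across cohorts.

    Weights are 1/se^2; returns (pooled beta, pooled se, z, -log10 p) with a
    two-sided normal p computed in log space.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.size == 0:
        raise ValueError("betas and ses must be equal-length, non-empty")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / s**2
    pooled_beta = float((w * b).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = pooled_beta / pooled_se
    mlog10p = float(-(np.log(2.0) + stats.norm.logsf(abs(z))) / LN10)
    return pooled_beta, pooled_se, z, mlog10p


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Cochran's heterogeneity Q and its chi-square p-value (df = k - 1)."""
    b = np.asarray(betas, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    pooled = (w * b).sum() / w.sum()
    q = float((w * (b - pooled) ** 2).sum())
    df = b.size - 1
    p = float(stats.chi2.sf(q, df)) if df >= 1 else np.nan
    return q, p


@dataclass(frozen=True)
class MetaResult:
    """Pooled per-locus table with the significance threshold used."""

    subset: SubsetSpec
    table: pd.DataFrame
    threshold: float
    excluded: pd.DataFrame  # SNP + reason (allele-mismatch etc.)


def meta_scan(
    cohorts: list[CohortNSS],
    subset: SubsetSpec | None = None,
    alpha: float = 0.05,
    df_convention: DfConvention = "centered",
) -> MetaResult:
    """Run the chosen-subset reconstruction per cohort and pool per locus.

    Loci are intersected across cohorts by snp_id and allele-aligned to the
    first cohort; allele-incompatible loci are excluded with reason
    "allele-mismatch".  Palindromic (A/T, C/G) variants are aligned by allele
    labels only and listed in a warning.  The significance threshold is the
    Bonferroni line at the intersection size.
    """
    if not cohorts:
        raise ValueError("no cohorts given")
    if subset is None:
        subset = SubsetSpec(tuple(range(1, cohorts[0].generic.m + 1)))
    for cohort in cohorts:
        if cohort.generic.m < subset.k or any(
            i > cohort.generic.m for i in subset.included
        ):
            raise ValueError(
                f"cohort {cohort.cohort_id} exposes m={cohort.generic.m} covariates; "
                f"subset {subset.included} not available"
            )
    shared = set(cohorts[0].loci)
    for cohort in cohorts[1:]:
        shared &= set(cohort.loci)
    if not shared:
        raise ValueError("no shared snp_ids across cohorts")
    order = [sid for sid in cohorts[0].loci if sid in shared]

    reference = {
        sid: (cohorts[0].loci[sid].a1, cohorts[0].loci[sid].a2) for sid in order
    }
    palindromic = [
        sid for sid in order if frozenset(reference[sid]) in PALINDROMIC
    ]
    if palindromic:
        warnings.warn(
            f"{len(palindromic)} palindromic variants aligned by allele labels "
            f"only (first: {palindromic[:5]})",
            stacklevel=2,
        )

    excluded_rows: list[dict[str, str]] = []
    usable = []
    aligned_per_cohort: list[list[LocusNSS]] = []
    for sid in order:
        row = []
        try:
            for cohort in cohorts:
                row.append(align_alleles(reference[sid], cohort.loci[sid]))
        except AlleleMismatchError:
            excluded_rows.append({"SNP": sid, "REASON": "allele-mismatch"})
            continue
        usable.append(sid)
        aligned_per_cohort.append(row)

    n_loci = len(usable)
    betas = np.empty((n_loci, len(cohorts)))
    ses = np.empty((n_loci, len(cohorts)))
    flipped = np.zeros((n_loci, len(cohorts)), dtype=bool)
    for c, cohort in enumerate(cohorts):
        loci_c = [aligned_per_cohort[i][c] for i in range(n_loci)]
        flipped[:, c] = [
            loc.a1 != cohort.loci[loc.snp_id].a1 for loc in loci_c
        ]
        res = scan(cohort.generic, loci_c, subset, df_convention)
        betas[:, c] = res.records["BETA"].to_numpy()
        ses[:, c] = res.records["SE"].to_numpy()

    ok = np.all(np.isfinite(ses) & (ses > 0), axis=1)
    w = np.zeros_like(ses)
    w[ok] = 1.0 / ses[ok] ** 2
    wsum = w.sum(axis=1)
    pooled_beta = np.full(n_loci, np.nan)
    pooled_se = np.full(n_loci, np.nan)
    pooled_beta[ok] = (w[ok] * betas[ok]).sum(axis=1) / wsum[ok]
    pooled_se[ok] = 1.0 / np.sqrt(wsum[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = pooled_beta / pooled_se
    mlog10p = np.full(n_loci, np.nan)
    mlog10p[ok] = -(np.log(2.0) + stats.norm.logsf(np.abs(z[ok]))) / LN10

    table = pd.DataFrame(
        {
            "SNP": usable,
            "N_COHORTS": len(cohorts),
            "BETA_META": pooled_beta,
            "SE_META": pooled_se,
            "Z": z,
            "MLOG10P": mlog10p,
        }
    )
    for c, cohort in enumerate(cohorts):
        table[f"BETA_{cohort.cohort_id}"] = betas[:, c]
        table[f"SE_{cohort.cohort_id}"] = ses[:, c]
        table[f"FLIP_{cohort.cohort_id}"] = flipped[:, c]
    threshold = bonferroni_threshold(alpha, n_loci)
    return MetaResult(
        subset=subset,
        table=table,
        threshold=threshold,
        excluded=pd.DataFrame(excluded_rows, columns=["SNP", "REASON"]),
    )
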