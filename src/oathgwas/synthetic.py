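"""Seeded generators: structured genotypes, GRM eigenvector covariates,
additive phenotypes, and the worked single-locus fixture.

Population structure follows the Balding-Nichols model: each locus draws an
ancestral frequency p uniformly from the configured MAF range, subpopulation
frequencies from Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst), and genotypes
Binomial(2, p_subpop).  Fst = 0 gives a panmictic population.  The *inbred*
mode draws a haploid allele and doubles it, emulating fully homozygous inbred
lines.  Loci are independent (no linkage disequilibrium); traits are strictly
additive.

All generators take an explicit seed; nothing touches global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.linalg

from .gwama import CohortNSS
from .nss_codec import GenericNSS, LocusNSS, PhiMatrix, encode_generic, encode_locus

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated genotype/phenotype panel.

    ``causal`` lists (locus index, fraction of total phenotypic variance
    explained); fractions must sum to < 1.  ``fst`` > 0 with ``n_subpops`` > 1
    turns on Balding-Nichols structure.  ``seed`` is mandatory.
    """

    n_samples: int
    n_loci: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 1
    fst: float = 0.0
    causal: tuple[tuple[int, float], ...] = ()
    n_covariates: int = 0
    inbred: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst={self.fst} outside [0, 1)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        fracs = [f for _, f in self.causal]
        if any(f <= 0 for f in fracs) or sum(fracs) >= 1.0:
            raise ValueError("causal variance fractions must be positive and sum < 1")
        if any(not 0 <= i < self.n_loci for i, _ in self.causal):
            raise ValueError("causal locus index out of range")


@dataclass(frozen=True)
class GenotypeSim:
    """Genotype matrix (n x L, allele-count coding) with locus metadata."""

    genotypes: np.ndarray
    loci: pd.DataFrame  # SNP CHR BP A1 A2 P_ANC
    subpop: np.ndarray  # length-n subpopulation labels


def sim_genotypes(config: SimConfig) -> GenotypeSim:
    """Draw a genotype panel under the configured structure model."""
    rng = np.random.default_rng(config.seed)
    n, L = config.n_samples, config.n_loci
    p_anc = rng.uniform(*config.maf_range, size=L)
    subpop = rng.integers(config.n_subpops, size=n)
    if config.fst > 0.0 and config.n_subpops > 1:
        a = p_anc * (1.0 - config.fst) / config.fst
        b = (1.0 - p_anc) * (1.0 - config.fst) / config.fst
        p_sub = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, L))
    else:
        p_sub = np.broadcast_to(p_anc, (config.n_subpops, L))
    p_ind = p_sub[subpop, :]  # n x L
    if config.inbred:
        G = 2 * rng.binomial(1, p_ind).astype(np.int8)
    else:
        G = rng.binomial(2, p_ind).astype(np.int8)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(len(_ALLELE_PAIRS), size=L)]
    loci = pd.DataFrame(
        {
            "SNP": [f"snp{i + 1}" for i in range(L)],
            "CHR": "1",
            "BP": np.arange(1, L + 1) * 1000,
            "A1": [p[0] for p in pairs],
            "A2": [p[1] for p in pairs],
            "P_ANC": p_anc,
        }
    )
    return GenotypeSim(genotypes=G, loci=loci, subpop=subpop)


def grm(genotypes: np.ndarray) -> np.ndarray:
    """Genetic relationship matrix from allele counts.

    Each polymorphic locus is standardized by its observed mean 2p and
    standard deviation sqrt(2p(1-p)); the GRM is the average cross-product
    (1/L) sum_l w_l w_l'.  Monomorphic loci are skipped (count logged).  For
    Hardy-Weinberg data the mean diagonal is close to 1.
    """
    G = np.asarray(genotypes, dtype=float)
    p = G.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    n_skip = int((~poly).sum())
    if n_skip:
        import logging

        logging.getLogger(__name__).info("GRM: skipped %d monomorphic loci", n_skip)
    p = p[poly]
    W = (G[:, poly] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return (W @ W.T) / W.shape[1]


def top_eigenvectors(K: np.ndarray, k: int) -> np.ndarray:
    """Unit-norm eigenvectors of the k largest eigenvalues of a GRM.

    Columns are ordered by decreasing eigenvalue and mutually orthogonal;
    each column's sign is fixed so its largest-magnitude entry is positive
    (a degenerate spectrum still yields an orthonormal, reproducible basis,
    though which basis is then arbitrary).  Because the GRM's columns of
    standardized genotypes are centered, every eigenvector off the null space
    has exactly zero mean -- their sample covariance matrix is diagonal.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if n > 512 and k < n // 4:
        v0 = np.linspace(1.0, 2.0, n)  # deterministic ARPACK start
        vals, vecs = scipy.sparse.linalg.eigsh(K, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
    else:
        vals, vecs = np.linalg.eigh(K)
        order = np.argsort(vals)[::-1][:k]
    V = vecs[:, order]
    signs = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    return V * signs


def sim_phenotype(
    genotypes: np.ndarray,
    causal: tuple[tuple[int, float], ...] = (),
    covariates: np.ndarray | None = None,
    covariate_effects: np.ndarray | None = None,
    seed: int = 0,
    standardize: bool = False,
) -> np.ndarray:
    """Additive phenotype: causal standardized genotypes + covariates + noise.

    Each causal locus contributes sqrt(fraction) times its standardized
    genotype, so its marginal variance share matches the spec up to sampling
    error; the noise variance is set to 1 minus the causal and covariate
    shares, for unit total variance in expectation.
    """
    rng = np.random.default_rng(seed)
    G = np.asarray(genotypes, dtype=float)
    n = G.shape[0]
    y = np.zeros(n)
    explained = 0.0
    for idx, frac in causal:
        g = G[:, idx]
        sd = g.std(ddof=1)
        if sd == 0:
            raise ValueError(f"causal locus {idx} is monomorphic")
        y += np.sqrt(frac) * (g - g.mean()) / sd
        explained += frac
    if covariates is not None and covariate_effects is not None:
        zy = np.asarray(covariates) @ np.asarray(covariate_effects)
        y += zy - zy.mean()
        explained += float(np.var(zy, ddof=1))
    noise_var = 1.0 - explained
    if noise_var <= 0.0:
        raise ValueError(f"infeasible variance budget: explained={explained:.3f} >= 1")
    y += rng.normal(scale=np.sqrt(noise_var), size=n)
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
    return y


def encode_panel(
    sim: GenotypeSim,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> tuple[GenericNSS, list[LocusNSS]]:
    """Encode a simulated panel into its NSS representation."""
    generic = encode_generic(phenotype, covariates, covariate_names)
    loci = [
        encode_locus(
            sim.genotypes[:, j],
            phenotype,
            covariates,
            snp_id=row.SNP,
            chrom=row.CHR,
            pos=int(row.BP),
            a1=row.A1,
            a2=row.A2,
        )
        for j, row in enumerate(sim.loci.itertuples(index=False))
    ]
    return generic, loci


# ---------------------------------------------------------------------------
# Worked single-locus fixture: a biallelic locus of MAF 0.23 with zero true
# effect, three independent N(0,1) covariates, an N(0,1) phenotype, n = 200.
# The covariance entries below are the published rendering of that sample,
# rounded for display -- downstream checks against it use display-rounding
# tolerances rather than exact equality.

_WORKED_PHI = np.array(
    [
        [1.0, -0.005, 0.092, -0.121, 0.113],
        [-0.005, 0.338, -0.035, 0.0063, -0.0505],
        [0.092, -0.035, 1.0, 0.0608, 0.0506],
        [-0.121, 0.0063, 0.0608, 1.0, 0.0083],
        [0.113, -0.0505, 0.0506, 0.0083, 1.0],
    ]
)


def worked_example_phi() -> PhiMatrix:
    """The demonstration 5x5 Phi (order [y, x, z1, z2, z3]) with n = 200."""
    return PhiMatrix(M=_WORKED_PHI.copy(), n=200)


@dataclass(frozen=True)
class TwoCohortSim:
    """Two-cohort meta-analysis panel sharing one causal locus."""

    cohorts: list[CohortNSS]
    causal_snp: str
    truth: dict = field(default_factory=dict)


def sim_two_cohorts(
    seed: int = 0,
    n_samples: tuple[int, int] = (3191, 2309),
    n_loci: int = 9124,
    causal_frac: float = 0.05,
    n_covariates: int = 3,
    fst: float = 0.01,
    n_subpops: int = 2,
) -> TwoCohortSim:
    """Emulate a two-cohort consortium exchange on one chromosome.

    Defaults mirror the demonstration design: cohorts of 3191 and 2309
    samples, 9124 shared common variants, one causal locus explaining 5% of
    the phenotypic variance in each cohort, and three GRM-eigenvector
    covariates per cohort (covariates are cohort-local).  Mild two-subpopulation
    structure (Fst = 0.01) makes the eigenvectors informative.  Both cohorts
    draw subpopulation allele frequencies from the same ancestral pool, so
    their loci share ids and allele labels.
    """
    rng = np.random.default_rng(seed)
    master = sim_genotypes(
        SimConfig(
            n_samples=2,  # only used for frequencies/metadata; regenerated per cohort
            n_loci=n_loci,
            maf_range=(0.05, 0.5),
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    causal_idx = n_loci // 2
    causal_snp = str(master.loci.loc[causal_idx, "SNP"])
    cohorts: list[CohortNSS] = []
    for cid, n in zip(("NA", "SLE"), n_samples):
        cfg = SimConfig(
            n_samples=n,
            n_loci=n_loci,
            maf_range=(0.05, 0.5),
            n_subpops=n_subpops,
            fst=fst,
            seed=int(rng.integers(2**31 - 1)),
        )
        sim = sim_genotypes(cfg)
        # share locus metadata (ids, positions, alleles) across cohorts
        sim = GenotypeSim(
            genotypes=sim.genotypes, loci=master.loci, subpop=sim.subpop
        )
        y = sim_phenotype(
            sim.genotypes,
            causal=((causal_idx, causal_frac),),
            seed=int(rng.integers(2**31 - 1)),
            standardize=True,
        )
        K = grm(sim.genotypes)
        V = top_eigenvectors(K, n_covariates)
        generic, loci = encode_panel(
            sim, y, V, [f"EV{j + 1}" for j in range(n_covariates)]
        )
        cohorts.append(CohortNSS.from_lists(cid, generic, loci))
    return TwoCohortSim(
        cohorts=cohorts,
        causal_snp=causal_snp,
        truth={"causal_index": causal_idx, "causal_frac": causal_frac},
    )
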