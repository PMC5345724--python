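"""Least-squares reconstruction from the sufficient-statistic matrix Phi.

For a centered multiple-regression GWAS model y = x*b_snp + Z_s*b_s + e the
least-squares solution depends on the data only through the covariance matrix
Phi of [y, x, z1..zm].  Writing Omega for Phi restricted to the chosen
predictors, Lambda = diag(Omega), and b-hat for the vector of *marginal*
single-predictor coefficients b_j = cov(y, v_j)/var(v_j), the multiple
regression coefficients are

    beta = Omega^{-1} Lambda b_hat

with covariance

    cov(beta) = ((var_y - beta' Lambda b_hat) / df) * Omega^{-1}.

Any covariate subset s of the m candidates can be fitted this way from the
same Phi -- no individual-level data, and no re-export, is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import linalg, stats

from .nss_codec import PhiMatrix

#: Reciprocal-condition-number threshold below which Omega is treated as singular.
RCOND_MIN = 1e-12

LN10 = np.log(10.0)

DfConvention = Literal["centered", "ols"]


class CollinearityError(np.linalg.LinAlgError):
    """Omega for the requested covariate subset is numerically singular."""


class MonomorphicError(ValueError):
    """The locus has zero genotype variance and cannot be fitted."""


@dataclass(frozen=True)
class SubsetSpec:
    """An ordered set of 1-based covariate indices; empty = naive model."""

    included: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "included", tuple(int(i) for i in self.included))
        if len(set(self.included)) != len(self.included):
            raise ValueError(f"duplicate covariate indices in {self.included}")
        if any(i < 1 for i in self.included):
            raise ValueError("covariate indices are 1-based")

    @property
    def k(self) -> int:
        return len(self.included)

    def validate(self, m: int) -> None:
        if any(i > m for i in self.included):
            raise ValueError(f"subset {self.included} out of range for m={m}")

    def mask_string(self, m: int) -> str:
        """Render as +/- inclusion mask, e.g. ``+-+--`` for {1,3} with m=5."""
        self.validate(m)
        return "".join("+" if j + 1 in self.included else "-" for j in range(m))

    @classmethod
    def from_mask(cls, mask: str) -> "SubsetSpec":
        """Parse an inclusion mask; accepts ASCII ``-`` and the minus glyph."""
        included = []
        for j, ch in enumerate(mask):
            if ch == "+":
                included.append(j + 1)
            elif ch not in "-−":
                raise ValueError(f"bad mask character {ch!r} in {mask!r}")
        return cls(tuple(included))

    @classmethod
    def all_subsets(cls, m: int, include_empty: bool = True) -> Iterable["SubsetSpec"]:
        """All 2^m (or 2^m - 1) covariate subsets, smallest first."""
        from itertools import combinations

        for k in range(0 if include_empty else 1, m + 1):
            for combo in combinations(range(1, m + 1), k):
                yield cls(combo)


@dataclass(frozen=True)
class ModelFit:
    """One locus fitted under one covariate subset.

    ``beta``/``se``/``t`` are ordered SNP first, then the included covariates;
    ``b_hat`` holds the marginal coefficients the reconstruction started from.
    ``degenerate`` flags a fit whose computed residual variance was negative
    (numerically possible) and was clamped at zero.
    """

    subset: SubsetSpec
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    sigma2_resid: float
    mlog10p: float
    b_hat: np.ndarray
    degenerate: bool = False

    @property
    def beta_snp(self) -> float:
        return float(self.beta[0])

    @property
    def se_snp(self) -> float:
        return float(self.se[0])

    @property
    def t_snp(self) -> float:
        return float(self.t[0])


def split_phi(phi: PhiMatrix, subset: SubsetSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (Omega, Lambda, b_hat) for the predictors [x, z_s] from Phi.

    Omega is Phi restricted to the predictor rows/columns, Lambda its
    diagonal, and b_hat the marginal coefficients cov(y, v)/var(v) of each
    retained predictor.
    """
    subset.validate(phi.m)
    idx = np.array([1] + [i + 1 for i in subset.included], dtype=int)
    omega = phi.M[np.ix_(idx, idx)]
    lam = np.diag(omega).copy()
    b_hat = phi.M[0, idx] / lam
    return omega, lam, b_hat


def mlog10_p_from_t(t: float | np.ndarray, df: int | np.ndarray) -> float | np.ndarray:
    """Two-sided -log10 p for a t statistic, computed in log space.

    Never underflows to p = 0: the survival function is evaluated on the log
    scale, so |t| = 50 at df = 100 still yields a finite -log10 p.
    """
    if np.any(np.asarray(df) < 1):
        raise ValueError("df must be >= 1")
    logp = np.log(2.0) + stats.t.logsf(np.abs(t), df)
    out = -logp / LN10
    return float(out) if np.isscalar(t) else out


def oath_fit(
    phi: PhiMatrix,
    subset: SubsetSpec | None = None,
    df_convention: DfConvention = "centered",
) -> ModelFit:
    """Reconstruct the multiple-regression fit for one locus and one subset.

    Parameters
    ----------
    phi
        Assembled sufficient-statistic matrix for the locus.
    subset
        Covariate subset to include (default: all m candidates, the
        saturated model).
    df_convention
        Residual degrees of freedom for a subset of size k: ``"centered"`` uses
        n - k - 1; ``"ols"`` uses n - k - 2, matching a with-intercept
        least-squares fit on centered data.  The two differ by a factor
        sqrt((n-k-1)/(n-k-2)) in the standard errors.

    Raises
    ------
    MonomorphicError
        If the locus genotype variance is zero.
    CollinearityError
        If Omega for the subset has reciprocal condition number < 1e-12.
    """
    if subset is None:
        subset = SubsetSpec(tuple(range(1, phi.m + 1)))
    if phi.M[1, 1] <= 0.0:
        raise MonomorphicError("monomorphic locus: var_x = 0")
    omega, lam, b_hat = split_phi(phi, subset)
    k = subset.k
    rhs = lam * b_hat  # = cov([x, z_s], y)
    # SPD factorization first; pivoted LU as fallback for indefinite input
    try:
        cho = linalg.cho_factor(omega, lower=True)
        beta = linalg.cho_solve(cho, rhs)
        omega_inv_diag = np.diag(linalg.cho_solve(cho, np.eye(k + 1)))
    except linalg.LinAlgError:
        lu, piv = linalg.lu_factor(omega)
        if np.abs(np.diag(lu)).min() <= RCOND_MIN * np.abs(np.diag(lu)).max():
            raise CollinearityError(
                f"singular Omega for covariate subset {subset.included}"
            ) from None
        beta = linalg.lu_solve((lu, piv), rhs)
        omega_inv_diag = np.diag(linalg.lu_solve((lu, piv), np.eye(k + 1)))
    # explicit conditioning guard (cho_factor succeeds on near-singular input)
    w = np.linalg.eigvalsh(omega)
    if w[0] <= RCOND_MIN * w[-1]:
        raise CollinearityError(f"singular Omega for covariate subset {subset.included}")
    df = phi.n - k - 1 if df_convention == "centered" else phi.n - k - 2
    if df < 1:
        raise ValueError(f"no residual degrees of freedom (n={phi.n}, k={k})")
    sigma2 = float(phi.M[0, 0] - beta @ rhs)
    degenerate = sigma2 < 0.0
    sigma2 = max(sigma2, 0.0)
    var_beta = (sigma2 / df) * omega_inv_diag
    se = np.sqrt(np.maximum(var_beta, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    t = np.nan_to_num(t, nan=0.0)
    mlog10p = float(mlog10_p_from_t(float(t[0]), df)) if se[0] > 0 else np.inf
    return ModelFit(
        subset=subset,
        beta=beta,
        se=se,
        t=t,
        df=df,
        sigma2_resid=sigma2,
        mlog10p=mlog10p,
        b_hat=b_hat,
        degenerate=degenerate,
    )
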