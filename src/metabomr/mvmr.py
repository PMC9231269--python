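"""Multivariable MR: joint direct effects, conditional instrument strength,
and heterogeneity.

With K exposures instrumented by L SNPs (L > K), the direct effects theta
solve the weighted regression of the SNP-outcome effects on the L x K matrix
of SNP-exposure effects, without intercept:

    theta_hat = (Bx' W Bx)^-1 Bx' W by,   W = diag(1 / sy_j^2).

Instrument strength for exposure k *given the others* is the conditional
F-statistic: the minimised weighted residual sum of squares Q_x,k of
regressing exposure k's SNP effects on the other exposures' SNP effects,
with per-SNP variances built from the SNP-effect SEs and a phenotypic
correlation matrix rho (cov approximated as rho * se * se), divided by
L - K + 1.  A conditional F above ~10 indicates the model is unlikely to
suffer substantial weak-instrument bias.  Outlying instruments are flagged
by the Q-statistic with L - K - 1 degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import GwasSummaryTable
from .harmonise import (
    HarmonisedSet,
    LdMatrix,
    MAF_PALINDROME_LIMIT,
    R2_CLUMP,
    _align_outcome,
    is_palindromic,
)
from .uvmr import Z_95, _normal_p

__all__ = [
    "MvmrError",
    "CollinearityError",
    "MvmrDataset",
    "MvmrResult",
    "assemble_mvmr",
    "mvmr_ivw",
    "conditional_f",
    "mvmr_q",
]

logger = logging.getLogger("metabomr.mvmr")


class MvmrError(ValueError):
    pass


class CollinearityError(MvmrError):
    pass


@dataclass
class MvmrDataset:
    """Harmonised multi-exposure instrument panel for MVMR."""

    exposure_ids: list[str]
    snp_ids: list[str]
    Bx: np.ndarray  # L x K SNP-exposure effects
    Sx: np.ndarray  # L x K their SEs
    by: np.ndarray  # L SNP-outcome effects
    sy: np.ndarray  # L their SEs
    rho: np.ndarray | None = None  # K x K phenotypic correlations

    def __post_init__(self) -> None:
        self.Bx = np.atleast_2d(np.asarray(self.Bx, dtype=float))
        self.Sx = np.atleast_2d(np.asarray(self.Sx, dtype=float))
        self.by = np.asarray(self.by, dtype=float).ravel()
        self.sy = np.asarray(self.sy, dtype=float).ravel()
        L, K = self.Bx.shape
        if len(self.exposure_ids) != K or len(self.snp_ids) != L:
            raise MvmrError("exposure/snp id lengths inconsistent with Bx shape")
        if self.Sx.shape != (L, K) or self.by.shape != (L,) or self.sy.shape != (L,):
            raise MvmrError("inconsistent array dimensions")
        if not (np.all(self.Sx > 0) and np.all(self.sy > 0)):
            raise MvmrError("all SEs must be positive")
        if L <= K:
            raise MvmrError(f"underidentified: L={L} instruments for K={K} exposures")
        if self.rho is None:
            warnings.warn(
                "no phenotypic correlation matrix supplied; using the identity. "
                "Conditional F-statistics will ignore exposure correlation.",
                stacklevel=2,
            )
            self.rho = np.eye(K)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (K, K):
            raise MvmrError(f"rho shape {self.rho.shape} != ({K}, {K})")
        if not np.allclose(self.rho, self.rho.T, atol=1e-8):
            raise MvmrError("rho not symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-8):
            raise MvmrError("rho diagonal is not 1")
        if np.any(np.abs(self.rho) > 1 + 1e-8):
            raise MvmrError("|rho| exceeds 1")

    @property
    def L(self) -> int:
        return self.Bx.shape[0]

    @property
    def K(self) -> int:
        return self.Bx.shape[1]


@dataclass
class MvmrResult:
    """Joint direct-effect estimates with conditional Fs and Q diagnostics."""

    exposure_ids: list[str]
    estimates: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    conditional_f: np.ndarray
    q_stat: float
    q_df: int
    q_p: float
    n_snps: int
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure_id": self.exposure_ids,
                "estimate": self.estimates,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pvalue": self.pvalues,
                "conditional_F": self.conditional_f,
                "n_snps": self.n_snps,
                "Q": self.q_stat,
                "Q_df": self.q_df,
                "Q_p": self.q_p,
            }
        )


def assemble_mvmr(
    candidates: Sequence[HarmonisedSet],
    exposure_tables: Mapping[str, GwasSummaryTable],
    outcome: GwasSummaryTable,
    ld: LdMatrix,
    rho: np.ndarray | None = None,
    r2_threshold: float = R2_CLUMP,
    maf_palindrome_limit: float = MAF_PALINDROME_LIMIT,
) -> MvmrDataset:
    """Pool per-trait instruments into one cross-trait MVMR panel.

    Instruments from all candidate sets are pooled, ranked by their minimum
    p-value across the candidate exposures, and greedily clumped at
    ``r2_threshold`` so that no retained SNP for one trait is in LD with a
    retained SNP for another.  Every retained SNP's effect and SE is then
    looked up in *every* candidate exposure table (an absent SNP is an
    error), aligned to a common effect allele, and harmonised to the outcome.
    """
    if len(candidates) < 2:
        raise MvmrError("MVMR needs at least 2 candidate exposures")
    exposure_ids = [c.exposure_id for c in candidates]
    for eid in exposure_ids:
        if eid not in exposure_tables:
            raise MvmrError(f"no exposure table supplied for candidate '{eid}'")

    pooled: dict[str, float] = {}
    for cand in candidates:
        for rec in cand.records:
            best = pooled.get(rec.snp_id, np.inf)
            for eid in exposure_ids:
                tab = exposure_tables[eid]
                if rec.snp_id in tab:
                    best = min(best, tab.get(rec.snp_id).pvalue)
            pooled[rec.snp_id] = best

    ranked = sorted(pooled, key=lambda s: (pooled[s], s))
    missing_ld = [s for s in ranked if s not in ld]
    if missing_ld:
        logger.warning("%d pooled SNP(s) absent from LD matrix, dropped", len(missing_ld))
        ranked = [s for s in ranked if s in ld]
    retained: list[str] = []
    for snp in ranked:
        if all(ld.r2(snp, a) < r2_threshold for a in retained):
            retained.append(snp)

    ref_table = exposure_tables[exposure_ids[0]]
    snp_ids: list[str] = []
    bx_rows, sx_rows, by_rows, sy_rows = [], [], [], []
    for snp in retained:
        for eid in exposure_ids:
            if snp not in exposure_tables[eid]:
                raise MvmrError(f"SNP '{snp}' absent from exposure table '{eid}'")
        if snp not in ref_table or snp not in outcome:
            raise MvmrError(f"SNP '{snp}' absent from reference/outcome table")
        ref = ref_table.get(snp)
        row_b, row_s, ok = [], [], True
        for eid in exposure_ids:
            rec = exposure_tables[eid].get(snp)
            aligned = _aligned_beta(ref, rec, maf_palindrome_limit)
            if aligned is None:
                ok = False
                break
            row_b.append(aligned)
            row_s.append(rec.se)
        if not ok:
            logger.warning("SNP '%s' dropped during MVMR assembly (ambiguous alleles)", snp)
            continue
        out_aligned = _aligned_beta(ref, outcome.get(snp), maf_palindrome_limit)
        if out_aligned is None:
            logger.warning("SNP '%s' dropped: outcome alleles ambiguous", snp)
            continue
        snp_ids.append(snp)
        bx_rows.append(row_b)
        sx_rows.append(row_s)
        by_rows.append(out_aligned)
        sy_rows.append(outcome.get(snp).se)

    if len(snp_ids) <= len(exposure_ids):
        raise MvmrError(
            f"underidentified: {len(snp_ids)} instruments for {len(exposure_ids)} exposures "
            "after cross-trait clumping"
        )
    return MvmrDataset(
        exposure_ids=exposure_ids,
        snp_ids=snp_ids,
        Bx=np.array(bx_rows),
        Sx=np.array(sx_rows),
        by=np.array(by_rows),
        sy=np.array(sy_rows),
        rho=rho,
    )


def _aligned_beta(ref, rec, maf_palindrome_limit: float) -> float | None:
    """Beta of ``rec`` aligned to ``ref``'s effect allele (None if ambiguous)."""
    aligned = _align_outcome(ref, rec)
    if aligned is None:
        return None
    beta, eaf, _ = aligned
    if is_palindromic(ref.effect_allele, ref.other_allele):
        if ref.eaf is None or eaf is None:
            return None
        if min(ref.eaf, 1 - ref.eaf) > maf_palindrome_limit or min(eaf, 1 - eaf) > maf_palindrome_limit:
            return None
        if (ref.eaf - 0.5) * (eaf - 0.5) < 0:
            beta = -beta
    return beta


def mvmr_ivw(data: MvmrDataset) -> MvmrResult:
    """IVW multivariable regression of by on Bx (no intercept).

    SEs use the weighted-regression covariance with residual scale bounded
    below by 1 (the same capped-multiplicative convention as univariable
    IVW).  Conditional F-statistics (per exposure) and the Q-statistic with
    L - K - 1 degrees of freedom are attached.
    """
    L, K = data.L, data.K
    W = data.sy**-2
    Xw = data.Bx * W[:, None]
    A = data.Bx.T @ Xw  # K x K normal matrix
    if np.linalg.cond(A) > 1e10:
        raise CollinearityError(
            "exposure SNP-effect columns are (near-)collinear; prune genetically "
            "correlated traits before MVMR"
        )
    b = data.Bx.T @ (W * data.by)
    theta = np.linalg.solve(A, b)
    resid = data.by - data.Bx @ theta
    rss_w = float(np.sum(W * resid**2))
    scale = max(1.0, rss_w / (L - K))
    cov = np.linalg.inv(A) * scale
    se = np.sqrt(np.diag(cov))
    q, q_df, q_p = mvmr_q(data, theta)
    cond_f = np.array([conditional_f(data, k) for k in range(K)])
    z = theta / se
    return MvmrResult(
        exposure_ids=list(data.exposure_ids),
        estimates=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        pvalues=np.array([_normal_p(v) for v in z]),
        conditional_f=cond_f,
        q_stat=q,
        q_df=q_df,
        q_p=q_p,
        n_snps=L,
        diagnostics={"residual_scale": scale},
    )


def conditional_f(
    data: MvmrDataset, k: int, tol: float = 1e-8, max_iter: int = 100
) -> float:
    """Conditional F-statistic of exposure ``k`` given the other exposures.

    Minimises Q_x,k(delta) = sum_j (Bx_jk - delta' Bx_j,-k)^2 / v_j(delta)
    over delta by iterating weighted least squares with the per-SNP variance

        v_j = Sx_jk^2 + sum_{l,m != k} delta_l delta_m rho_lm Sx_jl Sx_jm
              - 2 sum_{l != k} delta_l rho_kl Sx_jk Sx_jl

    held fixed within each step, until delta moves by less than ``tol``.
    Pairwise covariances of SNP-effect estimates are approximated as
    rho * se * se from the phenotypic correlation matrix.  The statistic is
    Q_x,k(delta_hat) / (L - K + 1); with K = 1 it reduces exactly to the
    mean F-statistic.
    """
    L, K = data.L, data.K
    bk = data.Bx[:, k]
    sk = data.Sx[:, k]
    if K == 1:
        return float(np.sum((bk / sk) ** 2)) / (L - K + 1)
    others = [i for i in range(K) if i != k]
    Bo = data.Bx[:, others]  # L x (K-1)
    So = data.Sx[:, others]
    rho = data.rho
    rho_oo = rho[np.ix_(others, others)]  # (K-1) x (K-1)
    rho_ko = rho[k, others]  # (K-1)

    def v_of(delta: np.ndarray) -> np.ndarray:
        Sd = So * delta[None, :]  # L x (K-1), delta_l * Sx_jl
        quad = np.einsum("jl,lm,jm->j", Sd, rho_oo, Sd)
        cross = 2.0 * sk * (Sd @ rho_ko)
        return sk**2 + quad - cross

    delta = _wls_no_intercept(Bo, bk, sk**-2)
    trace = []
    for _ in range(max_iter):
        v = v_of(delta)
        if np.any(v <= 0):
            raise MvmrError("invalid covariance approximation: non-positive v_j")
        new = _wls_no_intercept(Bo, bk, 1.0 / v)
        step = float(np.max(np.abs(new - delta)))
        trace.append(step)
        delta = new
        if step < tol:
            break
    else:
        raise MvmrError(
            f"conditional F IWLS did not converge in {max_iter} iterations; "
            f"last steps: {trace[-5:]}"
        )
    v = v_of(delta)
    if np.any(v <= 0):
        raise MvmrError("invalid covariance approximation: non-positive v_j")
    q_x = float(np.sum((bk - Bo @ delta) ** 2 / v))
    return q_x / (L - K + 1)


def _wls_no_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    return np.linalg.solve(X.T @ Xw, X.T @ (w * y))


def mvmr_q(data: MvmrDataset, theta: np.ndarray) -> tuple[float, int, float]:
    """Q-statistic for outlying instruments at effect estimates ``theta``.

    Q = sum_j (by_j - theta' Bx_j)^2 / sy_j^2 with L - K - 1 degrees of
    freedom, compared against the upper chi-square tail.
    """
    L, K = data.L, data.K
    df = L - K - 1
    if df <= 0:
        raise MvmrError(f"Q degrees of freedom non-positive: L={L}, K={K}")
    theta = np.asarray(theta, dtype=float).ravel()
    resid = data.by - data.Bx @ theta
    q = float(np.sum((resid / data.sy) ** 2))
    return q, df, float(stats.chi2.sf(q, df))
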