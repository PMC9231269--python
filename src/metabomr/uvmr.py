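"""Univariable two-sample MR estimators and diagnostics.

The causal effect theta of an exposure X on an outcome Y is estimated from
per-SNP association pairs (beta_Xj, beta_Yj).  With a single instrument the
Wald ratio beta_Y/beta_X applies; with several, the inverse-variance-weighted
(IVW) estimator — a weighted regression of beta_Y on beta_X through the
origin with weights 1/se_Yj^2:

    theta_hat = sum_j w_j beta_Xj beta_Yj / sum_j w_j beta_Xj^2 ,
    w_j = se_Yj^-2.

Heterogeneity across per-SNP ratios is measured by Cochran's Q with K-1
degrees of freedom; instrument strength by the mean F-statistic,
mean_j (beta_Xj / se_Xj)^2.  The default IVW standard error uses a
multiplicative random-effects residual scale bounded below by 1 ("capped
multiplicative"): the fixed-effect SE is inflated by the residual standard
deviation when the data are overdispersed, never deflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy import stats

from .harmonise import HarmonisedRecord, HarmonisedSet

__all__ = [
    "MrResult",
    "wald_ratio",
    "ivw",
    "mean_f",
    "leave_one_out",
    "run_uvmr",
    "Z_95",
]

Z_95 = 1.959963984540054  # normal 97.5% quantile; one CI convention throughout
_P_FLOOR = 5e-324  # smallest subnormal double, keeps p in (0, 1]


def _normal_p(z: float) -> float:
    return max(2.0 * float(stats.norm.sf(abs(z))), _P_FLOOR)


@dataclass
class MrResult:
    """One univariable MR estimate with its uncertainty and diagnostics."""

    exposure_id: str
    outcome_id: str
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    diagnostics: dict = field(default_factory=dict)
    reason: str | None = None  # set when no estimate could be produced

    @property
    def is_missing(self) -> bool:
        return self.reason is not None

    def row(self) -> dict:
        d = {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
            "reason": self.reason or "",
        }
        for key in ("Q", "Q_df", "Q_p", "mean_F"):
            d[key] = self.diagnostics.get(key, np.nan)
        return d


def wald_ratio(
    r: HarmonisedRecord, exposure_id: str = "", outcome_id: str = ""
) -> MrResult:
    """Single-instrument causal estimate: beta_y / beta_x.

    The standard error is first-order delta method, se_y / |beta_x| (the
    uncertainty of beta_x is ignored, the usual convention for a
    genome-wide-significant instrument).
    """
    if r.beta_x == 0:
        raise ZeroDivisionError(f"{r.snp_id}: Wald ratio undefined for beta_x = 0")
    est = r.beta_y / r.beta_x
    se = r.se_y / abs(r.beta_x)
    return MrResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method="wald_ratio",
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se),
        n_snps=1,
        diagnostics={"snp_id": r.snp_id},
    )


def ivw(hset: HarmonisedSet, re_mode: str = "capped_multiplicative") -> MrResult:
    """Inverse-variance-weighted estimate over K >= 2 instruments.

    ``re_mode``:
      * ``"capped_multiplicative"`` (default) — SE = fixed-effect SE times
        max(1, sqrt(Q / (K - 1)));
      * ``"fixed"`` — plain fixed-effect SE.
    """
    k = hset.n_snps
    if k < 2:
        raise ValueError(f"IVW needs >= 2 instruments, got {k}; use wald_ratio")
    if re_mode not in {"capped_multiplicative", "fixed"}:
        raise ValueError(f"unknown re_mode '{re_mode}'")
    bx, _, by, sy = hset.arrays()
    w = sy**-2
    sxx = float(np.sum(w * bx * bx))
    if sxx <= 0:
        raise ZeroDivisionError("all exposure effects are zero")
    est = float(np.sum(w * bx * by)) / sxx
    q = float(np.sum(w * (by - est * bx) ** 2))
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, q_df))
    se_fixed = math.sqrt(1.0 / sxx)
    scale = max(1.0, q / q_df) if re_mode == "capped_multiplicative" else 1.0
    se = se_fixed * math.sqrt(scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bx != 0, by / bx, np.nan)
    return MrResult(
        exposure_id=hset.exposure_id,
        outcome_id=hset.outcome_id,
        method="ivw",
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se),
        n_snps=k,
        diagnostics={
            "Q": q,
            "Q_df": q_df,
            "Q_p": q_p,
            "re_mode": re_mode,
            "per_snp_ratios": ratios.tolist(),
        },
    )


def mean_f(hset: HarmonisedSet) -> float:
    """Mean instrument-strength F-statistic, mean_j (beta_Xj / se_Xj)^2."""
    if hset.n_snps == 0:
        raise ValueError("mean F undefined for an empty instrument set")
    bx, sx, _, _ = hset.arrays()
    return float(np.mean((bx / sx) ** 2))


def leave_one_out(hset: HarmonisedSet) -> list[tuple[str, MrResult]]:
    """Refit IVW K times, omitting one SNP each time (requires K >= 3)."""
    k = hset.n_snps
    if k < 3:
        raise ValueError(f"leave-one-out needs >= 3 instruments, got {k}")
    out = []
    for i, rec in enumerate(hset.records):
        sub = HarmonisedSet(
            exposure_id=hset.exposure_id,
            outcome_id=hset.outcome_id,
            records=hset.records[:i] + hset.records[i + 1 :],
        )
        out.append((rec.snp_id, ivw(sub)))
    return out


def run_uvmr(hset: HarmonisedSet, re_mode: str = "capped_multiplicative") -> MrResult:
    """Automated method dispatch on instrument count.

    K = 0 -> missing result with a reason (no exception); K = 1 -> Wald
    ratio; K >= 2 -> IVW with Cochran's Q and the mean F-statistic attached.
    """
    k = hset.n_snps
    if k == 0:
        return MrResult(
            exposure_id=hset.exposure_id,
            outcome_id=hset.outcome_id,
            method="none",
            estimate=float("nan"),
            se=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            pvalue=float("nan"),
            n_snps=0,
            reason="no_instruments",
        )
    if k == 1:
        res = wald_ratio(hset.records[0], hset.exposure_id, hset.outcome_id)
        res.diagnostics["mean_F"] = mean_f(hset)
        return res
    res = ivw(hset, re_mode=re_mode)
    res.diagnostics["mean_F"] = mean_f(hset)
    return res
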