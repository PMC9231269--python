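"""Pleiotropy-robust univariable MR estimators.

IVW is consistent only when every instrument affects the outcome solely
through the exposure.  Three estimators relax that assumption differently:

* **MR-Egger** — weighted regression of beta_Y on beta_X *with* an
  intercept.  Under the INSIDE assumption (pleiotropic effects independent
  of instrument strength) the slope is a consistent causal estimate and the
  intercept estimates the average directional pleiotropy.
* **Weighted median** — the ratio estimate at 50% of cumulative inverse-
  variance weight; consistent when at least half of the weight comes from
  valid instruments.
* **Weighted mode** — the maximiser of a weighted kernel density of the
  per-SNP ratios; consistent when the largest homogeneous cluster of
  instruments is valid.

Median and mode SEs come from a seeded parametric bootstrap (effect
estimates redrawn from normals centred on the observed values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .harmonise import HarmonisedSet
from .uvmr import MrResult, Z_95, _normal_p

__all__ = ["EggerResult", "mr_egger", "weighted_median", "weighted_mode"]


@dataclass
class EggerResult:
    """MR-Egger slope (causal estimate) and intercept (mean pleiotropy)."""

    slope: MrResult
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def _ratios_and_weights(hset: HarmonisedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ZeroDivisionError("per-SNP ratio undefined: beta_x = 0 present")
    return by / bx, bx**2 / sy**2


def mr_egger(hset: HarmonisedSet) -> EggerResult:
    """Weighted regression of beta_Y on beta_X with an intercept.

    Records are first oriented so every beta_X >= 0 (negating both betas
    where needed), which makes the intercept well defined.  Standard errors
    use the weighted-regression covariance with residual scale bounded below
    by 1, the same convention as IVW.
    """
    k = hset.n_snps
    if k < 3:
        raise ValueError(f"MR-Egger needs >= 3 instruments, got {k}")
    bx, _, by, sy = hset.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise ValueError("MR-Egger collinearity: no variation in |beta_x|")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=sy**-2).fit()
    scale = max(1.0, float(fit.scale))  # fit.scale = weighted RSS / (K - 2)
    se = np.sqrt(np.diag(fit.normalized_cov_params) * scale)
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    slope_se, intercept_se = float(se[1]), float(se[0])
    slope_res = MrResult(
        exposure_id=hset.exposure_id,
        outcome_id=hset.outcome_id,
        method="mr_egger",
        estimate=slope,
        se=slope_se,
        ci_low=slope - Z_95 * slope_se,
        ci_high=slope + Z_95 * slope_se,
        pvalue=_normal_p(slope / slope_se),
        n_snps=k,
    )
    return EggerResult(
        slope=slope_res,
        intercept=intercept,
        intercept_se=intercept_se,
        intercept_pvalue=_normal_p(intercept / intercept_se),
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios ``theta`` with weights ``w``.

    With weights normalised to sum 1 and ratios sorted ascending, the
    cumulative midpoint of ratio j is p_j = cumsum(w)_j - w_j/2; the median
    interpolates theta linearly in p at 0.5 (clamped at the extremes).
    """
    order = np.argsort(theta, kind="stable")
    t, wn = theta[order], w[order] / w[order].sum()
    p = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, p, t))


def _bootstrap_draws(
    hset: HarmonisedSet, boot_reps: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric-bootstrap (theta*, w*) arrays of shape (boot_reps, K)."""
    bx, sx, by, sy = hset.arrays()
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(boot_reps, bx.size))
    bys = rng.normal(by, sy, size=(boot_reps, by.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = bys / bxs
    w = bxs**2 / sy**2
    return theta, w


def weighted_median(
    hset: HarmonisedSet, boot_reps: int = 1000, seed: int | None = None
) -> MrResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Per-SNP ratios theta_j = beta_Yj/beta_Xj are weighted by the first-order
    inverse variance of the ratio, w_j = beta_Xj^2 / se_Yj^2.
    """
    if hset.n_snps < 3:
        raise ValueError(f"weighted median needs >= 3 instruments, got {hset.n_snps}")
    theta, w = _ratios_and_weights(hset)
    est = _weighted_median(theta, w)
    ts, ws = _bootstrap_draws(hset, boot_reps, seed)
    boot = np.array([_weighted_median(ts[b], ws[b]) for b in range(boot_reps)])
    se = float(np.std(boot, ddof=1))
    return MrResult(
        exposure_id=hset.exposure_id,
        outcome_id=hset.outcome_id,
        method="weighted_median",
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se) if se > 0 else float("nan"),
        n_snps=hset.n_snps,
        diagnostics={"boot_reps": boot_reps, "seed": seed},
    )


def _bandwidth(theta: np.ndarray, phi: float) -> float:
    """Modified Silverman bandwidth: phi * 0.9 * min(SD, 1.4826*MAD) * K^(-1/5).

    The min is taken over the *positive* spread measures so that a zero MAD
    with genuinely spread ratios falls back to the SD; it is 0 only when the
    ratios are all identical.
    """
    k = theta.size
    sd = float(np.std(theta, ddof=1)) if k > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(theta - np.median(theta))))
    spreads = [s for s in (sd, mad) if s > 0]
    if not spreads:
        return 0.0
    return phi * 0.9 * min(spreads) * k ** (-1.0 / 5.0)


def _kde_argmax_grid(theta: np.ndarray, w: np.ndarray, h: float, n_grid: int = 512):
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    i = int(np.argmax(dens))
    return grid, i


_INV_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section_max(f, a: float, b: float, tol: float = 1e-12) -> float:
    c = b - _INV_GOLDEN * (b - a)
    d = a + _INV_GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol * (1.0 + abs(a) + abs(b)):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _INV_GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INV_GOLDEN * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _weighted_mode(theta: np.ndarray, w: np.ndarray, phi: float, refine: bool) -> float:
    h = _bandwidth(theta, phi)
    if h == 0.0:
        return float(theta[0])
    grid, i = _kde_argmax_grid(theta, w, h)
    if not refine:
        return float(grid[i])
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]

    def dens(t: float) -> float:
        return float(np.exp(-0.5 * ((t - theta) / h) ** 2) @ w)

    return _golden_section_max(dens, lo, hi)


def weighted_mode(
    hset: HarmonisedSet,
    phi: float = 1.0,
    boot_reps: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Weighted-mode causal estimate with parametric-bootstrap SE.

    The estimate maximises the weighted Gaussian kernel density of the
    per-SNP ratios (weights as in :func:`weighted_median`); the argmax is
    located on a 512-point grid spanning [min - 3h, max + 3h] and refined by
    golden-section search.  Bootstrap replicates use the grid argmax only.
    If the bandwidth degenerates to 0 (identical ratios) the common ratio is
    returned with its bootstrap SE.
    """
    if hset.n_snps < 3:
        raise ValueError(f"weighted mode needs >= 3 instruments, got {hset.n_snps}")
    theta, w = _ratios_and_weights(hset)
    est = _weighted_mode(theta, w, phi, refine=True)
    ts, ws = _bootstrap_draws(hset, boot_reps, seed)
    boot = np.array(
        [_weighted_mode(ts[b], ws[b], phi, refine=False) for b in range(boot_reps)]
    )
    se = float(np.std(boot, ddof=1))
    return MrResult(
        exposure_id=hset.exposure_id,
        outcome_id=hset.outcome_id,
        method="weighted_mode",
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se) if se > 0 else float("nan"),
        n_snps=hset.n_snps,
        diagnostics={"boot_reps": boot_reps, "seed": seed, "phi": phi},
    )
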