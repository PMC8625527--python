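"""Two-sample Mendelian-randomization estimators.

All estimators operate on harmonized instrument tables (one row per SNP
with exposure and outcome effects referring to the same effect allele;
see :mod:`simpomr.harmonize`).  The per-SNP causal estimate is the Wald
ratio beta_out / beta_exp; instruments are combined by

* IVW — inverse-variance-weighted mean of ratios with first-order
  weights w_j = beta_exp_j^2 / se_out_j^2, equivalent to weighted
  regression of beta_out on beta_exp through the origin.  The default
  multiplicative random-effects model inflates the fixed-effect SE by
  max(1, sqrt(Q / (J - 1))).
* Weighted median — the interpolated weighted median of ratios, a
  consistent estimator when at least half the total weight comes from
  valid instruments; SE by parametric bootstrap.
* MR-Egger — weighted regression of beta_out on beta_exp with a free
  intercept after orienting all pairs to beta_exp >= 0.  The slope is
  the causal estimate under InSIDE; the intercept estimates average
  directional pleiotropy, with p > 0.05 read as "no evidence of
  pleiotropy".

Diagnostics: Cochran's Q heterogeneity statistic and leave-one-out IVW.
Estimates are reported both on the beta scale and as odds ratios
exp(beta) with 95% Wald intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MrEstimate",
    "PleiotropyTest",
    "HeterogeneityTest",
    "wald_ratio",
    "ivw_estimate",
    "weighted_median_estimate",
    "egger_estimate",
    "cochran_q",
    "leave_one_out",
    "to_odds_ratio",
]

_Z95 = 1.96


@dataclass(frozen=True)
class MrEstimate:
    """A causal estimate from one MR method, on the beta and OR scales."""

    method: str
    beta: float
    se: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_snps: int


@dataclass(frozen=True)
class PleiotropyTest:
    """MR-Egger intercept: average directional pleiotropy per instrument."""

    intercept: float
    se: float
    p_value: float


@dataclass(frozen=True)
class HeterogeneityTest:
    """Cochran's Q for dispersion of per-SNP ratios around a center."""

    q_stat: float
    df: int
    p_value: float


def _columns(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = pairs["beta_exp"].to_numpy(dtype=float)
    sx = pairs["se_exp"].to_numpy(dtype=float)
    by = pairs["beta_out"].to_numpy(dtype=float)
    sy = pairs["se_out"].to_numpy(dtype=float)
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("all standard errors must be positive")
    return bx, sx, by, sy


def _ivw_weights(bx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    # first-order weights: 1 / Var(wald ratio) with exposure treated as fixed
    return bx**2 / sy**2


def _estimate(method: str, beta: float, se: float, p: float, n: int) -> MrEstimate:
    or_, lo, hi = to_odds_ratio(beta, se)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        p_value=float(p),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=int(n),
    )


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Per-SNP causal estimate: ratio and its first-order delta-method SE."""
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def ivw_estimate(
    pairs: pd.DataFrame,
    model: str = "multiplicative_random",
    *,
    allow_single: bool = False,
) -> MrEstimate:
    """Inverse-variance-weighted causal estimate.

    ``model="fixed"`` uses se = sqrt(1/sum(w)); the default
    ``"multiplicative_random"`` inflates it by max(1, sqrt(Q/(J-1))),
    so it never undercuts the fixed-effect SE.  ``allow_single`` relaxes
    the two-instrument minimum, in which case the estimate is the single
    Wald ratio.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError("model must be 'fixed' or 'multiplicative_random'")
    j = len(pairs)
    minimum = 1 if allow_single else 2
    if j < minimum:
        raise ValueError(f"IVW requires >= {minimum} instruments, got {j}")
    bx, _, by, sy = _columns(pairs)
    if np.any(bx == 0):
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    w = _ivw_weights(bx, sy)
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    if model == "multiplicative_random" and j >= 2:
        q = float(np.sum(w * (ratios - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (j - 1)))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return _estimate("ivw", beta, se, p, j)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    pos = np.cumsum(w) - 0.5 * w
    if 0.5 <= pos[0]:
        return float(r[0])
    if 0.5 >= pos[-1]:
        return float(r[-1])
    return float(np.interp(0.5, pos, r))


def weighted_median_estimate(
    pairs: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the inverse-variance-weighted
    median of the Wald ratios.  The SE is the standard deviation of the
    estimate over ``n_boot`` parametric resamples of (beta_exp,
    beta_out) from normal distributions centred on the observed effects
    with the reported SEs; ``seed`` makes it reproducible.
    """
    j = len(pairs)
    if j < 3:
        raise ValueError(f"weighted median requires >= 3 instruments, got {j}")
    bx, sx, by, sy = _columns(pairs)
    if np.any(bx == 0):
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    w = _ivw_weights(bx, sy)
    beta = _weighted_median(by / bx, w)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        boot[b] = _weighted_median(by_b / bx_b, _ivw_weights(bx_b, sy))
    se = float(np.std(boot, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return _estimate("weighted_median", beta, se, p, j)


def egger_estimate(pairs: pd.DataFrame) -> tuple[MrEstimate, PleiotropyTest]:
    """MR-Egger regression: causal slope plus pleiotropy-intercept test.

    Pairs are oriented so that beta_exp >= 0 (both betas sign-flipped
    together; Egger is not orientation-invariant).  Weighted least
    squares of beta_out on beta_exp with intercept, weights 1/se_out^2,
    solved from the weighted normal equations.  Both SEs carry the
    residual scale factor max(1, sqrt(Q_egger / (J - 2))); p-values use
    a t(J-2) reference.
    """
    j = len(pairs)
    if j < 3:
        raise ValueError(f"MR-Egger requires >= 3 instruments, got {j}")
    bx, _, by, sy = _columns(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip
    if np.allclose(bx, bx[0]):
        raise ValueError("MR-Egger slope not identifiable: all exposure effects equal")

    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    cov_unscaled = np.linalg.inv(xtwx)
    resid = by - x @ coef
    q_egger = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q_egger / (j - 2)))
    se = np.sqrt(np.diag(cov_unscaled)) * scale

    df = j - 2
    t_slope = coef[1] / se[1]
    t_int = coef[0] / se[0]
    p_slope = 2.0 * stats.t.sf(abs(t_slope), df)
    p_int = 2.0 * stats.t.sf(abs(t_int), df)
    return (
        _estimate("egger", coef[1], se[1], p_slope, j),
        PleiotropyTest(intercept=float(coef[0]), se=float(se[0]), p_value=float(p_int)),
    )


def cochran_q(pairs: pd.DataFrame, center: float, df: int | None = None) -> HeterogeneityTest:
    """Cochran's Q: weighted squared dispersion of Wald ratios.

    ``df`` defaults to J - 1, appropriate when ``center`` is the IVW
    estimate; pass J - 2 for residual heterogeneity around an Egger fit.
    """
    j = len(pairs)
    if j < 2:
        raise ValueError(f"Cochran's Q requires >= 2 instruments, got {j}")
    bx, _, by, sy = _columns(pairs)
    w = _ivw_weights(bx, sy)
    q = float(np.sum(w * (by / bx - center) ** 2))
    if df is None:
        df = j - 1
    return HeterogeneityTest(q_stat=q, df=int(df), p_value=float(stats.chi2.sf(q, df)))


def leave_one_out(
    pairs: pd.DataFrame, model: str = "multiplicative_random"
) -> pd.DataFrame:
    """IVW re-estimated with each instrument excluded in turn.

    Returns one row per excluded SNP, in input order, with the combined
    estimate of the remaining J - 1 instruments.
    """
    if len(pairs) < 3:
        raise ValueError(f"leave-one-out requires >= 3 instruments, got {len(pairs)}")
    rows = []
    for i in range(len(pairs)):
        rest = pairs.drop(pairs.index[i])
        est = ivw_estimate(rest, model=model, allow_single=True)
        rows.append(
            {
                "excluded_snp": pairs.iloc[i]["snp"],
                "beta": est.beta,
                "se": est.se,
                "p_value": est.p_value,
            }
        )
    return pd.DataFrame(rows)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Convert a log-scale estimate to an OR with a 95% Wald interval."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - _Z95 * se)),
        float(np.exp(beta + _Z95 * se)),
    )
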