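"""Two-sample MR estimators on harmonised summary data.

Per-SNP Wald ratios feed the inverse-variance-weighted (IVW) estimator
(fixed or multiplicative random effects), MR-Egger regression, and the
weighted-median estimator with a parametric-bootstrap SE.  Cochran's Q / I²
quantify heterogeneity across per-SNP ratios, and the same fixed-effects
machinery serves subgroup-heterogeneity contrasts between published
estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2, norm, t as t_dist

from .errors import DomainError, EmptyInputError, InsufficientVariantsError
from .summary_stats import HarmonisationResult, HarmonisedVariant

Z95 = 1.959964  # 95% CI multiplier

#: exposure SD in milligravities of mean acceleration
SD_MILLIGRAVITY = 8.14


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio: causal log OR per exposure unit."""

    rsid: str
    theta: float
    se_theta: float
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se_theta <= 0.0:
            raise DomainError(f"{self.rsid}: se_theta must be > 0")
        self.weight = 1.0 / (self.se_theta * self.se_theta)


@dataclass
class MrResult:
    """One method's causal estimate with inference and diagnostics."""

    method: str
    beta: float
    se: float
    n_snps: int
    pvalue: float
    effects_model: str = "fixed"
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    i2: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    degenerate: bool = False
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.or_ = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - Z95 * self.se)
        self.ci_high = math.exp(self.beta + Z95 * self.se)


@dataclass
class SubgroupHeterogeneity:
    q_stat: float
    df: int
    pvalue: float
    i2_percent: float


def _variants(harmonised) -> list[HarmonisedVariant]:
    if isinstance(harmonised, HarmonisationResult):
        return list(harmonised.variants)
    return list(harmonised)


def wald_ratios(harmonised, outcome: str = "outcome") -> list[RatioEstimate]:
    """Per-SNP ratio estimates theta = beta_out/beta_exp, SE by delta method.

    Variants with a zero exposure beta are excluded with a warning (the ratio
    is undefined).
    """
    ratios: list[RatioEstimate] = []
    excluded = 0
    for v in _variants(harmonised):
        out = v.outcomes[outcome]
        if v.exposure.beta == 0.0:
            excluded += 1
            continue
        ratios.append(
            RatioEstimate(
                rsid=v.rsid,
                theta=out.beta / v.exposure.beta,
                se_theta=out.se / abs(v.exposure.beta),
            )
        )
    if excluded:
        warnings.warn(
            f"{excluded} variant(s) excluded from Wald ratios (exposure beta = 0)",
            stacklevel=2,
        )
    return ratios


def cochran_q(ratios: Sequence[RatioEstimate]) -> tuple[float, int, float, float]:
    """Cochran's Q about the fixed-effect IVW estimate; returns (Q, df, p, I²%)."""
    if len(ratios) < 2:
        raise InsufficientVariantsError("Cochran's Q requires >= 2 ratios")
    w = np.array([r.weight for r in ratios])
    th = np.array([r.theta for r in ratios])
    pooled = float(np.sum(w * th) / np.sum(w))
    q = float(np.sum(w * (th - pooled) ** 2))
    df = len(ratios) - 1
    p = float(chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p, i2


def ivw(ratios: Sequence[RatioEstimate], effects: str = "fixed") -> MrResult:
    """Inverse-variance-weighted pooling of Wald ratios.

    ``effects``: 'fixed', 'random' (multiplicative SE inflation by
    sqrt(Q/(J−1)), floored at 1), or 'auto' (random when Q p-value <= 0.05).
    A single ratio yields a degenerate result equal to that ratio.
    """
    if effects not in ("fixed", "random", "auto"):
        raise DomainError(f"unknown effects mode {effects!r}")
    ratios = list(ratios)
    if not ratios:
        raise EmptyInputError("ivw: no ratio estimates")
    if len(ratios) == 1:
        r = ratios[0]
        p = 2.0 * float(norm.sf(abs(r.theta) / r.se_theta))
        return MrResult(
            method="ivw_fixed", beta=r.theta, se=r.se_theta, n_snps=1,
            pvalue=p, effects_model="fixed", degenerate=True,
        )
    w = np.array([r.weight for r in ratios])
    th = np.array([r.theta for r in ratios])
    sw = float(np.sum(w))
    beta = float(np.sum(w * th) / sw)
    se_fixed = sw ** -0.5
    q, df, qp, i2 = cochran_q(ratios)
    model = effects
    if effects == "auto":
        model = "random" if qp <= 0.05 else "fixed"
    se = se_fixed if model == "fixed" else se_fixed * max(1.0, math.sqrt(q / df))
    p = 2.0 * float(norm.sf(abs(beta) / se))
    return MrResult(
        method=f"ivw_{model}", beta=beta, se=se, n_snps=len(ratios), pvalue=p,
        effects_model=model, q_stat=q, q_df=df, q_pvalue=qp, i2=i2,
    )


def mr_egger(harmonised, outcome: str = "outcome") -> MrResult:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Exposure betas are oriented non-negative first (the estimator is not
    orientation invariant).  Weights are 1/se_out²; SEs use multiplicative
    overdispersion floored at 1.  The intercept test (directional pleiotropy)
    is a t-test on J − 2 df; the slope p-value uses the normal reference.
    """
    variants = _variants(harmonised)
    j = len(variants)
    if j < 3:
        raise InsufficientVariantsError(f"MR-Egger requires >= 3 variants, got {j}")
    bx = np.array([v.exposure.beta for v in variants])
    by = np.array([v.outcomes[outcome].beta for v in variants])
    sy = np.array([v.outcomes[outcome].se for v in variants])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise DomainError("MR-Egger slope unidentifiable: all exposure betas equal")
    w = 1.0 / sy**2
    x_mat = np.column_stack([np.ones(j), bx])
    xtw = x_mat.T * w
    cov_unscaled = np.linalg.inv(xtw @ x_mat)
    coef = cov_unscaled @ (xtw @ by)
    resid = by - x_mat @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    infl = max(1.0, math.sqrt(sigma2))
    se_coef = np.sqrt(np.diag(cov_unscaled)) * infl
    slope, slope_se = float(coef[1]), float(se_coef[1])
    icept, icept_se = float(coef[0]), float(se_coef[0])
    slope_p = 2.0 * float(norm.sf(abs(slope) / slope_se))
    icept_p = 2.0 * float(t_dist.sf(abs(icept) / icept_se, j - 2))
    # heterogeneity about the Egger fit (Rucker's Q)
    q = float(np.sum(w * resid**2))
    df = j - 2
    return MrResult(
        method="egger", beta=slope, se=slope_se, n_snps=j, pvalue=slope_p,
        effects_model="random" if sigma2 > 1 else "fixed",
        q_stat=q, q_df=df, q_pvalue=float(chi2.sf(q, df)),
        i2=max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0,
        egger_intercept=icept, egger_intercept_se=icept_se,
        egger_intercept_p=icept_p,
    )


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by interpolation of cumulative standardised weights.

    Ratios are ordered ascending; s_j = (cumsum(w)_j − w_j/2) / sum(w); the
    estimate interpolates theta against s at s = 0.5.
    """
    order = np.argsort(theta)
    th = np.asarray(theta, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, th))


def weighted_median(
    harmonised,
    outcome: str = "outcome",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MrResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Each bootstrap draw resamples every (beta_exp, beta_out) pair from normal
    distributions with their reported SEs, recomputes the weighted median,
    and the SE is the standard deviation over draws.  Fully determined by
    ``seed``.
    """
    variants = _variants(harmonised)
    j = len(variants)
    if j < 3:
        raise InsufficientVariantsError(
            f"weighted median requires >= 3 variants, got {j}"
        )
    bx = np.array([v.exposure.beta for v in variants])
    sx = np.array([v.exposure.se for v in variants])
    by = np.array([v.outcomes[outcome].beta for v in variants])
    sy = np.array([v.outcomes[outcome].se for v in variants])
    theta = by / bx
    w = (bx / sy) ** 2  # 1/se_theta^2 under the delta method
    est = weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    boots = np.empty(n_boot)
    for k in range(n_boot):
        th_b = by_b[k] / bx_b[k]
        w_b = (bx_b[k] / sy) ** 2
        boots[k] = weighted_median_point(th_b, w_b)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * float(norm.sf(abs(est) / se))
    return MrResult(
        method="weighted_median", beta=est, se=se, n_snps=j, pvalue=p,
    )


def scale_to_sd(result: MrResult, sd_units: float = SD_MILLIGRAVITY) -> MrResult:
    """Rescale a per-measurement-unit estimate to per-SD of exposure.

    Multiplies beta and se by ``sd_units`` and recomputes OR/CI; the p-value
    is scale invariant.  ``sd_units = 1`` is the identity.
    """
    if sd_units <= 0.0:
        raise DomainError(f"sd_units must be > 0, got {sd_units}")
    return MrResult(
        method=result.method,
        beta=result.beta * sd_units,
        se=result.se * sd_units,
        n_snps=result.n_snps,
        pvalue=result.pvalue,
        effects_model=result.effects_model,
        q_stat=result.q_stat,
        q_df=result.q_df,
        q_pvalue=result.q_pvalue,
        i2=result.i2,
        egger_intercept=result.egger_intercept,
        egger_intercept_se=result.egger_intercept_se,
        egger_intercept_p=result.egger_intercept_p,
        degenerate=result.degenerate,
    )


def subgroup_heterogeneity(estimates: Iterable) -> SubgroupHeterogeneity:
    """Fixed-effects Q / I² across subgroup estimates.

    Each estimate is either ``(log_or, se)`` or ``(odds_ratio, ci_low,
    ci_high)``; in the latter case the SE is reconstructed as
    ``(ln hi − ln lo) / (2·1.96)``.
    """
    betas, ses = [], []
    for est in estimates:
        if len(est) == 2:
            b, s = float(est[0]), float(est[1])
        elif len(est) == 3:
            or_, lo, hi = (float(x) for x in est)
            if not 0 < lo < hi:
                raise DomainError(f"invalid CI ({lo}, {hi})")
            b = math.log(or_)
            s = (math.log(hi) - math.log(lo)) / (2.0 * 1.96)
        else:
            raise DomainError("estimates must be (beta, se) or (OR, lo, hi)")
        if s <= 0:
            raise DomainError(f"non-positive se {s}")
        betas.append(b)
        ses.append(s)
    if len(betas) < 2:
        raise InsufficientVariantsError("need >= 2 subgroup estimates")
    w = 1.0 / np.array(ses) ** 2
    b = np.array(betas)
    pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(betas) - 1
    return SubgroupHeterogeneity(
        q_stat=q,
        df=df,
        pvalue=float(chi2.sf(q, df)),
        i2_percent=max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0,
    )
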