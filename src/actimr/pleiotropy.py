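"""Pleiotropy diagnostics: MR-PRESSO, leave-one-out, SNP exclusion, MVMR.

MR-PRESSO is a simulation test on the leave-one-out residual sum of squares:
each SNP's outcome beta is compared with the IVW prediction fitted without
that SNP, and the observed weighted RSS is referred to a parametric null
simulated from the reported standard errors.  Flagged outliers are removed
for an "after" estimate, and a distortion test asks whether the before/after
shift exceeds what removing random SNP subsets produces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import CollinearityError, EmptyInputError, InsufficientVariantsError
from .mr_estimators import MrResult, ivw, wald_ratios
from .summary_stats import Instrument

#: rsids previously associated with adiposity traits, excluded in the
#: adiposity sensitivity analysis
ADIPOSITY_RSIDS = (
    "rs34517439",
    "rs6775319",
    "rs11012732",
    "rs1550435",
    "rs59499656",
)


@dataclass
class PressoResult:
    global_rss_observed: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]  # Bonferroni-corrected, capped at 1
    outlier_rsids: list[str]
    estimate_before: MrResult
    estimate_after: MrResult | None
    distortion_pvalue: float | None
    n_sim: int
    seed: int | None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every SNP, vectorised.

    IVW slope = sum(w·bx·by) / sum(w·bx²); leaving SNP j out subtracts its
    terms from the sums.
    """
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx * bx) - w * bx * bx
    return num / den


def mr_presso(
    harmonised,
    outcome: str = "outcome",
    n_sim: int = 5_000,
    significance: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Per-SNP outlier p-values are empirical tail probabilities of the observed
    weighted squared residual within the simulated null, Bonferroni-corrected
    across SNPs; SNPs below ``significance`` after correction are flagged.
    Empirical p-values are floored at 1/n_sim.  Fully seeded.
    """
    from .summary_stats import HarmonisationResult

    variants = (
        list(harmonised.variants)
        if isinstance(harmonised, HarmonisationResult)
        else list(harmonised)
    )
    j = len(variants)
    if j < 4:
        raise InsufficientVariantsError(f"MR-PRESSO requires >= 4 variants, got {j}")
    rsids = [v.rsid for v in variants]
    bx = np.array([v.exposure.beta for v in variants])
    sx = np.array([v.exposure.se for v in variants])
    by = np.array([v.outcomes[outcome].beta for v in variants])
    sy = np.array([v.outcomes[outcome].se for v in variants])
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, j))
    num = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True) - w * bx_sim * by_sim
    den = np.sum(w * bx_sim**2, axis=1, keepdims=True) - w * bx_sim**2
    resid_sim = w * (by_sim - (num / den) * bx_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)

    global_p = max(float(np.mean(rss_sim >= rss_obs)), 1.0 / n_sim)
    raw_p = np.maximum(np.mean(resid_sim >= resid_obs, axis=0), 1.0 / n_sim)
    corrected = np.minimum(raw_p * j, 1.0)
    outliers = [rsids[i] for i in range(j) if corrected[i] < significance]

    ratios = wald_ratios(variants, outcome)
    before = ivw(ratios, effects="fixed")
    after = None
    distortion_p = None
    if outliers:
        keep = [r for r in ratios if r.rsid not in outliers]
        if len(keep) >= 1:
            after = ivw(keep, effects="fixed")
            # distortion null: remove random subsets of the same size
            n_out = len(outliers)
            d_obs = after.beta - before.beta
            d_null = np.empty(n_sim)
            idx = np.arange(j)
            for k in range(n_sim):
                drop = rng.choice(idx, size=n_out, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                b_k = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(
                    w[mask] * bx[mask] ** 2
                )
                d_null[k] = b_k - before.beta
            distortion_p = max(
                float(np.mean(np.abs(d_null) >= abs(d_obs))), 1.0 / n_sim
            )
    return PressoResult(
        global_rss_observed=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=dict(zip(rsids, corrected.tolist())),
        outlier_rsids=outliers,
        estimate_before=before,
        estimate_after=after,
        distortion_pvalue=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(harmonised, outcome: str = "outcome") -> list[tuple[str, MrResult]]:
    """IVW (auto effects) on every J−1 subset plus the all-SNP estimate.

    Returns ``[(excluded_rsid, result), ..., ("none", overall)]``.
    """
    ratios = wald_ratios(harmonised, outcome)
    if len(ratios) < 3:
        raise InsufficientVariantsError(
            f"leave-one-out requires >= 3 variants, got {len(ratios)}"
        )
    results = []
    for i in range(len(ratios)):
        subset = ratios[:i] + ratios[i + 1 :]
        results.append((ratios[i].rsid, ivw(subset, effects="auto")))
    results.append(("none", ivw(ratios, effects="auto")))
    return results


def exclude_snps(instrument: Instrument, rsids) -> Instrument:
    """New instrument without the named variants; strength metadata recomputed.

    Absent rsids are ignored with a warning; removing every variant is an
    error.
    """
    rsids = list(rsids)
    present = set(instrument.rsids)
    missing = [r for r in rsids if r not in present]
    if missing:
        warnings.warn(f"rsids not in instrument, ignored: {missing}", stacklevel=2)
    keep = [v for v in instrument.variants if v.rsid not in set(rsids)]
    if not keep:
        raise EmptyInputError(f"excluding {rsids} empties instrument {instrument.name}")
    return Instrument(
        name=f"{instrument.name}_excl{len(instrument) - len(keep)}",
        variants=keep,
        exposure_unit=instrument.exposure_unit,
        r2_formula=instrument.r2_formula,
    )


@dataclass
class MultiExposureSet:
    """Per-SNP aligned effects for >= 2 exposures and one outcome."""

    rsids: list[str]
    exposure_names: list[str]
    exposure_betas: np.ndarray  # (J, K)
    exposure_ses: np.ndarray  # (J, K)
    outcome_beta: np.ndarray  # (J,)
    outcome_se: np.ndarray  # (J,)

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)
        j, k = self.exposure_betas.shape
        if len(self.rsids) != j or len(self.outcome_beta) != j:
            raise ValueError("rsid / beta block lengths differ")
        if len(self.exposure_names) != k:
            raise ValueError("exposure name count does not match beta columns")


def multivariable_ivw(multi: MultiExposureSet) -> dict[str, MrResult]:
    """Multivariable IVW: WLS of outcome betas on the exposure beta matrix.

    No intercept; weights 1/se_out²; SEs inflated by the residual standard
    error when it exceeds 1 (multiplicative overdispersion, floored).  With a
    single exposure this reproduces univariable fixed/random IVW exactly.
    """
    x = multi.exposure_betas
    y = multi.outcome_beta
    j, k = x.shape
    if j < k + 1:
        raise InsufficientVariantsError(
            f"multivariable IVW requires >= {k + 1} variants, got {j}"
        )
    if np.linalg.matrix_rank(x) < k:
        raise CollinearityError("exposure beta matrix is rank deficient")
    w = 1.0 / multi.outcome_se**2
    xtw = x.T * w
    cov_unscaled = np.linalg.inv(xtw @ x)
    coef = cov_unscaled @ (xtw @ y)
    resid = y - x @ coef
    df = j - k
    sigma2 = float(np.sum(w * resid**2) / df) if df > 0 else 1.0
    infl = max(1.0, math.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unscaled)) * infl
    out: dict[str, MrResult] = {}
    for name, b, s in zip(multi.exposure_names, coef, se):
        p = 2.0 * float(norm.sf(abs(b) / s))
        out[name] = MrResult(
            method="multivariable_ivw", beta=float(b), se=float(s), n_snps=j,
            pvalue=p, effects_model="random" if sigma2 > 1 else "fixed",
        )
    return out
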