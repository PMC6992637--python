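"""Instrument-strength metrics (R², F) and binary-outcome power.

Two variance-explained formulas are provided: the simple ``2·EAF·(1−EAF)·β²``
form, valid when beta is expressed in SD units of the exposure, and a
scale-invariant form that normalises by the sampling variance and therefore
works for betas on an arbitrary measurement scale.  Power for a binary
outcome uses the non-centrality approximation of the mRnd calculator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq
from scipy.stats import norm

from .errors import DegenerateParameterError, DomainError, NoSolutionError

WEAK_INSTRUMENT_F = 10.0


def r2_simple(eaf: float, beta: float) -> float:
    """Variance explained by one variant: 2·EAF·(1−EAF)·beta².

    Assumes the exposure (and hence beta) is on the SD scale.  Symmetric in
    ``eaf`` vs ``1 − eaf``.
    """
    if not 0.0 <= eaf <= 1.0:
        raise DomainError(f"eaf {eaf} outside [0, 1]")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def r2_from_se(eaf: float, beta: float, se: float, n: int) -> float:
    """Scale-invariant per-variant variance explained.

    ``2pq·β² / (2pq·β² + 2pq·N·SE²)``, which reduces to
    ``β² / (β² + N·SE²)`` and is invariant to linear rescaling of the
    exposure.
    """
    if not 0.0 < eaf < 1.0:
        raise DegenerateParameterError(f"eaf {eaf} degenerate (monomorphic variant)")
    if se <= 0.0:
        raise DomainError(f"se must be > 0, got {se}")
    if n < 2:
        raise DomainError(f"n must be >= 2, got {n}")
    g = 2.0 * eaf * (1.0 - eaf)
    num = g * beta * beta
    return num / (num + g * n * se * se)


def f_statistic(r2: float, n: int) -> float:
    """One-instrument F: R²·(N − 2) / (1 − R²)."""
    if not 0.0 <= r2 < 1.0:
        raise DomainError(f"r2 {r2} outside [0, 1)")
    if n < 2:
        raise DomainError(f"n must be >= 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


@dataclass
class PowerParams:
    """Inputs to the binary-outcome power approximation."""

    n_total: int
    case_fraction: float
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.case_fraction < 1.0:
            raise DomainError(f"case_fraction {self.case_fraction} outside (0, 1)")
        if not 0.0 < self.r2 < 1.0:
            raise DomainError(f"r2 {self.r2} outside (0, 1)")
        if self.or_alt <= 0.0:
            raise DomainError(f"or_alt must be > 0, got {self.or_alt}")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha {self.alpha} outside (0, 1)")
        if self.n_total < 2:
            raise DomainError(f"n_total must be >= 2, got {self.n_total}")


@dataclass
class StrengthReport:
    """Per-variant R²/F plus instrument-level aggregates."""

    rsids: list[str]
    r2: list[float]
    f: list[float]
    total_r2: float = field(init=False)
    min_f: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_r2 = float(sum(self.r2))
        self.min_f = float(min(self.f)) if self.f else float("nan")

    @property
    def weak(self) -> bool:
        return self.min_f < WEAK_INSTRUMENT_F


def instrument_strength(instrument) -> StrengthReport:
    """Compute per-variant R² and F and instrument aggregates."""
    r2s = instrument.per_variant_r2()
    fs = [f_statistic(r2, v.n) for r2, v in zip(r2s, instrument.variants)]
    return StrengthReport(rsids=instrument.rsids, r2=r2s, f=fs)


def power_binary(params: PowerParams) -> float:
    """A priori power of an MR test on a binary outcome.

    Non-centrality approximation: with case fraction K and odds ratio OR per
    exposure SD,

        b = K·(OR / (1 + K·(OR − 1)) − 1)
        v = (K·(1 − K) − b²) / (N·R²)
        power = Φ(√(b²/v) − z₁₋α/₂)

    The upper-tail term of the two-sided test is omitted (negligible at any
    realistic non-centrality, and required to reproduce the reference tool).
    """
    k = params.case_fraction
    b = k * (params.or_alt / (1.0 + k * (params.or_alt - 1.0)) - 1.0)
    kq = k * (1.0 - k)
    if kq - b * b <= 0.0:
        raise DegenerateParameterError(
            f"K(1-K) = {kq:.6g} <= b^2 = {b * b:.6g}: approximation breaks down"
        )
    v = (kq - b * b) / (params.n_total * params.r2)
    ncp = b * b / v
    z_crit = norm.ppf(1.0 - params.alpha / 2.0)
    return float(norm.cdf(ncp**0.5 - z_crit))


def minimum_detectable_or(
    n_total: int,
    case_fraction: float,
    r2: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    side: str = "protective",
) -> float:
    """Invert :func:`power_binary`: the OR at which power equals the target.

    ``side='protective'`` searches OR in (0.01, 1); ``'risk'`` in (1, 100).
    """
    if not 0.0 < target_power < 1.0:
        raise DomainError(f"target_power {target_power} outside (0, 1)")
    if side not in ("protective", "risk"):
        raise DomainError(f"side must be 'protective' or 'risk', got {side!r}")
    lo, hi = (0.01, 1.0 - 1e-9) if side == "protective" else (1.0 + 1e-9, 100.0)

    def gap(or_alt: float) -> float:
        return (
            power_binary(
                PowerParams(
                    n_total=n_total,
                    case_fraction=case_fraction,
                    r2=r2,
                    or_alt=or_alt,
                    alpha=alpha,
                )
            )
            - target_power
        )

    # pull the far end of the bracket toward OR = 1 until the approximation
    # is defined there
    far = lo if side == "protective" else hi
    for _ in range(200):
        try:
            gap(far)
            break
        except DegenerateParameterError:
            far = (far + 1.0) / 2.0
    else:
        raise NoSolutionError("power approximation undefined on the whole bracket")
    if side == "protective":
        lo = far
    else:
        hi = far
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0.0:
        raise NoSolutionError(
            f"target power {target_power} not bracketed on the {side} side "
            f"(power ranges {g_lo + target_power:.4g}..{g_hi + target_power:.4g}); "
            "note power -> alpha/2 as OR -> 1"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10, rtol=8.9e-16))
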