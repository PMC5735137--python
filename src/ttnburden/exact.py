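"""Exact inference for 2x2 tables, implemented from first principles.

Conditioning on all margins of a 2x2 table, the exposed-cell count ``a``
follows Fisher's noncentral hypergeometric distribution with odds parameter
psi. This module provides the pmf (computed in log space and normalised over
the support, so cells up to ~1e6 are safe), the central-hypergeometric
Fisher and mid-p exact tests, the cross-product and conditional-MLE odds
ratios, and confidence intervals by Woolf's asymptotic formula or by exact
inversion of the one-sided mid-p tails.

Conventions (those of the common epidemiological exact calculators): the
two-sided p-value is twice the smaller one-sided mid-p tail, capped at 1;
a ``(1-alpha)`` mid-p CI solves one-sided tail = alpha/2 on each side by
monotone bisection on log(psi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .model import ContingencyTable2x2, EnrichmentResult

__all__ = [
    "ExactConfig",
    "UndefinedOddsRatioError",
    "noncentral_hypergeom_pmf",
    "support_pmf",
    "cross_product_or",
    "cmle_or",
    "fisher_exact_p",
    "midp_p",
    "midp_ci",
    "woolf_ci",
    "enrichment_test",
]


class UndefinedOddsRatioError(ValueError):
    """Both products a*d and b*c are zero: the odds ratio is 0/0."""


@dataclass(frozen=True)
class ExactConfig:
    """Knobs of the exact machinery.

    ``sidedness`` selects the reported p-value; ``two_sided_doubling`` (the
    default, matching the study's calculator) doubles the smaller one-sided
    tail. ``two_sided_minlike`` sums all outcomes with probability at most
    that of the observed table (the "minimum-likelihood" rule) and is kept
    behind this flag for comparison only.
    """

    level: float = 0.95
    sidedness: str = "two_sided_doubling"
    ci_method: str = "midp_exact"
    root_tolerance: float = 1e-8
    psi_bracket: tuple[float, float] = (1e-8, 1e8)

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0,1)")
        if self.sidedness not in (
            "one_sided_greater",
            "one_sided_less",
            "two_sided_doubling",
            "two_sided_minlike",
        ):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.ci_method not in ("woolf", "midp_exact"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        if self.root_tolerance <= 0:
            raise ValueError("root_tolerance must be positive")
        lo, hi = self.psi_bracket
        if not 0 < lo < hi:
            raise ValueError("psi_bracket must be ordered and positive")


DEFAULT_CONFIG = ExactConfig()


def _log_weights(n1: int, n2: int, m: int, psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised log masses over the support of Fisher's distribution."""
    lo, hi = max(0, m - n2), min(n1, m)
    if lo > hi:
        raise ValueError(f"infeasible margins n1={n1}, n2={n2}, m={m}")
    ks = np.arange(lo, hi + 1)
    logw = (
        gammaln(n1 + 1)
        - gammaln(ks + 1)
        - gammaln(n1 - ks + 1)
        + gammaln(n2 + 1)
        - gammaln(m - ks + 1)
        - gammaln(n2 - (m - ks) + 1)
        + ks * math.log(psi)
    )
    return ks, logw


def support_pmf(n1: int, n2: int, m: int, psi: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Support and normalised pmf of the (non)central hypergeometric law."""
    if psi <= 0:
        raise ValueError(f"odds parameter psi must be positive, got {psi}")
    ks, logw = _log_weights(n1, n2, m, psi)
    return ks, np.exp(logw - logsumexp(logw))


def noncentral_hypergeom_pmf(k: int, n1: int, n2: int, m: int, psi: float) -> float:
    """P(X = k) under Fisher's noncentral hypergeometric distribution.

    Infeasible ``k`` (outside the margin-determined support) has mass 0;
    ``psi = 1`` reduces exactly to the central hypergeometric.
    """
    ks, pmf = support_pmf(n1, n2, m, psi)
    hit = pmf[ks == k]
    return float(hit[0]) if hit.size else 0.0


def cross_product_or(t: ContingencyTable2x2) -> float:
    """The sample odds ratio (a*d)/(b*c), with boundary conventions.

    A zero in the denominator with a positive numerator yields ``+inf`` (a
    table like the rare 1000-Genomes stratum, which has no control alleles);
    a zero numerator with a positive denominator yields 0. A 0/0 table has
    no defined estimate and raises :class:`UndefinedOddsRatioError`.
    """
    ad, bc = t.a * t.d, t.b * t.c
    if ad == 0 and bc == 0:
        raise UndefinedOddsRatioError(f"odds ratio undefined for table {t.as_tuple()}")
    if bc == 0:
        return math.inf
    return ad / bc


def cmle_or(t: ContingencyTable2x2, cfg: ExactConfig = DEFAULT_CONFIG) -> float:
    """Conditional-MLE odds ratio: psi maximising the noncentral likelihood.

    Solves the score equation ``E_psi[X] = a`` (the conditional mean is
    strictly increasing in psi) by bisection on log(psi); an observed count
    at the bottom or top of the support returns 0 or ``+inf``.
    """
    lo, hi = t.support
    if t.a == lo:
        return 0.0
    if t.a == hi:
        return math.inf

    def mean_minus_a(log_psi: float) -> float:
        ks, pmf = support_pmf(t.n1, t.n2, t.m, math.exp(log_psi))
        return float(np.dot(ks, pmf)) - t.a

    return math.exp(_bisect(mean_minus_a, cfg, increasing=True))


def _bisect(f, cfg: ExactConfig, increasing: bool) -> float:
    """Root of a monotone function of log(psi) within the configured bracket."""
    lo = math.log(cfg.psi_bracket[0])
    hi = math.log(cfg.psi_bracket[1])
    flo, fhi = f(lo), f(hi)
    if not increasing:
        flo, fhi = fhi, flo
        lo, hi = hi, lo
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"no sign change on psi bracket {cfg.psi_bracket}: f(ends) = {flo:.3g}, {fhi:.3g}"
        )
    while abs(hi - lo) > cfg.root_tolerance:
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _tails(t: ContingencyTable2x2, psi: float, mid: bool) -> tuple[float, float]:
    """(greater, less) one-sided tails at the observed count.

    With ``mid=True`` the observed outcome contributes half its mass to each
    tail; otherwise it contributes fully to both (Fisher's convention).
    """
    ks, pmf = support_pmf(t.n1, t.n2, t.m, psi)
    p_obs = float(pmf[ks == t.a][0])
    weight = 0.5 if mid else 1.0
    greater = float(pmf[ks > t.a].sum()) + weight * p_obs
    less = float(pmf[ks < t.a].sum()) + weight * p_obs
    return min(greater, 1.0), min(less, 1.0)


def _minlike(t: ContingencyTable2x2, mid: bool) -> float:
    ks, pmf = support_pmf(t.n1, t.n2, t.m, 1.0)
    p_obs = float(pmf[ks == t.a][0])
    total = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    if mid:
        total -= 0.5 * p_obs
    return min(total, 1.0)


def _p_value(t: ContingencyTable2x2, cfg: ExactConfig, mid: bool) -> float:
    greater, less = _tails(t, 1.0, mid)
    if cfg.sidedness == "one_sided_greater":
        return greater
    if cfg.sidedness == "one_sided_less":
        return less
    if cfg.sidedness == "two_sided_minlike":
        return _minlike(t, mid)
    return min(1.0, 2.0 * min(greater, less))


def fisher_exact_p(t: ContingencyTable2x2, cfg: ExactConfig = DEFAULT_CONFIG) -> float:
    """Fisher's exact p-value; the observed table counts fully in each tail."""
    return _p_value(t, cfg, mid=False)


def midp_p(t: ContingencyTable2x2, cfg: ExactConfig = DEFAULT_CONFIG) -> float:
    """Mid-p exact p-value: half the observed mass plus the more-extreme tail."""
    return _p_value(t, cfg, mid=True)


def midp_ci(t: ContingencyTable2x2, cfg: ExactConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """Mid-p exact CI for the odds ratio by test inversion.

    The lower bound is the psi at which the upper (greater) one-sided mid
    tail equals ``(1-level)/2``; the upper bound likewise for the lower tail.
    Both tails are monotone in psi, so bisection on log(psi) is guaranteed.
    An observed count at the support boundary leaves the corresponding bound
    open (0 or ``+inf``), as for tables with an empty control cell.
    """
    alpha = (1.0 - cfg.level) / 2.0
    lo_support, hi_support = t.support

    if t.a == lo_support:
        lower = 0.0
    else:
        lower = math.exp(
            _bisect(lambda lp: _tails(t, math.exp(lp), mid=True)[0] - alpha, cfg, increasing=True)
        )
    if t.a == hi_support:
        upper = math.inf
    else:
        upper = math.exp(
            _bisect(lambda lp: _tails(t, math.exp(lp), mid=True)[1] - alpha, cfg, increasing=False)
        )
    return lower, upper


def woolf_ci(t: ContingencyTable2x2, cfg: ExactConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """Asymptotic (log-OR +/- z * SE) interval; requires all cells positive."""
    if min(t.as_tuple()) == 0:
        raise ValueError(
            f"Woolf CI undefined for table {t.as_tuple()} with a zero cell; use midp_ci"
        )
    log_or = math.log(cross_product_or(t))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = float(norm.ppf(1.0 - (1.0 - cfg.level) / 2.0))
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def enrichment_test(
    t: ContingencyTable2x2,
    cfg: ExactConfig = DEFAULT_CONFIG,
    stratum: str = "patient-level",
) -> EnrichmentResult:
    """Bundle point estimates, CI and exact p-values for one 2x2 comparison."""
    ci = midp_ci(t, cfg) if cfg.ci_method == "midp_exact" else woolf_ci(t, cfg)
    return EnrichmentResult(
        table=t,
        or_cross_product=cross_product_or(t),
        or_cmle=cmle_or(t, cfg),
        ci=ci,
        ci_method=cfg.ci_method,
        level=cfg.level,
        p_midp=midp_p(t, cfg),
        p_fisher=fisher_exact_p(t, cfg),
        stratum=stratum,
    )
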