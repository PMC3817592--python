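"""True type-1 error, power, bias, genomic-control inflation and design
sample sizes, derived from the marginal moments of the test statistics.

Under the true polygenic model a naive statistic tau is approximately
N(E(tau), V(tau)).  A practitioner rejects beyond the nominal two-sided
threshold t_{alpha/2} = Phi^-1(1 - alpha/2); the *true* type-1 error is the
null mass beyond that threshold, and the *true-alpha* power recalibrates the
threshold so that the realised type-1 error equals the nominal one before
evaluating the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .marginal import Relationships, marginal_test_moments
from .models import ModelParams, TestMoments
from .pedigree import HalfSibDesign

__all__ = [
    "RateResult",
    "nominal_threshold",
    "true_type1",
    "power",
    "threshold_for_true_alpha",
    "grammar_bias",
    "gc_inflation",
    "effect_conversions",
    "required_sample_size",
    "rate_result",
    "rate_table",
]


def nominal_threshold(alpha: float) -> float:
    """Two-sided standard-normal threshold t_{alpha/2} = Phi^-1(1 - alpha/2)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(norm.ppf(1.0 - alpha / 2.0))


def _check_h0(moments: TestMoments) -> None:
    if moments.hypothesis != "H0":
        raise ValueError("null-hypothesis moments required")
    if moments.V_tau <= 0:
        raise ValueError("V(tau) under H0 must be positive")


def true_type1(moments_H0: TestMoments, alpha: float) -> float:
    """Actual rejection rate under H0 at the nominal two-sided threshold."""
    _check_h0(moments_H0)
    t = nominal_threshold(alpha)
    sd = np.sqrt(moments_H0.V_tau)
    e0 = moments_H0.E_tau
    return float(
        (1.0 - norm.cdf((t - e0) / sd)) + norm.cdf((-t - e0) / sd)
    )


def power(moments_H1: TestMoments, threshold: float) -> float:
    """P(tau > threshold) under the alternative (upper tail, as the lower
    rejection mass is negligible at realistic effect sizes)."""
    if moments_H1.V_tau <= 0:
        raise ValueError("V(tau) must be positive")
    return float(1.0 - norm.cdf((threshold - moments_H1.E_tau) / np.sqrt(moments_H1.V_tau)))


def threshold_for_true_alpha(moments_H0: TestMoments, alpha: float) -> float:
    """Threshold at which the true type-1 error equals alpha."""
    _check_h0(moments_H0)
    return float(moments_H0.E_tau + np.sqrt(moments_H0.V_tau) * nominal_threshold(alpha))


def gc_inflation(moments_H0: TestMoments) -> float:
    """Genomic-control inflation factor, approximated by V(tau) under H0."""
    _check_h0(moments_H0)
    return float(moments_H0.V_tau)


def grammar_bias(rel: Relationships, params: ModelParams) -> float:
    """Relative bias (E(beta_hat) - b)/b of the GRAMMAR estimator."""
    if params.beta == 0:
        raise ValueError("bias is defined for a nonzero SNP effect b")
    m = marginal_test_moments("grammar", rel, params, "H1")
    return float((m.E_beta_hat - params.beta) / params.beta)


def effect_conversions(params: ModelParams) -> tuple[float, float]:
    """(allele substitution effect, QTL-scale coefficient) implied by beta.

    beta_allele = beta / sqrt(2 p q); with LD r^2 between SNP and QTL the QTL
    regression coefficient is beta / r.
    """
    p, q = params.p, 1.0 - params.p
    beta_allele = params.beta / np.sqrt(2.0 * p * q)
    beta_qtl = params.beta / np.sqrt(params.r2)
    return float(beta_allele), float(beta_qtl)


@dataclass
class RateResult:
    """Operating characteristics of one method on one design/parameter set."""

    method: str
    n: int
    family_size: Optional[int]
    h2_true: float
    h2_used: Optional[float]
    alpha_nominal: float
    alpha_true: float
    power_nominal: float
    power_true: float
    bias_rel: Optional[float]
    gc_lambda: float


def rate_result(
    method: str,
    rel: Relationships,
    params: ModelParams,
    alpha: float = 0.01,
) -> RateResult:
    """All operating characteristics for one method at one configuration."""
    m0 = marginal_test_moments(method, rel, params, "H0")
    alpha_true = true_type1(m0, alpha)
    gc = gc_inflation(m0)
    t_nom = nominal_threshold(alpha)
    if params.beta != 0.0:
        m1 = marginal_test_moments(method, rel, params, "H1")
        p_nom = power(m1, t_nom)
        p_true = power(m1, threshold_for_true_alpha(m0, alpha))
        bias = (m1.E_beta_hat - params.beta) / params.beta
    else:
        p_nom = p_true = alpha_true
        bias = None
    if isinstance(rel, HalfSibDesign):
        n, fam = rel.n, rel.family_size
    else:
        n, fam = rel.n, None
    return RateResult(
        method=method,
        n=n,
        family_size=fam,
        h2_true=params.h2_true,
        h2_used=params.h2_used,
        alpha_nominal=alpha,
        alpha_true=alpha_true,
        power_nominal=p_nom,
        power_true=p_true,
        bias_rel=bias,
        gc_lambda=gc,
    )


def rate_table(
    rel: Relationships,
    h2_grid: Sequence[float],
    methods: Sequence[str] = ("regression", "grammar", "fasta", "qtdt"),
    snp_variance: float = 0.02,
    alpha: float = 0.01,
    sigma_y2: float = 1.0,
    h2_used: Optional[float] = None,
    p: float = 0.5,
    r2: float = 1.0,
) -> pd.DataFrame:
    """Tidy table of operating characteristics, one row per method x h2."""
    beta = float(np.sqrt(snp_variance * sigma_y2))
    rows = []
    for h2 in h2_grid:
        params = ModelParams(
            h2_true=float(h2), beta=beta, sigma_y2=sigma_y2,
            h2_used=h2_used, p=p, r2=r2,
        )
        for method in methods:
            rows.append(asdict(rate_result(method, rel, params, alpha)))
    return pd.DataFrame(rows)


def required_sample_size(
    target_power: float,
    alpha: float,
    family_size: int,
    h2: float,
    snp_var_fraction: float,
    method: str = "fasta",
    h2_used: Optional[float] = None,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n (a whole number of half-sib families of the given size)
    whose power at the recalibrated true type-1 error reaches the target."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")
    beta = float(np.sqrt(snp_var_fraction))
    params = ModelParams(h2_true=h2, beta=beta, h2_used=h2_used)

    def power_true(k: int) -> float:
        design = HalfSibDesign(k, family_size)
        m0 = marginal_test_moments(method, design, params, "H0")
        m1 = marginal_test_moments(method, design, params, "H1")
        return power(m1, threshold_for_true_alpha(m0, alpha))

    # geometric bracket then bisect on the number of families; designs below
    # ~8 animals cannot support the moment formulas (df <= 0, degenerate x)
    k_min = max(1, int(np.ceil(8.0 / family_size)))
    lo, hi = k_min, k_min
    while power_true(hi) < target_power:
        lo = hi
        hi *= 2
        if hi * family_size > max_n:
            raise RuntimeError(
                f"target power {target_power} not reached below n={max_n}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_true(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi * family_size
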