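"""Conditional moments of SNP-association test statistics under a polygenic
mixed model.

The true model for the phenotypes is

    y = 1*mu + x*beta + u + e,   V(u) = A*sigma_u^2,  V(e) = I*sigma_e^2,

with x the centred standardized SNP genotype.  Four practitioner statistics
are analysed: simple regression, GRAMMAR (regression of BLUP residuals on
x), FASTA (GLS with variance components pre-estimated in the SNP-free
random model) and the QTDT within-family regression; the exact generalised
least squares test under the true model ("true") is the benchmark.

Each statistic has the shape tau = beta_hat / sqrt(c * q / df) where c is
the naive variance coefficient and q a residual quadratic.  Its first two
moments under the true model are rational functions of quadratic forms in
x (x'x, x'Ax, x'Cuu x, ...), which this module evaluates for a concrete
genotype vector; :mod:`assocpower.marginal` re-evaluates the identical
expressions with the forms replaced by their expectations over genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "METHODS",
    "H2_EPS",
    "ModelParams",
    "GenotypeVectors",
    "MMEBlocks",
    "TestMoments",
    "resolve_lambda",
    "mme_cuu",
    "conditional_moments",
    "moments_from_forms",
]

METHODS = ("regression", "grammar", "fasta", "qtdt", "true")

# heritability is clipped to this open interval before forming the shrinkage
# ratio lambda = sigma_e^2/sigma_u^2, which is infinite/zero at the ends;
# the moments are continuous there so the clipped value is a faithful limit
H2_EPS = 1e-6


@dataclass
class ModelParams:
    """Parameters of the true polygenic model and of the analysis.

    beta is the SNP regression coefficient on the standardized genotype
    scale (phenotypic-SD units when sigma_y2 = 1); h2_used, when given,
    overrides the heritability plugged into the two-step methods (the
    misspecification analysis), otherwise the plug-in expectations of the
    random-model variance components are used.
    """

    h2_true: float
    beta: float = 0.0
    sigma_y2: float = 1.0
    mu: float = 0.0
    p: float = 0.5
    r2: float = 1.0
    h2_used: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")
        if self.sigma_y2 <= 0:
            raise ValueError("sigma_y2 must be positive")
        if self.beta**2 > self.sigma_y2:
            raise ValueError("beta^2 cannot exceed the phenotypic variance")
        if not 0.0 < self.p < 1.0:
            raise ValueError("allele frequency p must lie in (0, 1)")
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError("r2 must lie in (0, 1]")
        if self.h2_used is not None and not 0.0 <= self.h2_used <= 1.0:
            raise ValueError("h2_used must lie in [0, 1]")

    @property
    def sigma_u2(self) -> float:
        return self.h2_true * self.sigma_y2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2_true) * self.sigma_y2

    @property
    def lambda_true(self) -> float:
        h2 = np.clip(self.h2_true, H2_EPS, 1.0 - H2_EPS)
        return (1.0 - h2) / h2


def resolve_lambda(params: ModelParams, hypothesis: str) -> float:
    """Shrinkage ratio used by the two-step methods (GRAMMAR/FASTA).

    With an explicit h2_used, lambda = (1 - h2_used)/h2_used regardless of
    hypothesis.  Otherwise the ratio of the plug-in expectations of the
    random-model variance-component estimators is used,
    sigma_e^2 / (sigma_u^2 + beta^2), which reduces to the true ratio under
    H0 (beta = 0).
    """
    if hypothesis not in ("H0", "H1"):
        raise ValueError("hypothesis must be 'H0' or 'H1'")
    if params.h2_used is not None:
        h2 = float(np.clip(params.h2_used, H2_EPS, 1.0 - H2_EPS))
        return (1.0 - h2) / h2
    beta = params.beta if hypothesis == "H1" else 0.0
    su2 = max(params.sigma_u2 + beta**2, H2_EPS * params.sigma_y2)
    se2 = min(params.sigma_e2, (1.0 - H2_EPS) * params.sigma_y2)
    return se2 / su2


@dataclass
class GenotypeVectors:
    """Standardized genotypes w, centred codes x = w - mean(w), and the
    mid-parent code z = (w_s + w_d)/2 where parental genotypes are known."""

    w: np.ndarray
    z: Optional[np.ndarray] = None
    x: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.x = self.w - self.w.mean()
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != self.w.shape:
                raise ValueError("z must match w in length")

    @property
    def n(self) -> int:
        return self.w.size

    def Q(self) -> np.ndarray:
        """QTDT design [1, z - mean(z), x - z]."""
        if self.z is None:
            raise ValueError("QTDT requires parental genotypes (z)")
        wf = self.x - self.z
        if float(wf @ wf) < 1e-12:
            raise ValueError(
                "no within-family genotype variation: the QTDT design is degenerate"
            )
        return np.column_stack([np.ones(self.n), self.z - self.z.mean(), wf])


@dataclass
class MMEBlocks:
    """Blocks of the inverse coefficient matrix of the SNP-free random model
    mixed-model equations [[n, 1'], [1, I + lambda*A^-1]]."""

    C11: float
    C1u: np.ndarray
    Cuu: np.ndarray
    lambda_used: float
    Ainv: np.ndarray


def mme_cuu(A: np.ndarray, lambda_used: float) -> MMEBlocks:
    """Invert the random-model MME coefficient matrix.

    Cuu is the shrinkage operator of the polygenic BLUP: u_hat = Cuu*H*y and
    E(u_hat | x) = Cuu*x*beta under the true model.
    """
    if lambda_used <= 0:
        raise ValueError("lambda must be positive")
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "relationship matrix A is singular; supply the phenotyped subset only "
            "or add a small ridge to the diagonal"
        ) from exc
    K = np.empty((n + 1, n + 1))
    K[0, 0] = n
    K[0, 1:] = 1.0
    K[1:, 0] = 1.0
    K[1:, 1:] = np.eye(n) + lambda_used * Ainv
    C = np.linalg.inv(K)
    return MMEBlocks(C[0, 0], C[0, 1:], 0.5 * (C[1:, 1:] + C[1:, 1:].T), lambda_used, Ainv)


@dataclass
class TestMoments:
    """First two moments of estimator and statistic for one method/hypothesis."""

    method: str
    hypothesis: str
    E_beta_hat: float
    V_beta_hat: float
    E_resid_quad: float  # E(e'e), or E(e'y) for fasta/true
    E_tau: float
    V_tau: float
    df: int


def moments_from_forms(
    method: str,
    forms: dict,
    params: ModelParams,
    hypothesis: str,
    lambda_used: float,
) -> TestMoments:
    """Evaluate the moment expressions on a bundle of quadratic forms.

    ``forms`` holds either realised quadratic forms (conditional moments) or
    their expectations over the genotype distribution (marginal moments);
    the expressions are identical, so marginalizing amounts to replacing
    expectations of ratios by ratios of expectations.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    su2, se2 = params.sigma_u2, params.sigma_e2
    beta = params.beta if hypothesis == "H1" else 0.0
    n = forms["n"]
    xx = forms["xx"]

    if method == "regression":
        E_beta = beta
        V_beta = se2 / xx + su2 * forms["xAx"] / xx**2
        E_quad = se2 * (n - 2) + su2 * (
            forms["trA"] - forms["xAx"] / xx - forms["oneA1"] / n
        )
        c_naive, df = 1.0 / xx, n - 2

    elif method == "grammar":
        gam = se2 - lambda_used * su2
        xCx, xCCx = forms["xCx"], forms["xCCx"]
        xCACx, xC1sq = forms["xCACx"], forms["xC1sq"]
        E_beta = beta * (1.0 - xCx / xx)
        V_beta = (se2 * (xx - xCx) - gam * lambda_used * xCACx) / xx**2
        E_quad = (
            se2 * (n - 2 - forms["trC"] + xCx / xx + forms["oneC1"] / n)
            + beta**2 * (xCCx - xCx**2 / xx - xC1sq / n)
            - gam
            * lambda_used
            * (forms["trCAC"] - xCACx / xx - forms["oneCAC1"] / n)
        )
        c_naive, df = 1.0 / xx, n - 2

    elif method in ("fasta", "true"):
        gam = 0.0 if method == "true" else se2 - lambda_used * su2
        xCx, xCACx = forms["xCx"], forms["xCACx"]
        g = xx - xCx
        E_beta = beta
        V_beta = (se2 * g - gam * lambda_used * xCACx) / g**2
        E_quad = (n - 2) * se2 - gam * (
            forms["trC"] - forms["oneC1"] / n - lambda_used * xCACx / g
        )
        c_naive, df = 1.0 / g, n - 2

    else:  # qtdt
        QQ, Qx, Q1, QAQ = forms["QQ"], forms["Qx"], forms["Q1"], forms["QAQ"]
        QQinv = np.linalg.inv(QQ)
        coef = QQinv @ Qx
        E_beta = beta * coef[2]
        V_beta = su2 * (QQinv @ QAQ @ QQinv)[2, 2] + se2 * QQinv[2, 2]
        mu = params.mu
        E_quad = (
            (n - 3) * se2
            + su2 * (forms["trA"] - np.trace(QQinv @ QAQ))
            + mu**2 * (n - Q1 @ QQinv @ Q1)
            + beta**2 * (xx - Qx @ QQinv @ Qx)
            - 2.0 * mu * beta * (Q1 @ QQinv @ Qx)
        )
        c_naive, df = QQinv[2, 2], n - 3

    if E_quad <= 0 or c_naive <= 0:
        raise FloatingPointError(
            f"non-positive naive variance for {method}: the configuration is degenerate"
        )
    denom = c_naive * E_quad / df
    return TestMoments(
        method=method,
        hypothesis=hypothesis,
        E_beta_hat=float(E_beta),
        V_beta_hat=float(V_beta),
        E_resid_quad=float(E_quad),
        E_tau=float(E_beta / np.sqrt(denom)),
        V_tau=float(V_beta / denom),
        df=df,
    )


def _conditional_forms(
    gv: GenotypeVectors, A: np.ndarray, blocks: Optional[MMEBlocks]
) -> dict:
    x = gv.x
    n = gv.n
    forms: dict = {
        "n": n,
        "xx": float(x @ x),
        "xAx": float(x @ A @ x),
        "trA": float(np.trace(A)),
        "oneA1": float(A.sum()),
    }
    if forms["xx"] < 1e-12:
        raise ValueError("monomorphic SNP: x'x is zero")
    if blocks is not None:
        C, Ainv = blocks.Cuu, blocks.Ainv
        Cx = C @ x
        C1 = C.sum(axis=1)
        CC = C @ C
        forms.update(
            xCx=float(x @ Cx),
            xCCx=float(Cx @ Cx),
            xCACx=float(Cx @ Ainv @ Cx),
            xC1sq=float(Cx.sum() ** 2),
            trC=float(np.trace(C)),
            oneC1=float(C.sum()),
            trCAC=float(np.sum(Ainv * CC)),
            oneCAC1=float(C1 @ Ainv @ C1),
        )
    if gv.z is not None:
        Q = gv.Q()
        forms.update(
            QQ=Q.T @ Q, Qx=Q.T @ x, Q1=Q.T @ np.ones(n), QAQ=Q.T @ A @ Q
        )
    return forms


def conditional_moments(
    method: str,
    gv: GenotypeVectors,
    A: np.ndarray,
    params: ModelParams,
    hypothesis: str = "H0",
) -> TestMoments:
    """Moments of the test statistic given a realised genotype vector.

    These are exact for E(beta_hat), V(beta_hat) and the residual quadratic;
    E(tau) and V(tau) carry the normal approximation of the t statistic and
    the ratio-of-expectations step shared with the marginal layer.
    """
    A = np.asarray(A, dtype=float)
    lam = resolve_lambda(params, hypothesis)
    blocks = None
    if method in ("grammar", "fasta"):
        blocks = mme_cuu(A, lam)
    elif method == "true":
        lam = params.lambda_true
        blocks = mme_cuu(A, lam)
    elif method == "qtdt" and gv.z is None:
        raise ValueError("QTDT requires parental genotypes (z) for every animal")
    forms = _conditional_forms(gv, A, blocks)
    return moments_from_forms(method, forms, params, hypothesis, lam)
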