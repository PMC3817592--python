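"""Marginal moments of the test statistics: the conditional expressions with
every quadratic form in the genotypes replaced by its expectation.

Under Hardy-Weinberg founders and gene dropping the standardized genotypes
satisfy E(w w') = A exactly, and the mid-parent codes z satisfy
E(z z') = E(w z') = A - D.  Every expectation needed is therefore an exact
trace: for centred x = H w (H = I - J/n),

    E(x' M x) = tr(M H A H).

This pins the expected forms by the gene-dropping distribution itself rather
than by printed expansions.  Two interchangeable backends are provided: a
dense one for an arbitrary relationship matrix and an O(1) closed-form one
for balanced half-sib designs (see :mod:`assocpower.halfsib`).

The QTDT bookkeeping uses w - z for the within-family column (the fitted
statistic is invariant to this choice because the two candidates differ by a
multiple of the intercept column); with that convention E(Q'Q), E(Q'x) and
E(Q'AQ) are exact and diagonal/sparse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .halfsib import ExchangeableMatrix
from .models import ModelParams, TestMoments, mme_cuu, moments_from_forms, resolve_lambda
from .pedigree import HalfSibDesign, RelationshipSet

__all__ = [
    "ExpectedForms",
    "PluginVariance",
    "plugin_variance",
    "expected_forms",
    "expected_forms_halfsib",
    "marginal_test_moments",
]

Relationships = Union[RelationshipSet, HalfSibDesign]


@dataclass
class ExpectedForms:
    """Expectations over the genotype distribution of every quadratic form
    entering the test-statistic moments, for one value of lambda."""

    n: int
    lambda_used: float
    xx: float
    xAx: float
    xCx: float
    xCCx: float
    xCACx: float
    xC1sq: float
    trA: float
    oneA1: float
    trC: float
    oneC1: float
    trCAC: float
    oneCAC1: float
    QQ: np.ndarray
    Qx: np.ndarray
    Q1: np.ndarray
    QAQ: np.ndarray

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class PluginVariance:
    """Expectations of the random-model variance-component estimators: the
    polygenic estimator absorbs the SNP variance, E(su2_hat) = su2 + beta^2,
    while E(se2_hat) = se2."""

    Ex_sigma_u2: float
    Ex_sigma_e2: float
    Ex_lambda: float


def plugin_variance(params: ModelParams) -> PluginVariance:
    su2 = params.sigma_u2 + params.beta**2
    return PluginVariance(su2, params.sigma_e2, params.sigma_e2 / su2)


def _qtdt_expected(n, trA, oneA1, trD, trHB, trGB, trAD) -> dict:
    # exact for a terminal tested generation (no tested animal is a parent of
    # another tested animal), where E(z z') = E(w z') = A - D
    QQ = np.diag([n, trHB, trD])
    Qx = np.array([0.0, trHB, trD * (n - 1.0) / n])
    Q1 = np.array([float(n), 0.0, 0.0])
    QAQ = np.diag([oneA1, trGB, trAD])
    return {"QQ": QQ, "Qx": Qx, "Q1": Q1, "QAQ": QAQ}


def expected_forms(A: np.ndarray, D: np.ndarray, lambda_used: float) -> ExpectedForms:
    """Dense-matrix expectations for an arbitrary relationship structure."""
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    n = A.shape[0]
    if D.shape != A.shape:
        raise ValueError("A and D must have the same shape")
    blocks = mme_cuu(A, lambda_used)
    C, Ainv = blocks.Cuu, blocks.Ainv

    H = np.eye(n) - np.ones((n, n)) / n
    G = H @ A @ H  # E(x x')
    CC = C @ C
    CAC = C @ Ainv @ C
    C1 = C.sum(axis=1)
    Bm = A - D  # E(z z') = E(w z')

    trA = float(np.trace(A))
    oneA1 = float(A.sum())
    trD = float(np.trace(D))
    trHB = float(np.trace(Bm) - Bm.sum() / n)
    return ExpectedForms(
        n=n,
        lambda_used=lambda_used,
        xx=float(np.trace(G)),
        xAx=float(np.sum(A * G)),
        xCx=float(np.sum(C * G)),
        xCCx=float(np.sum(CC * G)),
        xCACx=float(np.sum(CAC * G)),
        xC1sq=float(C1 @ G @ C1),
        trA=trA,
        oneA1=oneA1,
        trC=float(np.trace(C)),
        oneC1=float(C.sum()),
        trCAC=float(np.trace(CAC)),
        oneCAC1=float(C1 @ Ainv @ C1),
        **_qtdt_expected(
            n,
            trA,
            oneA1,
            trD,
            trHB,
            float(np.sum(G * Bm)),
            float(np.trace(A @ D)),
        ),
    )


def expected_forms_halfsib(design: HalfSibDesign, lambda_used: float) -> ExpectedForms:
    """Closed-form expectations for a balanced half-sib design (O(1) in n)."""
    f, d = design.n_families, design.family_size
    n = f * d
    EM = ExchangeableMatrix
    I = EM.identity(f, d)
    J = EM.from_abc(f, d, 0.0, 0.0, 1.0)
    H = EM.centering(f, d)
    A = EM.relationship(f, d)
    D = EM.mendelian(f, d)
    Ainv = A.inv()
    C = (I + lambda_used * Ainv - (1.0 / n) * J).inv()
    G = H @ A @ H
    CC = C @ C
    CAC = C @ Ainv @ C
    Bm = A - D

    return ExpectedForms(
        n=n,
        lambda_used=lambda_used,
        xx=G.trace(),
        xAx=(A @ G).trace(),
        xCx=(C @ G).trace(),
        xCCx=(CC @ G).trace(),
        xCACx=(CAC @ G).trace(),
        xC1sq=(C @ G @ C).quad_ones(),
        trA=A.trace(),
        oneA1=A.quad_ones(),
        trC=C.trace(),
        oneC1=C.quad_ones(),
        trCAC=CAC.trace(),
        oneCAC1=(CAC).quad_ones(),
        **_qtdt_expected(
            n,
            A.trace(),
            A.quad_ones(),
            D.trace(),
            (H @ Bm).trace(),
            (G @ Bm).trace(),
            (A @ D).trace(),
        ),
    )


def _forms_for(rel: Relationships, lambda_used: float) -> ExpectedForms:
    if isinstance(rel, HalfSibDesign):
        return expected_forms_halfsib(rel, lambda_used)
    if isinstance(rel, RelationshipSet):
        return expected_forms(rel.A, rel.D, lambda_used)
    raise TypeError("relationships must be a RelationshipSet or HalfSibDesign")


def marginal_test_moments(
    method: str,
    rel: Relationships,
    params: ModelParams,
    hypothesis: str = "H0",
) -> TestMoments:
    """Marginal E(tau), V(tau) (and estimator moments) for one method.

    The shrinkage ratio entering the two-step methods follows the plug-in
    rule (true components under H0; sigma_e^2/(sigma_u^2 + beta^2) under H1)
    unless params.h2_used pins it explicitly; the exact GLS benchmark
    ("true") always uses the true ratio.
    """
    lam = params.lambda_true if method == "true" else resolve_lambda(params, hypothesis)
    forms = _forms_for(rel, lam)
    return moments_from_forms(method, forms.as_dict(), params, hypothesis, lam)
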