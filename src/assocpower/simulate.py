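"""Gene-dropping simulator used to validate the analytic moments.

Founder genotypes are drawn in Hardy-Weinberg proportions and transmitted
down the pedigree one allele per parent; polygenic values follow the
recursion u_i = (u_s + u_d)/2 + m_i with Mendelian deviation variance
d_ii * sigma_u^2, so V(u) = A * sigma_u^2 holds exactly by construction.
Variance components for the two-step methods are re-estimated per replicate
by REML on the SNP-free random model (eigendecomposition of A and a 1-D
profile likelihood in h2), and each statistic is computed exactly as a
practitioner would compute it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .models import GenotypeVectors, ModelParams
from .pedigree import HalfSibDesign, Pedigree, RelationshipSet, build_A

__all__ = [
    "SimConfig",
    "SimulatedData",
    "gene_drop",
    "gene_drop_matrix",
    "simulate_trait",
    "reml_fit",
    "run_test",
    "empirical_rates",
]


# ----------------------------------------------------------------------
# gene dropping
# ----------------------------------------------------------------------

def _drop_alleles(ped: Pedigree, p: float, rng: np.random.Generator, reps: int):
    """Allele counts (N, reps) by gene dropping; founders HWE(p)."""
    pos = {a: i for i, a in enumerate(ped.ids)}
    counts = np.zeros((ped.n, reps), dtype=np.int8)
    idx = np.arange(reps)
    alleles = np.empty((ped.n, 2, reps), dtype=np.int8)
    for i, (_, sire, dam) in enumerate(ped.records):
        for k, parent in enumerate((sire, dam)):
            if parent is None:
                alleles[i, k] = rng.random(reps) < p
            else:
                j = pos[parent]
                alleles[i, k] = alleles[j, rng.integers(2, size=reps), idx]
        counts[i] = alleles[i, 0] + alleles[i, 1]
    return counts


def _standardize(counts: np.ndarray, p: float) -> np.ndarray:
    return (counts - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def gene_drop_matrix(
    ped: Pedigree,
    p: float,
    reps: int,
    rng: np.random.Generator,
    subset: Optional[Sequence[str]] = None,
):
    """(W, Z) standardized genotype and mid-parent matrices, shape (n, reps).

    Z rows are NaN for animals without both parents recorded.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    pos = {a: i for i, a in enumerate(ped.ids)}
    counts = _drop_alleles(ped, p, rng, reps)
    W_all = _standardize(counts, p)
    ids = list(subset) if subset is not None else ped.ids
    W = np.stack([W_all[pos[a]] for a in ids])
    Z = np.full_like(W, np.nan)
    parent_of = {a: (s, d) for a, s, d in ped.records}
    for k, a in enumerate(ids):
        s, d = parent_of[a]
        if s is not None and d is not None:
            Z[k] = 0.5 * (W_all[pos[s]] + W_all[pos[d]])
    return W, Z


def gene_drop(
    ped: Pedigree,
    p: float = 0.5,
    seed: Optional[Union[int, np.random.Generator]] = None,
    subset: Optional[Sequence[str]] = None,
) -> GenotypeVectors:
    """One gene-dropped genotype vector for ``subset`` (default all animals)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W, Z = gene_drop_matrix(ped, p, 1, rng, subset)
    z = Z[:, 0]
    return GenotypeVectors(w=W[:, 0], z=None if np.isnan(z).any() else z)


# ----------------------------------------------------------------------
# trait simulation
# ----------------------------------------------------------------------

@dataclass
class SimulatedData:
    """One replicate: genotypes, polygenic values, residuals and phenotype."""

    gv: GenotypeVectors
    u: np.ndarray
    e: np.ndarray
    y: np.ndarray
    params: ModelParams


def _mendelian_sd(ped: Pedigree) -> np.ndarray:
    """sqrt(d_ii) per animal in pedigree order (founders: full genetic SD)."""
    rel = build_A(ped)
    return np.sqrt(np.clip(np.diag(rel.D), 0.0, None))


def _drop_polygenic(
    ped: Pedigree,
    sigma_u: float,
    rng: np.random.Generator,
    reps: int,
    mend_sd: Optional[np.ndarray] = None,
) -> np.ndarray:
    pos = {a: i for i, a in enumerate(ped.ids)}
    if mend_sd is None:
        mend_sd = _mendelian_sd(ped)
    u = np.empty((ped.n, reps))
    for i, (_, sire, dam) in enumerate(ped.records):
        mid = np.zeros(reps)
        if sire is not None:
            mid += 0.5 * u[pos[sire]]
        if dam is not None:
            mid += 0.5 * u[pos[dam]]
        u[i] = mid + sigma_u * mend_sd[i] * rng.standard_normal(reps)
    return u


def simulate_trait(
    ped: Pedigree,
    gv: GenotypeVectors,
    params: ModelParams,
    seed: Optional[Union[int, np.random.Generator]] = None,
    subset: Optional[Sequence[str]] = None,
) -> SimulatedData:
    """Simulate y = 1*mu + x*beta + u + e for the phenotyped subset."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(subset) if subset is not None else ped.ids
    pos = {a: i for i, a in enumerate(ped.ids)}
    idx = [pos[a] for a in ids]
    if gv.n != len(ids):
        raise ValueError("genotype vector does not match the phenotyped subset")
    u = _drop_polygenic(ped, np.sqrt(params.sigma_u2), rng, 1)[:, 0][idx]
    e = np.sqrt(params.sigma_e2) * rng.standard_normal(len(ids))
    y = params.mu + gv.x * params.beta + u + e
    return SimulatedData(gv=gv, u=u, e=e, y=y, params=params)


# ----------------------------------------------------------------------
# REML on the SNP-free random model
# ----------------------------------------------------------------------

def _reml_h2(yt: np.ndarray, onet: np.ndarray, evals: np.ndarray) -> float:
    """Profile-REML heritability for y = 1*mu + u + e in the eigenbasis of A."""
    n = yt.size

    def negll(h2: float) -> float:
        k = h2 * (evals - 1.0) + 1.0
        ki = 1.0 / k
        oKo = float(onet @ (ki * onet))
        yKy = float(yt @ (ki * yt))
        yKo = float(yt @ (ki * onet))
        ypy = max(yKy - yKo**2 / oKo, 1e-300)
        return float(np.log(k).sum() + np.log(oKo) + (n - 1) * np.log(ypy / (n - 1)))

    res = minimize_scalar(negll, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
                          options={"xatol": 1e-9})
    return float(res.x)


def reml_fit(y: np.ndarray, A: np.ndarray) -> tuple[float, float]:
    """REML variance components (sigma_u2, sigma_e2) of y = 1*mu + u + e."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("REML needs at least 10 observations")
    evals, U = np.linalg.eigh(np.asarray(A, dtype=float))
    if evals.min() < -1e-8:
        raise np.linalg.LinAlgError("A is not positive semidefinite")
    evals = np.clip(evals, 1e-12, None)
    yt, onet = U.T @ y, U.T @ np.ones(n)
    h2 = _reml_h2(yt, onet, evals)
    k = h2 * (evals - 1.0) + 1.0
    ki = 1.0 / k
    oKo = float(onet @ (ki * onet))
    ypy = float(yt @ (ki * yt)) - float(yt @ (ki * onet)) ** 2 / oKo
    s2 = ypy / (n - 1)
    return h2 * s2, (1.0 - h2) * s2


# ----------------------------------------------------------------------
# the four practitioner statistics
# ----------------------------------------------------------------------

def _tau_regression(x, y):
    n = y.size
    xx = float(x @ x)
    b = float(x @ y) / xx
    r = y - y.mean() - b * x
    s2 = float(r @ r) / (n - 2)
    return b / np.sqrt(s2 / xx), b


def _tau_grammar(xt, yt, onet, lam, evals, xx):
    n = yt.size
    om = lam / (lam + evals)
    mu = float(onet @ (om * yt)) / float(onet @ (om * onet))
    et = om * (yt - mu * onet)  # residuals of the random model, eigenbasis
    xe = float(xt @ et)
    b = xe / xx
    rss = float(et @ et) - float(onet @ et) ** 2 / n - xe**2 / xx
    s2 = rss / (n - 2)
    return b / np.sqrt(s2 / xx), b


def _tau_gls(xt, yt, onet, lam, evals):
    n = yt.size
    om = lam / (lam + evals)
    Xt = np.column_stack([onet, xt])
    Xw = Xt * om[:, None]
    M = Xt.T @ Xw
    rhs = Xw.T @ yt
    Minv = np.linalg.inv(M)
    b = Minv @ rhs
    eqy = float(yt @ (om * yt)) - float(rhs @ b)
    s2 = eqy / (n - 2)
    return b[1] / np.sqrt(max(s2, 1e-300) * Minv[1, 1]), b[1]


def _tau_qtdt(x, z, y):
    n = y.size
    Q = np.column_stack([np.ones(n), z - z.mean(), x - z])
    QtQ = Q.T @ Q
    wf = Q[:, 2]
    if float(wf @ wf) < 1e-10:
        raise ValueError("no within-family genotype variation")
    Qinv = np.linalg.inv(QtQ)
    coef = Qinv @ (Q.T @ y)
    r = y - Q @ coef
    s2 = float(r @ r) / (n - 3)
    return coef[2] / np.sqrt(s2 * Qinv[2, 2]), coef[2]


def run_test(
    method: str,
    data: SimulatedData,
    rel: RelationshipSet,
    varcomp: str = "reml",
    h2_used: Optional[float] = None,
) -> float:
    """Compute the naive statistic tau exactly as a practitioner would.

    varcomp selects the shrinkage ratio of the two-step methods: 'reml'
    (re-estimated from this replicate's phenotypes with the SNP-free random
    model), 'true' (the generating components) or 'fixed' (from h2_used).
    """
    x, y = data.gv.x, data.y
    if float(x @ x) < 1e-10:
        raise ValueError("monomorphic SNP in this replicate")
    if method == "regression":
        return _tau_regression(x, y)[0]
    if method == "qtdt":
        if data.gv.z is None:
            raise ValueError("QTDT requires parental genotypes")
        return _tau_qtdt(x, data.gv.z, y)[0]
    if method not in ("grammar", "fasta", "true"):
        raise ValueError(f"unknown method {method!r}")
    evals, U = np.linalg.eigh(rel.A)
    yt, xt, onet = U.T @ y, U.T @ x, U.T @ np.ones(y.size)
    if method == "true" or varcomp == "true":
        lam = data.params.lambda_true
    elif varcomp == "fixed":
        h2 = float(np.clip(h2_used, 1e-6, 1 - 1e-6))
        lam = (1 - h2) / h2
    else:
        su2, se2 = reml_fit(y, rel.A)
        lam = se2 / max(su2, 1e-12)
    if method == "grammar":
        return _tau_grammar(xt, yt, onet, lam, evals, float(x @ x))[0]
    return _tau_gls(xt, yt, onet, lam, evals)[0]


# ----------------------------------------------------------------------
# replicated experiment
# ----------------------------------------------------------------------

@dataclass
class SimConfig:
    """A replicated gene-dropping experiment over an h2 grid."""

    design: Union[HalfSibDesign, tuple]
    p: float = 0.5
    beta_allele: float = 0.20
    h2_grid: Sequence[float] = (0.0, 0.3, 0.6, 0.9)
    alpha: float = 0.05
    n_reps: int = 2000
    seed: int = 0
    methods: Sequence[str] = ("regression", "grammar", "fasta", "qtdt")
    varcomp: str = "reml"
    h2_used: Optional[float] = None
    mu: float = 0.0

    def resolve(self) -> tuple[Pedigree, list]:
        if isinstance(self.design, HalfSibDesign):
            return self.design.pedigree(), self.design.offspring_ids()
        ped, ids = self.design
        return ped, list(ids)

    @property
    def beta(self) -> float:
        return self.beta_allele * np.sqrt(2.0 * self.p * (1.0 - self.p))


def empirical_rates(config: SimConfig) -> pd.DataFrame:
    """Empirical type-1 error (H0 phenotype) and power (H1 phenotype) per
    design x h2 x method, with binomial Monte-Carlo standard errors.

    Both phenotypes of a replicate share genotypes, polygenic values and
    residuals; the H1 phenotype adds x*beta.  Replicates with a monomorphic
    SNP are skipped and counted.
    """
    ped, ids = config.resolve()
    pos = {a: i for i, a in enumerate(ped.ids)}
    idx = np.array([pos[a] for a in ids])
    n = len(ids)
    rel = build_A(ped).subset(ids)
    mend_sd = _mendelian_sd(ped)
    evals, U = np.linalg.eigh(rel.A)
    evals = np.clip(evals, 1e-12, None)
    onet = U.T @ np.ones(n)
    from scipy.stats import norm as _norm

    thr = float(_norm.ppf(1.0 - config.alpha / 2.0))
    rng = np.random.default_rng(config.seed)
    R = config.n_reps
    design_label = (
        f"{config.design.n_families}x{config.design.family_size}"
        if isinstance(config.design, HalfSibDesign)
        else "pedigree"
    )

    rows = []
    for h2 in config.h2_grid:
        params = ModelParams(
            h2_true=float(h2), beta=config.beta, p=config.p, mu=config.mu,
            h2_used=config.h2_used,
        )
        W, Z = gene_drop_matrix(ped, config.p, R, rng, subset=ids)
        u = _drop_polygenic(ped, np.sqrt(params.sigma_u2), rng, R, mend_sd)[idx]
        e = np.sqrt(params.sigma_e2) * rng.standard_normal((n, R))
        X = W - W.mean(axis=0)
        Y0 = params.mu + u + e
        Y1 = Y0 + X * params.beta
        # one big rotation into the eigenbasis of A, then O(n) per replicate
        Xt, Y0t, Y1t = U.T @ X, U.T @ Y0, U.T @ Y1

        taus = {(m, h): np.full(R, np.nan) for m in config.methods for h in ("H0", "H1")}
        betas = {(m, h): np.full(R, np.nan) for m in config.methods for h in ("H0", "H1")}
        skipped = 0
        for r in range(R):
            x = X[:, r]
            xx = float(x @ x)
            if xx < 1e-10:
                skipped += 1
                continue
            for hyp, y, yt in (("H0", Y0[:, r], Y0t[:, r]), ("H1", Y1[:, r], Y1t[:, r])):
                lam = None
                if {"grammar", "fasta"} & set(config.methods):
                    if config.varcomp == "true":
                        lam = params.lambda_true
                    elif config.varcomp == "fixed":
                        h2u = float(np.clip(config.h2_used, 1e-6, 1 - 1e-6))
                        lam = (1 - h2u) / h2u
                    else:
                        h2hat = _reml_h2(yt, onet, evals)
                        lam = (1.0 - h2hat) / h2hat
                for m in config.methods:
                    if m == "regression":
                        tau, b = _tau_regression(x, y)
                    elif m == "grammar":
                        tau, b = _tau_grammar(Xt[:, r], yt, onet, lam, evals, xx)
                    elif m == "fasta":
                        tau, b = _tau_gls(Xt[:, r], yt, onet, lam, evals)
                    elif m == "true":
                        tau, b = _tau_gls(Xt[:, r], yt, onet, params.lambda_true, evals)
                    elif m == "qtdt":
                        tau, b = _tau_qtdt(x, Z[:, r], y)
                    else:
                        raise ValueError(f"unknown method {m!r}")
                    taus[(m, hyp)][r] = tau
                    betas[(m, hyp)][r] = b
        for m in config.methods:
            for hyp in ("H0", "H1"):
                t = taus[(m, hyp)]
                ok = ~np.isnan(t)
                used = int(ok.sum())
                rate = float((np.abs(t[ok]) > thr).mean()) if used else np.nan
                rows.append({
                    "design": design_label,
                    "h2": float(h2),
                    "method": m,
                    "hypothesis": hyp,
                    "n_reps": used,
                    "n_skipped": skipped,
                    "rate": rate,
                    "mc_se": float(np.sqrt(max(rate * (1 - rate), 1e-12) / used)) if used else np.nan,
                    "mean_tau": float(t[ok].mean()),
                    "var_tau": float(t[ok].var(ddof=1)),
                    "mean_beta_hat": float(betas[(m, hyp)][ok].mean()),
                })
    return pd.DataFrame(rows)
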