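import numpy as np
import pytest
from hypothesis import settings

from assocpower.pedigree import Pedigree, build_A, halfsib_design

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_halfsib():
    """3 families x 4 half-sibs: pedigree, offspring relationship set."""
    ped, rel = halfsib_design(3, 4)
    return ped, rel


@pytest.fixture(scope="session")
def irregular_pedigree():
    """Two-generation pedigree with unequal families and full sibs; the
    tested animals are a terminal generation (no tested animal is a parent)."""
    founders = [(a, 0, 0) for a in ("s1", "s2", "s3", "d1", "d2", "d3", "d4", "d5")]
    offspring = [
        ("o1", "s1", "d1"), ("o2", "s1", "d1"), ("o3", "s1", "d2"),
        ("o4", "s2", "d3"), ("o5", "s2", "d3"), ("o6", "s2", "d4"),
        ("o7", "s1", "d3"), ("o8", "s3", "d5"), ("o9", "s3", "d5"),
        ("o10", "s3", "d1"),
    ]
    ped = Pedigree(founders + offspring)
    tested = [o[0] for o in offspring]
    return ped, tested


@pytest.fixture(scope="session")
def irregular_rel(irregular_pedigree):
    ped, tested = irregular_pedigree
    return build_A(ped).subset(tested)


def t_corrected_moments(tm):
    """Finite-sample (noncentral-t) mean and variance implied by the normal
    approximation moments: the statistic is a t-type ratio with tm.df
    denominator degrees of freedom, so tau ~ sqrt(V) * t_nc(delta = E/sqrt(V))
    up to the approximations shared with the analytic derivation."""
    from scipy.special import gammaln

    df, E, V = tm.df, tm.E_tau, tm.V_tau
    c1 = np.sqrt(df / 2.0) * np.exp(gammaln((df - 1) / 2.0) - gammaln(df / 2.0))
    E_t = E * c1
    V_t = (V + E**2) * df / (df - 2.0) - E_t**2
    return E_t, V_t


def mc_statistics(gv, A, params, hypothesis, reps, rng):
    """Monte-Carlo draw of all five statistics with the genotype vector held
    fixed; each statistic is computed from its textbook definition (OLS /
    BLUP residual regression / GLS / within-family OLS), independently of the
    package's analytic and simulator code paths."""
    from assocpower.models import resolve_lambda

    x, z = gv.x, gv.z
    n = x.size
    beta = params.beta if hypothesis == "H1" else 0.0
    L = np.linalg.cholesky(params.sigma_u2 * A + params.sigma_e2 * np.eye(n))
    Y = params.mu + beta * x[:, None] + L @ rng.standard_normal((n, reps))
    xx = float(x @ x)
    one = np.ones(n)
    out = {}

    # simple regression
    b = (x @ Y) / xx
    resid = Y - Y.mean(axis=0) - x[:, None] * b
    rss = (resid**2).sum(axis=0)
    out["regression"] = b / np.sqrt(rss / (n - 2) / xx)

    lam_hat = resolve_lambda(params, hypothesis)
    evals, U = np.linalg.eigh(A)
    xt, onet, Yt = U.T @ x, U.T @ one, U.T @ Y

    def gls_tau(lam):
        om = lam / (lam + evals)
        M = np.array([
            [onet @ (om * onet), onet @ (om * xt)],
            [xt @ (om * onet), xt @ (om * xt)],
        ])
        Minv = np.linalg.inv(M)
        rhs = np.vstack([(om * onet) @ Yt, (om * xt) @ Yt])
        coef = Minv @ rhs
        eqy = (om[:, None] * Yt * Yt).sum(axis=0) - (rhs * coef).sum(axis=0)
        return coef[1] / np.sqrt(eqy / (n - 2) * Minv[1, 1])

    # GRAMMAR: regress random-model BLUP residuals on x
    om = lam_hat / (lam_hat + evals)
    mu_gls = (onet * om) @ Yt / (onet @ (om * onet))
    Et = om[:, None] * (Yt - np.outer(onet, mu_gls))
    xe = xt @ Et
    bg = xe / xx
    rss = (Et**2).sum(axis=0) - ((onet @ Et) ** 2) / n - xe**2 / xx
    out["grammar"] = bg / np.sqrt(rss / (n - 2) / xx)

    out["fasta"] = gls_tau(lam_hat)
    out["true"] = gls_tau(params.lambda_true)

    if z is not None:
        Q = np.column_stack([one, z - z.mean(), (x - z)])
        Qinv = np.linalg.inv(Q.T @ Q)
        coef = Qinv @ (Q.T @ Y)
        resid = Y - Q @ coef
        rss = (resid**2).sum(axis=0)
        out["qtdt"] = coef[2] / np.sqrt(rss / (n - 3) * Qinv[2, 2])
    return out


def gene_drop_reference(ped, p, rng, reps):
    """Independent gene-dropping oracle (kept deliberately naive)."""
    pos = {a: i for i, a in enumerate(ped.ids)}
    alleles = np.empty((ped.n, 2, reps), dtype=np.int8)
    idx = np.arange(reps)
    for i, (_, sire, dam) in enumerate(ped.records):
        for k, parent in enumerate((sire, dam)):
            if parent is None:
                alleles[i, k] = rng.random(reps) < p
            else:
                j = pos[parent]
                alleles[i, k] = alleles[j, rng.integers(2, size=reps), idx]
    counts = alleles.sum(axis=1)
    w = (counts - 2 * p) / np.sqrt(2 * p * (1 - p))
    return w, pos
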