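"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a route disjoint from the library
implementation: tensor-product Gauss-Hermite quadrature for the GP
marginal likelihood and predictive probabilities, full hypergeometric
enumeration for Fisher's exact test, O(n^2) pair counting for the AUC,
n-fold refitting for Cook's distance, exhaustive sign-flip enumeration for
the Wilcoxon signed-rank test, and numerical integration of the t density
for the correlation p-value.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import quad
from scipy.special import ndtr


def gpc_quadrature(X, y, Xstar, sf2=1.0, jitter=1e-8, deg=50):
    """Exact (to quadrature accuracy) log marginal likelihood and
    predictive P(+1) for the probit GP with linear kernel, by integrating
    the n-dimensional latent prior on a tensor Gauss-Hermite grid."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    n = len(y)
    K = sf2 * (X @ X.T) + jitter * np.eye(n)
    L = np.linalg.cholesky(K)
    nodes, wts = hermegauss(deg)
    wts = wts / np.sqrt(2.0 * np.pi)  # N(0,1) expectation weights
    grids = np.meshgrid(*([nodes] * n), indexing="ij")
    Z = np.stack([g.ravel() for g in grids])
    idx = np.meshgrid(*([np.arange(deg)] * n), indexing="ij")
    W = np.ones(Z.shape[1])
    for k in range(n):
        W *= wts[idx[k].ravel()]
    F = L @ Z  # latent draws at the quadrature nodes, n x M
    lik = np.prod(ndtr(y[:, None] * F), axis=0)
    Zev = float(np.sum(W * lik))

    Ks = sf2 * (Xstar @ X.T)  # m x n
    kss = sf2 * np.sum(Xstar**2, axis=1)
    A = np.linalg.solve(K, Ks.T)  # n x m
    mu_c = F.T @ A  # M x m  conditional mean of f* given f
    var_c = np.maximum(kss - np.sum(Ks.T * A, axis=0), 1e-300)
    p = np.sum((W * lik)[:, None] * ndtr(mu_c / np.sqrt(1.0 + var_c)), axis=0) / Zev
    return math.log(Zev), p


def fisher_enumeration(table, rel_slack=1e-7):
    """Two-sided Fisher p by summing hypergeometric log-probabilities of
    every table sharing the observed margins whose probability is at most
    the observed one (probability-mass rule)."""
    t = np.asarray(table, dtype=int)
    r1, r2 = t.sum(axis=1)
    c1 = t[0, 0] + t[1, 0]
    total = r1 + r2

    def logp(a):
        return (
            math.lgamma(r1 + 1) - math.lgamma(a + 1) - math.lgamma(r1 - a + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - a + 1)
            - math.lgamma(r2 - (c1 - a) + 1)
            - (math.lgamma(total + 1) - math.lgamma(c1 + 1)
               - math.lgamma(total - c1 + 1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    lp_obs = logp(t[0, 0])
    cutoff = lp_obs + math.log1p(rel_slack)
    terms = [logp(a) for a in range(lo, hi + 1) if logp(a) <= cutoff]
    m = max(terms)
    return min(1.0, math.exp(m) * sum(math.exp(v - m) for v in terms))


def auc_pair_count(p, truth):
    """AUC as the exhaustive Mann-Whitney count over positive/negative
    pairs, ties counted one half."""
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth)
    pos = p[truth > 0]
    neg = p[truth <= 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def cooks_refit(x, y):
    """Cook distances via the defining leave-one-out refits:
    D_i = sum_j (yhat_j - yhat_j(i))^2 / (p * s^2), p = 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    A = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    yhat = A @ beta
    s2 = np.sum((y - yhat) ** 2) / (n - 2)
    D = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.lstsq(A[keep], y[keep], rcond=None)[0]
        D[i] = np.sum((yhat - A @ beta_i) ** 2) / (2.0 * s2)
    return D


def wilcoxon_signflip(a, b):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments of
    the nonzero differences (average ranks for ties)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (pos + (pos + (j - i))) / 2.0
        pos += j - i + 1
        i = j + 1
    w_plus_obs = float(np.sum(ranks[d > 0]))
    total = float(np.sum(ranks))
    center = total / 2.0
    dev_obs = abs(w_plus_obs - center)
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - center) >= dev_obs - 1e-12:
            count += 1
    return count / 2.0**n


def pearson_p_quadrature(rho, n):
    """Two-sided p of a Pearson correlation via numerical integration of
    the t_{n-2} density over the tail beyond the observed |t|."""
    df = n - 2
    t_obs = abs(rho) * math.sqrt(df / (1.0 - rho**2))
    c = math.exp(
        math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0)
    ) / math.sqrt(df * math.pi)

    def density(t):
        return c * (1.0 + t * t / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(density, t_obs, np.inf, epsabs=1e-14, epsrel=1e-12)
    return min(1.0, 2.0 * tail)
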