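"""Bayesian binary Gaussian-process classification with a linear kernel.

Model
-----
Latent function f ~ GP(0, k) with linear kernel k(x, x') = sigma_f^2 x.x'
(a small jitter is added to the training Gram matrix for conditioning),
observed through a cumulative-Gaussian (probit) likelihood
p(y_i = +1 | f_i) = Phi(f_i).  The intractable posterior over the latent
values is approximated by Expectation Propagation (EP): each likelihood
factor is replaced by a scaled Gaussian "site" with natural parameters
(tnu_i, ttau_i), refined by moment matching against the probit factor in
its cavity distribution until the sites stop moving.  If EP fails to
converge or loses positive-definiteness, a Laplace (mode + curvature)
approximation is used instead.

Predictions push the latent predictive Gaussian N(mu*, s2*) through the
probit link analytically: P(y* = +1) = Phi(mu* / sqrt(1 + s2*)), which is
why the classifier returns calibrated class probabilities rather than hard
labels.  For the linear kernel the latent predictive mean is a linear
functional of the test point, so the model admits an exact multivariate
weight vector w with mu*(x) = w.x.

The single kernel hyperparameter sigma_f^2 can be left fixed (log
sigma_f^2 = 0, sensible for z-scored features) or chosen by maximising the
EP approximation to the log marginal likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.special import log_ndtr, ndtr

__all__ = ["GPCModel", "WeightMap", "fit_gpc", "predict_proba", "extract_weights"]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(z: np.ndarray | float) -> np.ndarray | float:
    return np.exp(-0.5 * np.square(z)) / _SQRT_2PI


def _pdf_over_cdf(z):
    """N(z)/Phi(z), computed in log space so large negative z stay finite."""
    return np.exp(-0.5 * np.square(z) - np.log(_SQRT_2PI) - log_ndtr(z))


@dataclass(frozen=True)
class WeightMap:
    """Per-feature weights of the linear-kernel latent mean.

    The latent predictive mean at x equals ``weights @ x`` exactly.  Weights
    reflect the discriminative pattern — they are shaped by covariance
    between regions and do not directly measure group mean differences.
    """

    weights: np.ndarray
    feature_names: tuple[str, ...] | None = None
    class_convention: str = "+1"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.feature_names is not None and len(self.feature_names) != w.size:
            raise ValueError("feature_names length must match weights")


@dataclass
class GPCModel:
    """Fitted approximate-posterior state of the classifier.

    Stores everything needed to predict without refitting: the training
    inputs, the site natural parameters, and the representer coefficients
    ``alpha`` such that the latent predictive mean at x* is
    sigma_f^2 * sum_i alpha_i (x_i . x*).
    """

    train_features: np.ndarray
    train_labels: np.ndarray
    log_signal_variance: float
    site_tau: np.ndarray
    site_nu: np.ndarray
    posterior_mean_coeffs: np.ndarray
    log_marginal_likelihood: float
    jitter: float
    inference: str  # "ep" or "laplace"

    @property
    def n_train(self) -> int:
        return self.train_features.shape[0]

    @property
    def n_features(self) -> int:
        return self.train_features.shape[1]

    @property
    def signal_variance(self) -> float:
        return float(np.exp(self.log_signal_variance))

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "train_features": self.train_features.tolist(),
            "train_labels": self.train_labels.tolist(),
            "log_signal_variance": self.log_signal_variance,
            "site_tau": self.site_tau.tolist(),
            "site_nu": self.site_nu.tolist(),
            "posterior_mean_coeffs": self.posterior_mean_coeffs.tolist(),
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "jitter": self.jitter,
            "inference": self.inference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPCModel":
        return cls(
            train_features=np.asarray(d["train_features"], dtype=float),
            train_labels=np.asarray(d["train_labels"], dtype=float),
            log_signal_variance=float(d["log_signal_variance"]),
            site_tau=np.asarray(d["site_tau"], dtype=float),
            site_nu=np.asarray(d["site_nu"], dtype=float),
            posterior_mean_coeffs=np.asarray(
                d["posterior_mean_coeffs"], dtype=float
            ),
            log_marginal_likelihood=float(d["log_marginal_likelihood"]),
            jitter=float(d["jitter"]),
            inference=str(d["inference"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GPCModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _gram(X: np.ndarray, sf2: float, jitter: float) -> np.ndarray:
    K = sf2 * (X @ X.T)
    K[np.diag_indices_from(K)] += jitter
    return K


def _posterior_from_sites(K, ttau, tnu):
    """Recompute (Sigma, mu, L, sW) from site parameters; numerically stable
    form via the Cholesky factor of B = I + sW K sW."""
    n = K.shape[0]
    sW = np.sqrt(ttau)
    B = np.eye(n) + (sW[:, None] * K) * sW[None, :]
    L = cholesky(B, lower=True)
    V = solve_triangular(L, sW[:, None] * K, lower=True)
    Sigma = K - V.T @ V
    mu = Sigma @ tnu
    return Sigma, mu, L, sW


def _ep_inference(K, y, tol=1e-6, max_sweeps=100):
    """Expectation-Propagation sweeps with probit moment matching.

    Sites are visited in ascending index order (deterministic); negative
    site precisions are clipped to zero so site variances stay nonnegative.
    Returns (ttau, tnu, logZ, alpha) or raises RuntimeError.
    """
    n = K.shape[0]
    ttau = np.zeros(n)
    tnu = np.zeros(n)
    Sigma = K.copy()
    mu = np.zeros(n)
    converged = False
    for _ in range(max_sweeps):
        ttau_old = ttau.copy()
        tnu_old = tnu.copy()
        for i in range(n):
            s2_i = Sigma[i, i]
            tau_ni = 1.0 / s2_i - ttau[i]  # cavity precision
            nu_ni = mu[i] / s2_i - tnu[i]  # cavity nat. mean
            if tau_ni <= 0:
                # cavity collapsed; skip the update this sweep
                continue
            mu_ni = nu_ni / tau_ni
            s2_ni = 1.0 / tau_ni
            denom = np.sqrt(1.0 + s2_ni)
            z = y[i] * mu_ni / denom
            ratio = _pdf_over_cdf(z)
            # tilted (cavity x probit) moments
            mu_hat = mu_ni + y[i] * s2_ni * ratio / denom
            s2_hat = s2_ni - s2_ni**2 * ratio * (z + ratio) / (1.0 + s2_ni)
            if s2_hat <= 0:
                continue
            new_ttau = max(1.0 / s2_hat - tau_ni, 0.0)
            dtau = new_ttau - ttau[i]
            ttau[i] = new_ttau
            tnu[i] = mu_hat / s2_hat - nu_ni
            # rank-1 downdate of Sigma, then refresh mu
            si = Sigma[:, i].copy()
            Sigma -= (dtau / (1.0 + dtau * s2_i)) * np.outer(si, si)
            mu = Sigma @ tnu
        try:
            Sigma, mu, L, sW = _posterior_from_sites(K, ttau, tnu)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise RuntimeError("EP posterior lost positive-definiteness") from exc
        delta = max(
            np.max(np.abs(ttau - ttau_old), initial=0.0),
            np.max(np.abs(tnu - tnu_old), initial=0.0),
        )
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"EP did not converge within {max_sweeps} sweeps")

    # EP approximation to the log marginal likelihood (zero prior mean)
    diag = np.diag(Sigma)
    tau_n = 1.0 / diag - ttau
    nu_n = mu / diag - tnu
    if np.any(tau_n <= 0):
        raise RuntimeError("negative cavity precision at convergence")
    mu_n = nu_n / tau_n
    z = y * mu_n / np.sqrt(1.0 + 1.0 / tau_n)
    lZ = log_ndtr(z)
    nlZ = (
        np.sum(np.log(np.diag(L)))
        - np.sum(lZ)
        - 0.5 * tnu @ Sigma @ tnu
        - 0.5 * nu_n @ ((ttau / tau_n * nu_n - 2.0 * tnu) / (ttau + tau_n))
        + 0.5 * np.sum(tnu**2 / (tau_n + ttau))
        - 0.5 * np.sum(np.log1p(ttau / tau_n))
    )
    alpha = _alpha_from_sites(K, ttau, tnu)
    return ttau, tnu, float(-nlZ), alpha


def _alpha_from_sites(K, ttau, tnu):
    """alpha with latent mean mu* = k*.alpha, i.e. (K + S^-1)^-1 S^-1 tnu
    rewritten without inverting S."""
    n = K.shape[0]
    sW = np.sqrt(ttau)
    B = np.eye(n) + (sW[:, None] * K) * sW[None, :]
    L = cholesky(B, lower=True)
    t = solve_triangular(L, sW * (K @ tnu), lower=True)
    return tnu - sW * solve_triangular(L.T, t, lower=False)


def _laplace_inference(K, y, tol=1e-9, max_iter=100):
    """Laplace approximation: Newton ascent to the posterior mode.

    Returns equivalent site parameters (W, nu) so prediction code is shared
    with EP, plus the Laplace evidence approximation.
    """
    n = K.shape[0]
    f = np.zeros(n)
    obj_old = -np.inf
    for _ in range(max_iter):
        z = y * f
        ratio = _pdf_over_cdf(z)
        grad = y * ratio
        W = ratio * (z + ratio)  # -d2 log lik, in (0,1) for probit
        sW = np.sqrt(W)
        B = np.eye(n) + (sW[:, None] * K) * sW[None, :]
        L = cholesky(B, lower=True)
        b = W * f + grad
        t = solve_triangular(L, sW * (K @ b), lower=True)
        a = b - sW * solve_triangular(L.T, t, lower=False)
        f = K @ a
        obj = -0.5 * a @ f + np.sum(log_ndtr(y * f))
        if abs(obj - obj_old) < tol:
            break
        obj_old = obj
    z = y * f
    ratio = _pdf_over_cdf(z)
    W = ratio * (z + ratio)
    sW = np.sqrt(W)
    B = np.eye(n) + (sW[:, None] * K) * sW[None, :]
    L = cholesky(B, lower=True)
    a = np.linalg.solve(K, f)
    logZ = (
        -0.5 * a @ f + np.sum(log_ndtr(y * f)) - np.sum(np.log(np.diag(L)))
    )
    # express as sites: precision W, natural mean such that mean matches mode
    tnu = W * f + (y * ratio)
    return W, tnu, float(logZ), a


def _fit_at(X, y, log_sf2, jitter, tol, max_sweeps):
    K = _gram(X, float(np.exp(log_sf2)), jitter)
    try:
        ttau, tnu, logZ, alpha = _ep_inference(K, y, tol=tol, max_sweeps=max_sweeps)
        inference = "ep"
    except RuntimeError:
        ttau, tnu, logZ, alpha = _laplace_inference(K, y)
        inference = "laplace"
    return ttau, tnu, logZ, alpha, inference


def fit_gpc(
    X: np.ndarray,
    y: Sequence[int] | np.ndarray,
    optimize_hyperparameters: bool = False,
    seed: int | None = None,
    *,
    jitter: float = 1e-8,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> GPCModel:
    """Fit the probit GP classifier on (X, y) with y in {-1, +1}.

    The fit is deterministic given its inputs; ``seed`` is accepted for
    interface uniformity with stochastic stages but never consumed.  With
    ``optimize_hyperparameters`` the signal variance is chosen by bounded
    maximisation of the approximate log marginal likelihood over
    log sigma_f^2 in [-8, 8]; otherwise log sigma_f^2 = 0.
    """
    del seed  # deterministic algorithm
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects × features)")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match number of rows of X")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be coded -1/+1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")

    if optimize_hyperparameters:
        def neg_logz(log_sf2: float) -> float:
            try:
                return -_fit_at(X, y, log_sf2, jitter, tol, max_sweeps)[2]
            except (RuntimeError, np.linalg.LinAlgError):
                return np.inf

        res = minimize_scalar(
            neg_logz, bounds=(-8.0, 8.0), method="bounded",
            options={"xatol": 1e-6, "maxiter": 200},
        )
        log_sf2 = float(res.x)
    else:
        log_sf2 = 0.0

    ttau, tnu, logZ, alpha, inference = _fit_at(
        X, y, log_sf2, jitter, tol, max_sweeps
    )
    return GPCModel(
        train_features=X,
        train_labels=y,
        log_signal_variance=log_sf2,
        site_tau=ttau,
        site_nu=tnu,
        posterior_mean_coeffs=alpha,
        log_marginal_likelihood=logZ,
        jitter=jitter,
        inference=inference,
    )


def latent_predictive(model: GPCModel, Xstar: np.ndarray):
    """Mean and variance of the latent function at each test point."""
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.n_features:
        raise ValueError(
            f"test points have {Xstar.shape[1]} features, "
            f"model was trained on {model.n_features}"
        )
    sf2 = model.signal_variance
    Kstar = sf2 * (Xstar @ model.train_features.T)  # m × n
    mu = Kstar @ model.posterior_mean_coeffs
    K = _gram(model.train_features, sf2, model.jitter)
    sW = np.sqrt(model.site_tau)
    n = model.n_train
    B = np.eye(n) + (sW[:, None] * K) * sW[None, :]
    L = cholesky(B, lower=True)
    V = solve_triangular(L, sW[:, None] * Kstar.T, lower=True)
    kss = sf2 * np.sum(Xstar**2, axis=1)
    var = np.maximum(kss - np.sum(V**2, axis=0), 1e-12)
    return mu, var


def predict_proba(model: GPCModel, Xstar: np.ndarray) -> np.ndarray:
    """P(class = +1) per test row, from the probit-averaged latent Gaussian.

    Values are strictly inside (0, 1): finite predictive variance keeps the
    averaged probit away from the endpoints.
    """
    mu, var = latent_predictive(model, Xstar)
    p = ndtr(mu / np.sqrt(1.0 + var))
    eps = np.finfo(float).tiny
    return np.clip(p, eps, 1.0 - eps)


def extract_weights(
    model: GPCModel, feature_names: Sequence[str] | None = None
) -> WeightMap:
    """Multivariate weight vector w = sigma_f^2 X^T alpha of the linear
    latent mean, so that mu*(x) = w . x exactly."""
    w = model.signal_variance * (model.train_features.T @ model.posterior_mean_coeffs)
    return WeightMap(
        weights=w,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )
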