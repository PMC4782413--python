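"""Score statistics of the global association test, with exact decompositions.

The null hypothesis of no association between a count response y and a
covariate matrix X (n samples x p covariates) is phrased through a
random-effects model: the p regression coefficients are random with mean
zero and variance tau^2, and H0: tau^2 = 0 is tested by a score statistic.
The covariates enter only through the similarity kernel R = (1/p) X X^T,
so the statistic is well defined for p >> n and for perfectly collinear
covariates.

With weighted residuals e_i = (y_i - mu_i) / (1 + phi*mu_i) and trace
weights w_i = mu_i (1 + phi*y_i) / (1 + phi*mu_i)^2, the negative binomial
statistic is

    u_nb = (1/2) e' R e  -  (1/2) sum_i R_ii w_i,

which at phi = 0 reduces exactly to the Poisson form
u_pois = (1/2) res' R res - (1/2) sum_i R_ii mu_i with raw residuals.
Large values are evidence against H0. The statistic decomposes exactly
into per-sample and per-covariate contributions, each summing to u_nb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError


@dataclass
class CovariateSet:
    """A covariate matrix (samples x covariates) with its similarity kernel."""

    X: np.ndarray
    covariate_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.size == 0:
            raise InvalidInputError("X must be a non-empty 2-d matrix")
        self.X = X
        if self.covariate_ids is None:
            self.covariate_ids = [f"cov{j}" for j in range(X.shape[1])]
        elif len(self.covariate_ids) != X.shape[1]:
            raise InvalidInputError("covariate_ids length must equal the number of columns")
        self._kernel: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def kernel(self) -> np.ndarray:
        if self._kernel is None:
            self._kernel = covariance_kernel(self.X)
        return self._kernel


@dataclass
class Decomposition:
    """Per-sample and per-covariate contributions; each sums to the statistic."""

    sample_contrib: np.ndarray
    covariate_contrib: np.ndarray


def covariance_kernel(X: np.ndarray) -> np.ndarray:
    """Similarity kernel R = (1/p) X X^T between samples."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] < 1 or X.shape[0] < 1:
        raise InvalidInputError("X must have at least one row and one column")
    return X @ X.T / X.shape[1]


def _weights(y, mu_hat, phi_hat):
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu_hat, dtype=float)
    if y.shape != mu.shape:
        raise InvalidInputError("y and mu_hat must have the same length")
    if np.any(mu <= 0):
        raise InvalidInputError("mu_hat must be strictly positive")
    if phi_hat < 0:
        raise InvalidInputError("phi_hat must be non-negative")
    denom = 1.0 + phi_hat * mu
    e = (y - mu) / denom
    w = mu * (1.0 + phi_hat * y) / denom**2
    return e, w


def _check_kernel(R: np.ndarray, n: int) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (n, n):
        raise InvalidInputError("R must be n x n")
    return R


def nb_statistic(y, mu_hat, phi_hat: float, R: np.ndarray) -> float:
    """Negative binomial score statistic u_nb."""
    e, w = _weights(y, mu_hat, phi_hat)
    R = _check_kernel(R, e.size)
    return float(0.5 * e @ R @ e - 0.5 * np.diag(R) @ w)


def pois_statistic(y, mu_hat, R: np.ndarray) -> float:
    """Poisson score statistic u_pois (the phi = 0 case of u_nb)."""
    return nb_statistic(y, mu_hat, 0.0, R)


def sample_contributions(y, mu_hat, phi_hat: float, R: np.ndarray) -> np.ndarray:
    """Contribution s_i of each sample; sum_i s_i = u_nb exactly."""
    e, w = _weights(y, mu_hat, phi_hat)
    R = _check_kernel(R, e.size)
    return 0.5 * e * (R @ e) - 0.5 * np.diag(R) * w


def covariate_contributions(y, mu_hat, phi_hat: float, X: np.ndarray) -> np.ndarray:
    """Contribution c_j of each covariate; sum_j c_j = u_nb exactly.

    p * c_j equals the statistic that would be obtained from testing
    covariate j alone, so c_j is interpretable on its own and independent
    of the other covariates.
    """
    e, w = _weights(y, mu_hat, phi_hat)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != e.size:
        raise InvalidInputError("X must have one row per sample")
    p = X.shape[1]
    t = X.T @ e
    return (t**2 - (X**2).T @ w) / (2.0 * p)


def group_statistic(y, mu_hat, phi_hat: float, X: np.ndarray, group: Sequence[int]) -> float:
    """Statistic for a group of covariates: the mean of their single-covariate statistics.

    Equals nb_statistic computed on the column subset X[:, group].
    """
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise InvalidInputError("group must be non-empty")
    X = np.asarray(X, dtype=float)
    c = covariate_contributions(y, mu_hat, phi_hat, X)
    return float(np.mean(X.shape[1] * c[group]))


def batch_statistics(e: np.ndarray, w: np.ndarray, R: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Statistics for many joint permutations of (y, mu_hat) at once.

    Permuting the response together with the fitted means permutes the
    residual and trace-weight vectors while R stays fixed; alpha_hat and
    phi_hat do not change under permutation, so e and w are precomputed.

    Parameters
    ----------
    e, w
        Weighted residuals and trace weights of the *unpermuted* data.
    perms
        Integer array (k, n); each row is a permutation of 0..n-1.
    """
    E = e[perms]
    W = w[perms]
    return 0.5 * np.einsum("ki,ki->k", E @ R, E) - 0.5 * W @ np.diag(R)
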