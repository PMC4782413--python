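"""Intercept-only negative binomial / Poisson null model with library-size offsets.

For one gene the counts are modelled as y_i ~ NB(mu_i, phi) with
E[y_i] = mu_i, Var[y_i] = mu_i + phi * mu_i**2, and a logarithmic link.
Unequal sequencing depths enter through the offset log(m_i / mbar), where
m_i is the library size of sample i and mbar the geometric mean of all
library sizes, so that under the null hypothesis

    mu_i = (m_i / mbar) * exp(alpha).

The null fit (alpha_hat, phi_hat, mu_hat) is shared by every test statistic
and is *not* re-estimated under permutation: maximum likelihood for an
intercept-only model does not depend on the order of the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .exceptions import DegenerateResponseError, InvalidInputError

Family = Literal["negative_binomial", "poisson"]

_PHI_LO = 1e-8  # lower edge of the interior dispersion search (log scale)
_PHI_HI = 1e4


@dataclass
class CountResponse:
    """Counts for one gene, with optional library sizes.

    Parameters
    ----------
    y
        Non-negative integer counts, one per sample.
    m
        Positive library sizes; defaults to all ones.
    offset_enabled
        Whether the offset log(m_i / mbar) enters the model. Defaults to
        True exactly when library sizes are supplied, and can be switched
        off explicitly for depth-adjusted data.
    """

    y: np.ndarray
    m: np.ndarray | None = None
    offset_enabled: bool | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 1 or y.size == 0:
            raise InvalidInputError("y must be a non-empty 1-d vector")
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise InvalidInputError("counts must be non-negative integers")
        self.y = np.round(y).astype(np.int64)
        if self.offset_enabled is None:
            self.offset_enabled = self.m is not None
        if self.m is None:
            self.m = np.ones(self.y.size, dtype=float)
        else:
            m = np.asarray(self.m, dtype=float)
            if m.shape != self.y.shape:
                raise InvalidInputError("m must match y in length")
            if np.any(m <= 0):
                raise InvalidInputError("library sizes must be positive")
            self.m = m

    @property
    def n(self) -> int:
        return self.y.size

    def multipliers(self) -> np.ndarray:
        """Per-sample mean multipliers m_i/mbar (geometric mean 1), or ones."""
        if not self.offset_enabled:
            return np.ones(self.n)
        return np.exp(compute_offsets(self.m))


@dataclass
class NullFit:
    """Maximum-likelihood null fit of one gene."""

    family: Family
    alpha_hat: float
    phi_hat: float
    mu_hat: np.ndarray
    loglik: float
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "alpha_hat": float(self.alpha_hat),
            "phi_hat": float(self.phi_hat),
            "mu_hat": [float(v) for v in self.mu_hat],
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NullFit":
        return cls(
            family=d["family"],
            alpha_hat=float(d["alpha_hat"]),
            phi_hat=float(d["phi_hat"]),
            mu_hat=np.asarray(d["mu_hat"], dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d.get("converged", True)),
        )


def compute_offsets(m: np.ndarray) -> np.ndarray:
    """Offsets log(m_i/mbar) with mbar the geometric mean of the library sizes.

    The returned vector sums to zero, so the multipliers exp(offset) have
    geometric mean one.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 1 or m.size == 0:
        raise InvalidInputError("m must be a non-empty 1-d vector")
    if np.any(m <= 0):
        raise InvalidInputError("library sizes must be positive")
    logm = np.log(m)
    return logm - logm.mean()


def nb_log_likelihood(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Negative binomial log-likelihood sum_i log f(y_i; mu_i, phi).

    Uses the mean/dispersion parametrisation Var = mu + phi*mu**2; phi=0 is
    the Poisson limit. Evaluated in a form that is numerically continuous
    in phi at zero: the Gamma-ratio term Gamma(y+1/phi)/Gamma(1/phi) is
    expanded as the exact product prod_{t<y} (1 + t*phi) for integer y.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise InvalidInputError("y and mu must have the same length")
    if np.any(mu <= 0):
        raise InvalidInputError("mu must be strictly positive")
    if phi < 0:
        raise InvalidInputError("phi must be non-negative")
    yi = np.round(y).astype(np.int64)
    if phi == 0:
        return float(np.sum(yi * np.log(mu) - mu - gammaln(yi + 1.0)))
    ymax = int(yi.max())
    # lg[v] = sum_{t=0}^{v-1} log(1 + t*phi) = gammaln(v + 1/phi) - gammaln(1/phi) - v*log(1/phi)
    lg = np.concatenate(([0.0], np.cumsum(np.log1p(phi * np.arange(ymax, dtype=float)))))
    ll = (
        yi * (np.log(mu) - np.log1p(mu * phi))
        - np.log1p(mu * phi) / phi
        + lg[yi]
        - gammaln(yi + 1.0)
    )
    return float(np.sum(ll))


def _solve_alpha(y: np.ndarray, c: np.ndarray, phi: float, alpha0: float) -> float:
    """Newton root of the score in alpha: sum (y_i - mu_i)/(1 + phi*mu_i) = 0.

    The score is strictly decreasing in alpha, so safeguarded Newton from
    any start converges to the unique root.
    """
    alpha = alpha0
    for _ in range(200):
        mu = c * np.exp(alpha)
        denom = 1.0 + phi * mu
        g = np.sum((y - mu) / denom)
        dg = -np.sum(mu * (1.0 + phi * y) / denom**2)
        step = g / dg
        step = np.clip(step, -5.0, 5.0)  # guard against overflow far from the root
        alpha -= step
        if abs(step) < 1e-13 * max(1.0, abs(alpha)):
            break
    return float(alpha)


def fit_null(resp: CountResponse, family: Family = "negative_binomial") -> NullFit:
    """Fit the intercept-only null model by maximum likelihood.

    Poisson: closed form, exp(alpha_hat) = mbar * sum(y) / sum(m).
    Negative binomial: profile likelihood over log(phi) (bounded scalar
    maximisation) with Newton steps in alpha inside; the dispersion is
    initialised by method of moments and clamped to the boundary phi=0
    whenever the Poisson fit is at least as likely, in which case the
    statistic reduces exactly to its Poisson form.
    """
    if family not in ("negative_binomial", "poisson"):
        raise InvalidInputError(f"unknown family: {family!r}")
    y = resp.y.astype(float)
    if resp.n < 2:
        raise InvalidInputError("need at least two samples")
    if np.all(resp.y == 0):
        raise DegenerateResponseError("all counts are zero; intercept MLE diverges")
    c = resp.multipliers()

    alpha_p = float(np.log(y.sum() / c.sum()))
    mu_p = c * np.exp(alpha_p)
    ll_p = nb_log_likelihood(resp.y, mu_p, 0.0)
    if family == "poisson":
        return NullFit("poisson", alpha_p, 0.0, mu_p, ll_p)

    def profile(log_phi: float) -> tuple[float, float]:
        phi = float(np.exp(log_phi))
        a = _solve_alpha(y, c, phi, alpha_p)
        return nb_log_likelihood(resp.y, c * np.exp(a), phi), a

    # method-of-moments start; only used to seed a local refinement below
    ybar = y.mean()
    phi_mom = max(0.0, (y.var() - ybar) / ybar**2) if ybar > 0 else 0.0

    res = minimize_scalar(
        lambda lp: -profile(lp)[0],
        bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best_lp, best_ll = float(res.x), float(-res.fun)
    if phi_mom > _PHI_LO:
        ll_mom = profile(np.log(phi_mom))[0]
        if ll_mom > best_ll:  # bounded search missed the mode; restart nearby
            res2 = minimize_scalar(
                lambda lp: -profile(lp)[0],
                bounds=(np.log(phi_mom) - 3.0, np.log(phi_mom) + 3.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if -res2.fun > best_ll:
                best_lp, best_ll = float(res2.x), float(-res2.fun)

    if best_ll <= ll_p + 1e-8:
        # boundary: overdispersion absent, NB reduces to Poisson
        return NullFit("negative_binomial", alpha_p, 0.0, mu_p, ll_p)
    phi_hat = float(np.exp(best_lp))
    alpha_hat = _solve_alpha(y, c, phi_hat, alpha_p)
    mu_hat = c * np.exp(alpha_hat)
    return NullFit("negative_binomial", alpha_hat, phi_hat, mu_hat, best_ll)
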