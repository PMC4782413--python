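"""Joint testing of several covariate sets against one count response.

When gene expression may respond to several molecular profiles at once
(e.g. copy number and promoter methylation), each profile X_s gets its own
random-effects variance component, and the joint null hypothesis sets all
of them to zero. The joint statistic is the standardised sum of the
per-set statistics,

    u_joint = sum_s (u(X_s) - E^[u(X_s)]) / sqrt(Var^[u(X_s)]),

where the moments are estimated from the same shared permutation stream
that drives every set. Correlation between the per-set statistics is
deliberately ignored: it costs little power and keeps the statistic a
plain sum. The observed draw is included both in the moment estimates and
in the p-value count, so a joint test of a single set reproduces the crude
per-set p-value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSetError, InvalidInputError
from .global_test import CovariateSet, batch_statistics, _weights
from .null_model import CountResponse, Family, fit_null
from .permutation import generate_permutations, permutation_pvalue


@dataclass
class SetSummary:
    set_id: str
    u_obs: float
    mean: float
    variance: float
    z: float
    p_value: float


@dataclass
class JointTestResult:
    per_set: list[SetSummary]
    u_joint_obs: float
    u_joint_perm: np.ndarray
    p_joint: float
    k: int
    seed: int


def estimate_moments(perm_stats) -> tuple[float, float]:
    """Sample mean and variance (denominator k) of permuted statistics."""
    perm_stats = np.asarray(perm_stats, dtype=float)
    if perm_stats.size < 2:
        raise InvalidInputError("need at least two statistics to estimate moments")
    mean = float(perm_stats.mean())
    var = float(perm_stats.var())  # denominator k
    if var <= 0.0:
        raise DegenerateSetError("permuted statistics are constant for this set")
    return mean, var


def joint_statistic(u_values, moments) -> float:
    """Standardised sum of per-set statistics; extends to any number of sets."""
    u_values = np.asarray(u_values, dtype=float)
    if len(moments) != u_values.size:
        raise InvalidInputError("one (mean, variance) pair per set required")
    total = 0.0
    for u, (mean, var) in zip(u_values, moments):
        if not np.isfinite(mean) or not np.isfinite(var) or var <= 0.0:
            raise InvalidInputError("moments must be finite with positive variance")
        total += (u - mean) / np.sqrt(var)
    return float(total)


def run_joint_test(
    resp: CountResponse,
    sets,
    family: Family = "negative_binomial",
    k: int = 1000,
    strata=None,
    seed: int = 0,
    set_ids=None,
) -> JointTestResult:
    """Joint permutation test over multiple covariate sets.

    One shared permutation stream drives all sets, so per-set and joint
    p-values are directly comparable. Per-set moments are estimated from
    the k draws (observed plus k-1 permuted), and every permutation's joint
    statistic is standardised with those same global moments.
    """
    if k < 2:
        raise InvalidInputError("k must be at least 2")
    csets = [s if isinstance(s, CovariateSet) else CovariateSet(np.asarray(s, float)) for s in sets]
    if not csets:
        raise InvalidInputError("need at least one covariate set")
    for s in csets:
        if s.n != resp.n:
            raise InvalidInputError("all covariate sets must share the sample order of the response")
    if set_ids is None:
        set_ids = [f"set{i}" for i in range(len(csets))]

    fit = fit_null(resp, family)
    e, w = _weights(resp.y.astype(float), fit.mu_hat, fit.phi_hat)
    perms = generate_permutations(resp.n, k - 1, strata, seed)

    per_set: list[SetSummary] = []
    z_obs_total = 0.0
    z_perm_total = np.zeros(k - 1)
    for sid, cs in zip(set_ids, csets):
        R = cs.kernel
        u_obs = float(0.5 * e @ R @ e - 0.5 * np.diag(R) @ w)
        u_perm = batch_statistics(e, w, R, perms)
        mean, var = estimate_moments(np.concatenate(([u_obs], u_perm)))
        sd = np.sqrt(var)
        z_obs_total += (u_obs - mean) / sd
        z_perm_total += (u_perm - mean) / sd
        per_set.append(
            SetSummary(
                set_id=sid,
                u_obs=u_obs,
                mean=mean,
                variance=var,
                z=(u_obs - mean) / sd,
                p_value=permutation_pvalue(u_obs, u_perm),
            )
        )
    p_joint = permutation_pvalue(z_obs_total, z_perm_total)
    return JointTestResult(
        per_set=per_set,
        u_joint_obs=float(z_obs_total),
        u_joint_perm=z_perm_total,
        p_joint=p_joint,
        k=k,
        seed=seed,
    )
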