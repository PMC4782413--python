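"""Synthetic data generator and simulation studies for the global test.

The generator emulates a local eQTL design: SNP dosage covariates with a
block-correlation structure (standing in for linkage disequilibrium), a
coefficient vector whose non-zero entries form one consecutive run with
values s (probability 0.8) or 2s (probability 0.2), a mean vector obtained
through the identity relation mu = X beta, and negative binomial responses
y_i ~ NB(mu_i, phi). Data under the null hypothesis are obtained by
shuffling the elements of mu before sampling, which preserves the marginal
count distribution while destroying the association with X.

The identity link in the generator is deliberate and is kept even though
the test itself uses a logarithmic link: the test is meant to detect
association, not to match the generating link.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError
from .global_test import CovariateSet, batch_statistics, _weights
from .null_model import CountResponse, fit_null
from .permutation import generate_permutations, permutation_pvalue, run_test


@dataclass
class SimulationConfig:
    """Study conditions for the simulation protocol.

    Defaults describe a modest bulk RNA-Seq eQTL setting: 50 samples, 20
    local SNPs in blocks of 5 with within-block latent correlation 0.5,
    minor-allele frequencies between 0.1 and 0.4, a run of 5 causal SNPs
    with effect size 1, and dispersion 0.5 (strong overdispersion, as seen
    in tumour cohorts). 200 alternative and 200 null replicates with 200
    permutations per test keep a full study in the minutes range.
    """

    n: int = 50
    p: int = 20
    r: int = 5
    s: float = 1.0
    phi: float = 0.5
    n_alt: int = 200
    n_null: int = 200
    k: int = 200
    seed: int = 1
    block_size: int = 5
    rho: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.4)
    baseline: float = 0.0
    family: str = "negative_binomial"

    def __post_init__(self) -> None:
        if not 1 <= self.r <= self.p:
            raise InvalidInputError("need 1 <= r <= p")
        if self.n_alt < 1 or self.n_null < 1:
            raise InvalidInputError("replicate counts must be positive")
        if self.phi < 0 or self.s < 0 or self.baseline < 0:
            raise InvalidInputError("phi, s and baseline must be non-negative")


@dataclass
class CoefficientVector:
    """Sparse non-negative coefficients: one consecutive run of r non-zeros."""

    beta: np.ndarray
    run_start: int


def synthetic_genotypes(n, p, block_size=5, rho=0.5, maf_range=(0.1, 0.4), rng=None):
    """SNP dosage matrix (0/1/2) with within-block correlation.

    Each column gets a latent Gaussian that is equicorrelated (rho) with the
    other columns of its block, then thresholded at the Hardy-Weinberg
    quantiles of a minor-allele frequency drawn uniformly from maf_range:
    P(0) = (1-maf)^2, P(1) = 2 maf (1-maf), P(2) = maf^2.
    """
    if not 0.0 <= rho < 1.0:
        raise InvalidInputError("rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidInputError("maf_range must lie within (0, 0.5]")
    if block_size < 1:
        raise InvalidInputError("block_size must be positive")
    rng = np.random.default_rng(rng)
    X = np.empty((n, p), dtype=float)
    for start in range(0, p, block_size):
        width = min(block_size, p - start)
        shared = rng.standard_normal((n, 1))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, width))
        maf = rng.uniform(lo, hi, size=width)
        t1 = norm.ppf((1.0 - maf) ** 2)
        t2 = norm.ppf((1.0 - maf) ** 2 + 2.0 * maf * (1.0 - maf))
        X[:, start : start + width] = (latent > t1).astype(float) + (latent > t2)
    return X


def draw_coefficients(p, r, s, rng=None, run_start=None, values=None) -> CoefficientVector:
    """Coefficient vector with r consecutive non-zeros valued s (80%) or 2s (20%).

    run_start and values allow shortening or lengthening an existing run in
    place (the r-varying study reuses the original subset rather than
    drawing a new one).
    """
    if r > p or r < 1:
        raise InvalidInputError("need 1 <= r <= p")
    rng = np.random.default_rng(rng)
    if run_start is None:
        run_start = int(rng.integers(0, p - r + 1))
    if run_start < 0 or run_start + r > p:
        raise InvalidInputError("run does not fit inside the coefficient vector")
    if values is None:
        values = np.where(rng.random(r) < 0.8, s, 2.0 * s)
    else:
        values = np.asarray(values, dtype=float)[:r]
        if values.size < r:
            raise InvalidInputError("not enough values to fill the run")
    beta = np.zeros(p)
    beta[run_start : run_start + r] = values
    return CoefficientVector(beta=beta, run_start=run_start)


def simulate_response(X, beta, phi, rng=None, null_shuffle=False, baseline=0.0):
    """Counts y_i ~ NB(mu_i, phi) with mu = X beta (+ optional baseline).

    null_shuffle permutes the elements of mu before sampling, giving data
    with the same marginal count distribution but no association with X.
    phi = 0 samples Poisson; mu_i = 0 yields y_i = 0 with probability one.
    Sampling uses the gamma-Poisson mixture, so Var[y] = mu + phi mu^2.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    mu = X @ beta + baseline
    if np.any(mu < 0):
        raise InvalidInputError("mean vector has negative entries; generator contract violated")
    if null_shuffle:
        mu = rng.permutation(mu)
    if phi < 0:
        raise InvalidInputError("phi must be non-negative")
    if phi == 0:
        return rng.poisson(mu).astype(np.int64)
    lam = rng.gamma(1.0 / phi, phi * mu)
    return rng.poisson(lam).astype(np.int64)


def _auc(p_alt, p_null) -> float:
    """Area under the ROC curve separating alternative from null replicates.

    Equals P(p_alt < p_null) + 0.5 P(tie) by the rank (Mann-Whitney)
    identity; 0.5 means no discrimination.
    """
    u = mannwhitneyu(p_null, p_alt, alternative="two-sided").statistic
    return float(u / (len(p_alt) * len(p_null)))


def _simulate_pvalues(config: SimulationConfig, X, beta, rng) -> tuple[np.ndarray, np.ndarray]:
    """p-values of n_alt alternative and n_null shuffled-mu null replicates."""
    p_alt = np.empty(config.n_alt)
    p_null = np.empty(config.n_null)
    if np.all(np.asarray(X) @ np.asarray(beta) + config.baseline == 0):
        raise InvalidInputError(
            "mean vector is identically zero; set a positive baseline for zero-effect arms"
        )
    for arr, n_rep, null in ((p_alt, config.n_alt, False), (p_null, config.n_null, True)):
        for i in range(n_rep):
            while True:
                y = simulate_response(
                    X, beta, config.phi, rng, null_shuffle=null, baseline=config.baseline
                )
                if y.max() > 0:  # all-zero genes are excluded from testing
                    break
            res = run_test(
                CountResponse(y),
                X,
                family=config.family,
                k=config.k,
                seed=int(rng.integers(2**31)),
            )
            arr[i] = res.p_value
    return p_alt, p_null


def power_study(
    config: SimulationConfig,
    factor: str | None = None,
    levels=None,
    alphas=(0.01, 0.05, 0.1),
) -> pd.DataFrame:
    """Power/type-I/ROC study, optionally varying one factor at a time.

    factor is one of "phi", "n", "s", "r" (or None for a single condition);
    everything else is held equal: the covariate matrix is drawn once at the
    largest sample size and truncated, and the coefficient run is shortened
    or lengthened in place rather than redrawn. Each condition runs n_alt
    alternative and n_null shuffled-mu null replicates and reports the AUC
    (rank formula) plus rejection rates at the given levels.
    """
    if factor is None:
        factor, levels = "s", [config.s]
    if factor not in ("phi", "n", "s", "r"):
        raise InvalidInputError(f"unknown factor: {factor!r}")
    levels = list(levels)
    rng = np.random.default_rng(config.seed)

    n_max = max([config.n] + ([int(v) for v in levels] if factor == "n" else []))
    r_max = max([config.r] + ([int(v) for v in levels] if factor == "r" else []))
    X_full = synthetic_genotypes(
        n_max, config.p, config.block_size, config.rho, config.maf_range, rng
    )
    run_start = int(rng.integers(0, config.p - r_max + 1))
    base_values = np.where(rng.random(r_max) < 0.8, 1.0, 2.0)  # unit-effect pattern

    rows = []
    for level in levels:
        cfg = replace(config, **{factor: (int(level) if factor in ("n", "r") else float(level))})
        X = X_full[: cfg.n]
        coef = draw_coefficients(
            cfg.p, cfg.r, cfg.s, rng, run_start=run_start, values=cfg.s * base_values
        )
        p_alt, p_null = _simulate_pvalues(cfg, X, coef.beta, rng)
        row = {"factor": factor, "level": level, "auc": _auc(p_alt, p_null)}
        for a in alphas:
            row[f"power_at_{a}"] = float(np.mean(p_alt <= a))
            row[f"type1_at_{a}"] = float(np.mean(p_null <= a))
        rows.append(row)
    return pd.DataFrame(rows)


def _individual_pvalues(y, X, family, k, seed) -> np.ndarray:
    """Single-covariate permutation p-values for every column of X at once.

    Uses the identity p * c_j = u(x_j): per-covariate statistics for all
    permutations come from the same decomposition algebra as the global
    statistic, with one shared permutation stream across covariates.
    """
    resp = CountResponse(np.asarray(y))
    fit = fit_null(resp, family)
    e, w = _weights(resp.y.astype(float), fit.mu_hat, fit.phi_hat)
    X = np.asarray(X, dtype=float)
    u_obs = 0.5 * (X.T @ e) ** 2 - 0.5 * (X**2).T @ w
    perms = generate_permutations(resp.n, k - 1, None, seed)
    E = e[perms]
    W = w[perms]
    U = 0.5 * (E @ X) ** 2 - 0.5 * W @ (X**2)
    counts = (U >= u_obs).sum(axis=0)
    return (1 + counts) / k


def joint_vs_individual_study(
    config: SimulationConfig, alpha: float = 0.05, null: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Compare one global test of all covariates with p individual tests.

    Per replicate a fresh covariate matrix is drawn and the coefficient
    vector takes exclusively non-zero values (the many-small-effects
    regime). The global p-value is compared with the minimum of the
    Benjamini-Hochberg-adjusted individual p-values. null=True shuffles mu,
    turning both arms into calibration checks.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.n_alt):
        X = synthetic_genotypes(
            config.n, config.p, config.block_size, config.rho, config.maf_range, rng
        )
        coef = draw_coefficients(config.p, config.p, config.s, rng)
        while True:
            y = simulate_response(
                X, coef.beta, config.phi, rng, null_shuffle=null, baseline=config.baseline
            )
            if y.max() > 0:
                break
        seed = int(rng.integers(2**31))
        res = run_test(CountResponse(y), X, family=config.family, k=config.k, seed=seed)
        p_ind = _individual_pvalues(y, X, config.family, config.k, seed)
        p_bh = multipletests(p_ind, method="fdr_bh")[1]
        rows.append(
            {
                "replicate": rep,
                "p_joint": res.p_value,
                "min_p_bh_individual": float(p_bh.min()),
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "power_joint": float(np.mean(table["p_joint"] <= alpha)),
        "power_individual": float(np.mean(table["min_p_bh_individual"] <= alpha)),
        "alpha": alpha,
    }
    return table, summary
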