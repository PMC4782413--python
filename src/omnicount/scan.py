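"""Genome-wide scan: one global test per gene, with BH correction across genes."""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateResponseError, InvalidInputError
from .global_test import CovariateSet
from .null_model import CountResponse
from .permutation import Strata, run_test
from .windows import GeneAnnotation, select_window_covariates

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene", "n_cov", "u", "p", "p_bh", "k", "flag"]


def gene_seed(master_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed derived from (master seed, gene id).

    Hash-based, so scan output does not depend on gene order and parallel
    fan-out stays reproducible.
    """
    digest = hashlib.sha256(f"{master_seed}:{gene_id}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def genomewide_scan(
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_positions: pd.DataFrame,
    annotations: list[GeneAnnotation],
    window_bp: int = 1000,
    anchor: str = "gene_body",
    family: str = "negative_binomial",
    k: int = 1000,
    strata: pd.Series | None = None,
    seed: int = 0,
    use_offsets: bool = True,
) -> pd.DataFrame:
    """Test every annotated gene against the covariates in its window.

    counts: genes x samples; covariates: features x samples (aligned by
    sample id, not position); covariate_positions: BED-like frame whose
    `name` column matches the covariate index. Library sizes are the
    per-sample totals of the count matrix when offsets are enabled. Genes
    with an empty window or without variation (constant counts, including
    all-zero) are skipped and flagged; BH adjustment runs across the genes
    actually tested.
    """
    samples = list(counts.columns)
    missing = set(samples) - set(covariates.columns)
    if missing:
        raise InvalidInputError(f"samples absent from covariate matrix: {sorted(missing)[:5]}")
    cov = covariates[samples]
    pos = covariate_positions.set_index("name").loc[cov.index].reset_index()

    strata_arr = None
    if strata is not None:
        missing = set(samples) - set(strata.index)
        if missing:
            raise InvalidInputError(f"samples absent from strata: {sorted(missing)[:5]}")
        strata_arr = Strata(strata.loc[samples].to_numpy())

    m = counts.sum(axis=0).to_numpy(dtype=float) if use_offsets else None

    rows = []
    for gene in annotations:
        flag = ""
        if gene.gene_id not in counts.index:
            logger.warning("gene %s not in count matrix; skipped", gene.gene_id)
            rows.append((gene.gene_id, 0, np.nan, np.nan, np.nan, k, "missing"))
            continue
        idx = select_window_covariates(gene, pos, window_bp, anchor)
        y = counts.loc[gene.gene_id].to_numpy()
        if idx.size == 0:
            flag = "empty_window"
        elif np.all(y == y[0]):
            flag = "constant"
        if flag:
            logger.warning("gene %s skipped (%s)", gene.gene_id, flag)
            rows.append((gene.gene_id, int(idx.size), np.nan, np.nan, np.nan, k, flag))
            continue
        X = CovariateSet(cov.iloc[idx].to_numpy().T, covariate_ids=list(cov.index[idx]))
        try:
            res = run_test(
                CountResponse(y, m=m, offset_enabled=use_offsets),
                X,
                family=family,
                k=k,
                strata=strata_arr,
                seed=gene_seed(seed, gene.gene_id),
            )
        except DegenerateResponseError:
            logger.warning("gene %s skipped (degenerate)", gene.gene_id)
            rows.append((gene.gene_id, int(idx.size), np.nan, np.nan, np.nan, k, "degenerate"))
            continue
        rows.append((gene.gene_id, X.p, res.u_obs, res.p_value, np.nan, k, ""))

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = table["p"].notna()
    if not tested.any():
        raise InvalidInputError("no testable genes")
    table.loc[tested, "p_bh"] = multipletests(table.loc[tested, "p"], method="fdr_bh")[1]
    return table
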