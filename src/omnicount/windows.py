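"""Window-based covariate selection around annotated genes.

Coordinates are 0-based half-open throughout. A covariate (SNP, methylation
site, copy-number probe) is a point at its BED start coordinate. Two anchor
modes are supported: "gene_body" selects positions in [start - w, end + w),
"gene_start" selects positions in [start - w, start + w) (useful when only
the transcription start matters). Strand is ignored: "start" is always the
smaller coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidInputError(f"gene {self.gene_id}: start > end")


def select_window_covariates(
    gene: GeneAnnotation,
    positions: pd.DataFrame,
    window_bp: int,
    anchor: str = "gene_body",
) -> np.ndarray:
    """Indices (into `positions`) of covariates within the window around a gene.

    positions is a BED-like frame with columns chrom/start/name. The window
    edges are closed on the left and open on the right; a covariate exactly
    at start - window_bp is included. An empty selection is returned as an
    empty index array (callers skip the gene with a warning).
    """
    if window_bp < 0:
        raise InvalidInputError("window_bp must be non-negative")
    if anchor not in ("gene_body", "gene_start"):
        raise InvalidInputError(f"unknown anchor: {anchor!r}")
    lo = gene.start - window_bp
    hi = (gene.end if anchor == "gene_body" else gene.start) + window_bp
    pos = positions["start"].to_numpy()
    mask = (positions["chrom"].to_numpy() == gene.chrom) & (pos >= lo) & (pos < hi)
    return np.flatnonzero(mask)
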