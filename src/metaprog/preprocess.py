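"""Gene filtering and library-size normalization.

Produces the non-negative log1p(CP10K) matrix used both as NMF input and as
the expression basis for module scoring.  Normalization is per sample:
library sizes are computed within each sample, matching a per-sample
factorization design.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CountMatrix, NormalizedMatrix
from .errors import ContractError, DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = ["filter_genes", "normalize_cp10k_log1p"]


def filter_genes(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Retain genes detected (count > 0) in at least ``min_cells`` cells.

    Gene order is preserved; cells are untouched.  Raises
    :class:`DegenerateInputError` if no gene survives.
    """
    if min_cells < 0:
        raise ContractError("min_cells must be >= 0")
    detected = (m.counts > 0).sum(axis=1)
    keep = np.nonzero(detected >= min_cells)[0]
    if keep.size == 0:
        raise DegenerateInputError(
            f"no gene of sample {m.sample_id} is detected in "
            f">= {min_cells} cells")
    if keep.size == m.n_genes:
        return m
    return CountMatrix(
        sample_id=m.sample_id,
        gene_ids=[m.gene_ids[i] for i in keep],
        cell_ids=list(m.cell_ids),
        counts=m.counts[keep, :],
    )


def normalize_cp10k_log1p(m: CountMatrix, target_sum: float = 1e4
                          ) -> NormalizedMatrix:
    """log1p counts-per-10K: ``value_gc = log1p(count_gc / libsize_c * 1e4)``.

    Cells with zero total count cannot be normalized and are dropped with a
    warning.
    """
    libsize = m.counts.sum(axis=0).astype(np.float64)
    keep = np.nonzero(libsize > 0)[0]
    cell_ids = list(m.cell_ids)
    counts = m.counts
    if keep.size < m.n_cells:
        dropped = m.n_cells - keep.size
        logger.warning("sample %s: dropping %d zero-count cell(s)",
                       m.sample_id, dropped)
        counts = counts[:, keep]
        libsize = libsize[keep]
        cell_ids = [cell_ids[i] for i in keep]
    values = np.log1p(counts / libsize[None, :] * target_sum)
    return NormalizedMatrix(m.sample_id, list(m.gene_ids), cell_ids, values)
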