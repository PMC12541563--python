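"""Core in-memory containers shared across pipeline stages.

Both containers keep genes as rows and cells as columns, mirroring the
10x-style Matrix-Market layout used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError


def _check_ids(name: str, ids: list[str]) -> None:
    if len(set(ids)) != len(ids):
        raise FormatError(f"{name} contain duplicates")


def pooled_cell_id(sample_id: str, cell_id: str) -> str:
    """Cohort-wide cell identifier: barcodes may repeat across samples."""
    return f"{sample_id}:{cell_id}"


@dataclass
class CountMatrix:
    """One sample's genes x cells non-negative integer count matrix."""

    sample_id: str
    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray  # (n_genes, n_cells) integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D genes x cells matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_ids("gene_ids", self.gene_ids)
        _check_ids("cell_ids", self.cell_ids)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise FormatError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class NormalizedMatrix:
    """log1p(CP10K) expression values for one sample (genes x cells)."""

    sample_id: str
    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray = field(repr=False)  # (n_genes, n_cells) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("values shape does not match identifier lists")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)
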