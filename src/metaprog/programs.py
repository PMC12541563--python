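"""Turn NMF factors into ranked gene programs (top-N genes per factor)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io import GeneSetCollection
from .nmf import NMFFactorization

__all__ = ["Program", "extract_programs", "programs_to_gene_sets"]


@dataclass
class Program:
    """Top-N genes of one NMF factor of one sample, by decreasing loading."""

    program_id: str
    sample_id: str
    factor_index: int
    genes: list[str]
    loadings: list[float]

    @property
    def n(self) -> int:
        return len(self.genes)


def extract_programs(f: NMFFactorization, n_top: int = 50) -> list[Program]:
    """One :class:`Program` per factor: the ``n_top`` largest loadings.

    Ties are broken by lexicographic gene id, so extraction is deterministic
    even under exactly equal loadings.
    """
    n_genes = len(f.gene_ids)
    if not 1 <= n_top <= n_genes:
        raise ConfigurationError(
            f"n_top={n_top} must be in [1, {n_genes}]")
    gene_arr = np.asarray(f.gene_ids)
    out = []
    for j in range(f.k):
        col = f.W[:, j]
        # primary: loading descending; secondary: gene id ascending
        order = np.lexsort((gene_arr, -col))[:n_top]
        out.append(Program(
            program_id=f"{f.sample_id}_F{j + 1:02d}",
            sample_id=f.sample_id,
            factor_index=j,
            genes=[f.gene_ids[i] for i in order],
            loadings=[float(col[i]) for i in order],
        ))
    return out


def programs_to_gene_sets(programs: list[Program]) -> GeneSetCollection:
    """Export programs as one GMT collection (set name = program_id)."""
    return GeneSetCollection(
        sets={p.program_id: list(p.genes) for p in programs},
        descriptions={p.program_id:
                      f"sample={p.sample_id} factor={p.factor_index + 1}"
                      for p in programs},
    )
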