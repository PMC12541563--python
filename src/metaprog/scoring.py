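"""Per-cell gene-module enrichment scores with binned control genes.

The score of a gene set in a cell is the mean normalized expression of the
set's genes minus the mean expression of expression-matched control genes:
genes are ranked by their mean expression across cells and divided into
``n_bins`` equal-frequency bins; each member gene draws ``n_ctrl`` control
genes (seeded, without replacement, member excluded) from its own bin, and
the control mean is taken over the pooled multiset of drawn controls.  A
random gene set therefore scores near zero, and adding a constant to every
gene of a cell leaves the cell's score unchanged.

Cross-sample scoring: a program derived from sample A is scored on cells of
sample B through the genes shared with B's universe (missing genes are
dropped and the effective set size logged), using B's own expression-bin
structure.  Control draws are seeded per (sample, program) independently of
program ordering, so permuting the program list only permutes score columns.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .containers import NormalizedMatrix, pooled_cell_id
from .errors import ConfigurationError, ScoringError
from .programs import Program

logger = logging.getLogger(__name__)

__all__ = ["ScoringParams", "ScoreMatrix", "module_score", "score_all"]


@dataclass(frozen=True)
class ScoringParams:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 7

    def validate(self) -> None:
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if self.n_ctrl < 1:
            raise ConfigurationError("n_ctrl must be >= 1")


@dataclass
class ScoreMatrix:
    """Pooled cells x programs enrichment scores."""

    cell_ids: list[str]     # pooled ids, sample-prefixed
    program_ids: list[str]
    scores: np.ndarray = field(repr=False)  # (cells, programs)
    params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.cell_ids), len(self.program_ids)):
            raise ScoringError("score matrix shape mismatch")
        if np.isnan(self.scores).any():
            raise ScoringError("score matrix contains NaN")

    def column(self, program_id: str) -> np.ndarray:
        return self.scores[:, self.program_ids.index(program_id)]


def _expression_bins(values: np.ndarray, gene_ids: list[str], n_bins: int
                     ) -> np.ndarray:
    """Equal-frequency bin index per gene, on mean expression across cells.

    Ties in the mean are broken by gene id so binning is deterministic.
    """
    means = values.mean(axis=1)
    order = np.lexsort((np.asarray(gene_ids), means))
    bins = np.empty(len(gene_ids), dtype=np.int64)
    bins[order] = np.arange(len(gene_ids)) * n_bins // len(gene_ids)
    return bins


def _score_with_bins(values: np.ndarray, member_idx: np.ndarray,
                     bins: np.ndarray, bin_members: dict[int, np.ndarray],
                     n_ctrl: int, rng: np.random.Generator) -> np.ndarray:
    ctrl_parts = []
    for g in member_idx:
        pool = bin_members[int(bins[g])]
        pool = pool[pool != g]
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        ctrl_parts.append(rng.choice(pool, size=take, replace=False))
    member_mean = values[member_idx, :].mean(axis=0)
    if not ctrl_parts:
        logger.warning("no control genes available; returning member means")
        return member_mean
    ctrl_idx = np.concatenate(ctrl_parts)
    return member_mean - values[ctrl_idx, :].mean(axis=0)


def module_score(
    x: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 7,
) -> np.ndarray:
    """Score one gene set on one sample; returns a per-cell vector.

    Member genes absent from ``x`` are dropped with a warning; raises
    :class:`ScoringError` if none is present.
    """
    ScoringParams(n_bins, n_ctrl, seed).validate()
    pos = {g: i for i, g in enumerate(x.gene_ids)}
    seen = set()
    member_idx = []
    missing = []
    for g in gene_set:
        if g in seen:
            continue
        seen.add(g)
        if g in pos:
            member_idx.append(pos[g])
        else:
            missing.append(g)
    if not member_idx:
        raise ScoringError(
            f"gene set entirely absent from sample {x.sample_id}")
    if missing:
        logger.warning(
            "sample %s: %d/%d gene-set genes absent; scoring %d genes",
            x.sample_id, len(missing), len(seen), len(member_idx))
    bins = _expression_bins(x.values, x.gene_ids, n_bins)
    bin_members = {b: np.nonzero(bins == b)[0] for b in np.unique(bins)}
    rng = np.random.default_rng(seed)
    return _score_with_bins(x.values, np.asarray(member_idx), bins,
                            bin_members, n_ctrl, rng)


def _program_seed(base_seed: int, sample_id: str, program_id: str) -> int:
    """Stable per-(sample, program) seed, independent of iteration order."""
    ss = np.random.SeedSequence(
        entropy=(int(base_seed) & 0x7FFFFFFF,
                 zlib.crc32(sample_id.encode()),
                 zlib.crc32(program_id.encode())))
    return int(ss.generate_state(1)[0])


def score_all(
    matrices: list[NormalizedMatrix],
    programs: list[Program],
    params: ScoringParams = ScoringParams(),
) -> ScoreMatrix:
    """Score every program on every cell of every sample (pooled).

    Per-sample bin structures are computed once; each (sample, program)
    pair draws its controls from an independent seeded stream.
    """
    params.validate()
    program_ids = [p.program_id for p in programs]
    if len(set(program_ids)) != len(program_ids):
        raise ScoringError("duplicate program_ids")
    cell_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for x in matrices:
        pos = {g: i for i, g in enumerate(x.gene_ids)}
        bins = _expression_bins(x.values, x.gene_ids, params.n_bins)
        bin_members = {b: np.nonzero(bins == b)[0] for b in np.unique(bins)}
        block = np.empty((x.n_cells, len(programs)))
        for j, p in enumerate(programs):
            member_idx = np.asarray(
                [pos[g] for g in dict.fromkeys(p.genes) if g in pos])
            if member_idx.size == 0:
                raise ScoringError(
                    f"program {p.program_id} entirely absent from "
                    f"sample {x.sample_id}")
            if member_idx.size < len(p.genes):
                logger.info(
                    "program %s on sample %s: effective set size %d/%d",
                    p.program_id, x.sample_id, member_idx.size, len(p.genes))
            rng = np.random.default_rng(
                _program_seed(params.seed, x.sample_id, p.program_id))
            block[:, j] = _score_with_bins(
                x.values, member_idx, bins, bin_members, params.n_ctrl, rng)
        blocks.append(block)
        cell_ids.extend(pooled_cell_id(x.sample_id, c) for c in x.cell_ids)
    return ScoreMatrix(cell_ids, program_ids, np.vstack(blocks), params)
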