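"""Meta-program construction: correlate programs, cut the dendrogram,
build consensus gene sets, assign cells, and score recovery.

A meta-program (MP) is a cluster of gene programs — typically recurring
across samples — whose per-cell enrichment scores are mutually correlated.
Programs are clustered by agglomerative clustering on the distance
``d = 1 - r`` (Pearson correlation of score columns over all pooled cells)
and the tree is cut at a fixed height; clusters passing recurrence and
coherence filters are summarized by the genes occurring most frequently
among their member programs' top-N lists.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, ContractError
from .programs import Program
from .scoring import ScoreMatrix
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig", "ProgramCorrelation", "MetaProgram", "RecoveryReport",
    "program_correlation", "cluster_programs", "linkage_matrix",
    "dendrogram_order", "build_metaprograms", "assign_cells",
    "recovery_metrics",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end analysis parameters.

    ``cut_height`` acts on the distance ``1 - r`` (range 0-2), so 1.3
    separates clusters only where scores are anti-correlated on average —
    the hallmark of mutually exclusive transcriptional states.
    ``min_programs`` / ``min_samples`` demand recurrence across the cohort;
    ``min_coherence`` (mean pairwise within-cluster correlation) enforces
    the defining property of a meta-program and discards the loose cluster
    of residual factors that any over-complete per-sample factorization
    produces.  Set it to 0 to disable.
    """

    k: int = 15
    n_top: int = 50
    cut_height: float = 1.3
    n_consensus: int = 50
    linkage: str = "complete"
    distance: str = "one_minus_r"
    min_programs: int = 3
    min_samples: int = 2
    min_coherence: float = 0.3
    min_cells: int = 3
    n_bins: int = 24
    n_ctrl: int = 100
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-4
    restarts: int = 1

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.n_top < 1:
            raise ConfigurationError("n_top must be >= 1")
        if self.cut_height <= 0:
            raise ConfigurationError("cut_height must be > 0")
        if self.n_consensus < 1:
            raise ConfigurationError("n_consensus must be >= 1")
        if self.linkage not in ("average", "complete", "single", "ward"):
            raise ConfigurationError(f"unknown linkage {self.linkage!r}")
        if self.distance != "one_minus_r":
            raise ConfigurationError(f"unknown distance {self.distance!r}")
        if self.min_programs < 1:
            raise ConfigurationError("min_programs must be >= 1")
        if self.min_samples < 1:
            raise ConfigurationError("min_samples must be >= 1")
        if not 0.0 <= self.min_coherence <= 1.0:
            raise ConfigurationError("min_coherence must be in [0, 1]")


@dataclass
class ProgramCorrelation:
    """Symmetric Pearson correlation of program score columns."""

    program_ids: list[str]
    r: np.ndarray = field(repr=False)  # (programs, programs)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        n = len(self.program_ids)
        if self.r.shape != (n, n):
            raise ContractError("correlation matrix shape mismatch")

    def to_frame(self, order: np.ndarray | None = None) -> pd.DataFrame:
        ids = self.program_ids
        r = self.r
        if order is not None:
            ids = [ids[i] for i in order]
            r = r[np.ix_(order, order)]
        return pd.DataFrame(r, index=ids, columns=ids)


@dataclass
class MetaProgram:
    """A cluster of correlated programs with a consensus gene set."""

    mp_id: str
    member_program_ids: list[str]
    consensus_genes: list[str]
    gene_frequency: dict[str, int]
    coherence: float = float("nan")  # mean pairwise member correlation
    annotation: str = ""

    @property
    def n_members(self) -> int:
        return len(self.member_program_ids)


def program_correlation(s: ScoreMatrix) -> ProgramCorrelation:
    """Pearson correlation between score columns over all pooled cells.

    Constant columns are assigned correlation 0 with everything (unit
    diagonal retained) and logged.
    """
    if len(s.cell_ids) < 2:
        raise ContractError("correlation requires at least 2 cells")
    X = s.scores
    constant = (X == X[0, :]).all(axis=0)
    if constant.any():
        logger.warning("%d constant score column(s): %s",
                       int(constant.sum()),
                       [s.program_ids[i] for i in np.nonzero(constant)[0]])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ProgramCorrelation(list(s.program_ids), r)


def linkage_matrix(c: ProgramCorrelation, config: AnalysisConfig
                   ) -> np.ndarray:
    """Agglomerative linkage on ``d = 1 - r``."""
    config.validate()
    d = 1.0 - c.r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    condensed = squareform(d, checks=False)
    return sch.linkage(condensed, method=config.linkage)


def dendrogram_order(c: ProgramCorrelation, config: AnalysisConfig
                     ) -> np.ndarray:
    """Leaf order of the program dendrogram (for heatmap-style output)."""
    if len(c.program_ids) < 2:
        return np.arange(len(c.program_ids))
    return sch.leaves_list(linkage_matrix(c, config))


def cluster_programs(c: ProgramCorrelation, config: AnalysisConfig
                     ) -> list[list[str]]:
    """Cut the dendrogram at ``config.cut_height`` into flat clusters.

    Returns clusters of program_ids, ordered by each cluster's smallest
    program index (members keep their original order), so the partition is
    invariant to input permutation up to relabeling.
    """
    n = len(c.program_ids)
    if n == 0:
        return []
    if n == 1:
        return [[c.program_ids[0]]]
    Z = linkage_matrix(c, config)
    labels = sch.fcluster(Z, t=config.cut_height, criterion="distance")
    by_label: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(i)
    clusters = sorted(by_label.values(), key=lambda idx: idx[0])
    return [[c.program_ids[i] for i in idx] for idx in clusters]


def _consensus_genes(members: list[Program], n_consensus: int
                     ) -> tuple[list[str], dict[str, int]]:
    freq = Counter()
    rank_sum: Counter = Counter()
    for p in members:
        for rank, g in enumerate(p.genes, start=1):
            freq[g] += 1
            rank_sum[g] += rank
    # most frequent first; ties by better (lower) mean within-program rank,
    # then lexicographic gene id
    ordered = sorted(freq,
                     key=lambda g: (-freq[g], rank_sum[g] / freq[g], g))
    return ordered[:n_consensus], dict(freq)


def _cluster_coherence(c: ProgramCorrelation | None,
                       member_idx: list[int]) -> float:
    if c is None or len(member_idx) < 2:
        return 1.0
    sub = c.r[np.ix_(member_idx, member_idx)]
    iu = np.triu_indices(len(member_idx), k=1)
    return float(sub[iu].mean())


def build_metaprograms(
    partition: list[list[str]],
    programs: list[Program],
    config: AnalysisConfig,
    correlation: ProgramCorrelation | None = None,
) -> tuple[list[MetaProgram], list[str]]:
    """Promote qualifying clusters to MetaPrograms.

    A cluster qualifies when it has >= ``min_programs`` members spanning
    >= ``min_samples`` distinct samples and (if a correlation matrix is
    given) mean pairwise member correlation >= ``min_coherence``.  The
    consensus gene set holds the ``n_consensus`` genes occurring most
    frequently among member programs' top-N lists.  Returns the MP list
    (largest cluster first, mp_ids MP1..MPn) and the ids of programs left
    unclustered.  An empty MP list is a warning, not an error.
    """
    config.validate()
    by_id = {p.program_id: p for p in programs}
    covered = set(pid for cl in partition for pid in cl)
    missing = [p.program_id for p in programs if p.program_id not in covered]
    if missing:
        raise ContractError(f"partition does not cover programs: {missing}")
    if correlation is not None:
        cpos = {pid: i for i, pid in enumerate(correlation.program_ids)}

    kept: list[tuple[list[str], float]] = []
    unclustered: list[str] = []
    for cl in partition:
        members = [by_id[pid] for pid in cl]
        samples = {p.sample_id for p in members}
        coh = (_cluster_coherence(correlation, [cpos[pid] for pid in cl])
               if correlation is not None else 1.0)
        if (len(members) >= config.min_programs
                and len(samples) >= config.min_samples
                and coh >= config.min_coherence):
            kept.append((cl, coh))
        else:
            unclustered.extend(cl)

    prog_order = {p.program_id: i for i, p in enumerate(programs)}
    kept.sort(key=lambda item: (-len(item[0]),
                                min(prog_order[pid] for pid in item[0])))
    mps = []
    for i, (cl, coh) in enumerate(kept, start=1):
        members = [by_id[pid] for pid in cl]
        genes, freq = _consensus_genes(members, config.n_consensus)
        mps.append(MetaProgram(
            mp_id=f"MP{i}",
            member_program_ids=list(cl),
            consensus_genes=genes,
            gene_frequency=freq,
            coherence=coh,
        ))
    if not mps:
        logger.warning("no cluster passed the meta-program filters")
    return mps, unclustered


def assign_cells(
    s: ScoreMatrix,
    mps: list[MetaProgram],
) -> tuple[pd.Series, pd.DataFrame]:
    """Label every pooled cell with its top meta-program.

    The MP score of a cell is the mean of its member-program score columns;
    the label is the argmax, ties going to the lower mp_id.  Also returns
    the per-sample MP composition (fractions summing to 1 per sample).
    """
    if not mps:
        raise ContractError("assign_cells requires at least one MetaProgram")
    pos = {pid: j for j, pid in enumerate(s.program_ids)}
    mp_scores = np.column_stack([
        s.scores[:, [pos[pid] for pid in mp.member_program_ids]].mean(axis=1)
        for mp in mps
    ])
    labels = pd.Series(
        [mps[j].mp_id for j in np.argmax(mp_scores, axis=1)],
        index=pd.Index(s.cell_ids, name="cell_id"), name="mp_id")
    samples = labels.index.str.split(":").str[0]
    composition = (
        pd.crosstab(samples, labels, normalize="index")
        .reindex(columns=[mp.mp_id for mp in mps], fill_value=0.0)
        .rename_axis(index="sample_id", columns=None)
    )
    return labels, composition


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


@dataclass
class RecoveryReport:
    """How well recovered MPs match the planted shared programs."""

    n_metaprograms: int
    n_planted_shared: int
    matches: list[dict]          # {planted, mp_id, jaccard}
    mean_jaccard: float          # mean over planted programs (unmatched = 0)
    label_agreement: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_metaprograms": self.n_metaprograms,
            "n_planted_shared": self.n_planted_shared,
            "matches": self.matches,
            "mean_jaccard": self.mean_jaccard,
            "label_agreement": self.label_agreement,
        }


def recovery_metrics(
    truth: GroundTruth,
    mps: list[MetaProgram],
    labels: pd.Series | None = None,
) -> RecoveryReport:
    """Match planted shared programs to recovered MPs and score the match.

    Uses an optimal one-to-one (Hungarian) assignment on the Jaccard index
    between planted gene sets and MP consensus gene sets.  If per-cell
    ``labels`` are given, also reports the fraction of truly active cells
    (dominant planted shared program by activity) whose label is the MP
    matched to that program.
    """
    planted = truth.shared_program_ids()
    planted_sets = [set(truth.program_genes[p]) for p in planted]
    mp_sets = [set(mp.consensus_genes) for mp in mps]
    matches: list[dict] = []
    mp_of_planted: dict[str, str] = {}
    if planted and mps:
        J = np.array([[_jaccard(ps, ms) for ms in mp_sets]
                      for ps in planted_sets])
        rows, cols = linear_sum_assignment(-J)
        for i, j in zip(rows, cols):
            matches.append({"planted": planted[i], "mp_id": mps[j].mp_id,
                            "jaccard": float(J[i, j])})
            mp_of_planted[planted[i]] = mps[j].mp_id
    mean_j = (sum(m["jaccard"] for m in matches) / len(planted)
              if planted else 0.0)

    agreement = None
    if labels is not None and planted:
        hits = total = 0
        best: dict[str, tuple[float, str]] = {}
        for pid in planted:
            for cell, act in truth.cell_activity[pid].items():
                cur = best.get(cell)
                if cur is None or act > cur[0]:
                    best[cell] = (act, pid)
        for cell, (_, pid) in best.items():
            if cell not in labels.index or pid not in mp_of_planted:
                continue
            total += 1
            hits += labels.loc[cell] == mp_of_planted[pid]
        agreement = hits / total if total else None

    return RecoveryReport(
        n_metaprograms=len(mps),
        n_planted_shared=len(planted),
        matches=matches,
        mean_jaccard=mean_j,
        label_agreement=agreement,
    )
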