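"""End-to-end orchestration: preprocess -> NMF -> programs -> scoring ->
meta-programs, with on-disk artifacts and run provenance.

Default stage seeds: generator 1, NMF ``42 + sample_index``, scoring 7.
Re-running with identical configuration and seeds reproduces byte-identical
artifacts; wall-clock information is confined to ``run.log``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import (AnalysisConfig, MetaProgram, ProgramCorrelation,
                        assign_cells, build_metaprograms, cluster_programs,
                        dendrogram_order, program_correlation)
from .containers import CountMatrix
from .io import (SampleManifest, read_count_matrix, write_gene_sets,
                 write_matrix_csv)
from .nmf import NMFFactorization, nmf_factorize
from .preprocess import filter_genes, normalize_cp10k_log1p
from .programs import Program, extract_programs, programs_to_gene_sets
from .scoring import ScoreMatrix, ScoringParams, score_all
from .simulate import GeneratorConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "discover_metaprograms", "run_pipeline",
           "simulate_cohort", "DEFAULT_NMF_SEED", "DEFAULT_SCORING_SEED"]

DEFAULT_NMF_SEED = 42
DEFAULT_SCORING_SEED = 7


@dataclass
class PipelineResult:
    factorizations: list[NMFFactorization]
    programs: list[Program]
    score_matrix: ScoreMatrix
    correlation: ProgramCorrelation
    partition: list[list[str]]
    metaprograms: list[MetaProgram]
    unclustered: list[str]
    labels: pd.Series | None
    composition: pd.DataFrame | None


def discover_metaprograms(
    counts: list[CountMatrix],
    config: AnalysisConfig = AnalysisConfig(),
    nmf_seed: int = DEFAULT_NMF_SEED,
    scoring_seed: int = DEFAULT_SCORING_SEED,
) -> PipelineResult:
    """Run the full in-memory analysis over a list of sample count matrices."""
    config.validate()
    normalized = []
    factorizations = []
    programs: list[Program] = []
    for i, m in enumerate(counts):
        t0 = time.perf_counter()
        filtered = filter_genes(m, min_cells=config.min_cells)
        x = normalize_cp10k_log1p(filtered)
        normalized.append(x)
        f = nmf_factorize(x, k=config.k, seed=nmf_seed + i,
                          max_iter=config.nmf_max_iter, tol=config.nmf_tol,
                          restarts=config.restarts)
        factorizations.append(f)
        programs.extend(extract_programs(f, n_top=config.n_top))
        logger.info(
            "sample %s: %d genes x %d cells, NMF k=%d %d iter "
            "(err %.4g, %.1fs)",
            m.sample_id, x.n_genes, x.n_cells, config.k, f.n_iter,
            f.final_error, time.perf_counter() - t0)

    t0 = time.perf_counter()
    scores = score_all(normalized, programs,
                       ScoringParams(config.n_bins, config.n_ctrl,
                                     scoring_seed))
    logger.info("scored %d programs on %d pooled cells (%.1fs)",
                len(programs), len(scores.cell_ids),
                time.perf_counter() - t0)

    corr = program_correlation(scores)
    partition = cluster_programs(corr, config)
    mps, unclustered = build_metaprograms(partition, programs, config,
                                          correlation=corr)
    logger.info("%d clusters at cut %.2f -> %d meta-programs "
                "(%d programs unclustered)", len(partition),
                config.cut_height, len(mps), len(unclustered))
    labels = composition = None
    if mps:
        labels, composition = assign_cells(scores, mps)
    return PipelineResult(factorizations, programs, scores, corr, partition,
                          mps, unclustered, labels, composition)


# ---------------------------------------------------------------------------
# on-disk runs

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_factorization(f: NMFFactorization, out: Path) -> list[Path]:
    w_path = out / f"{f.sample_id}_W.csv"
    h_path = out / f"{f.sample_id}_H.csv"
    prov_path = out / f"{f.sample_id}_provenance.json"
    cols = [f"F{j + 1:02d}" for j in range(f.k)]
    write_matrix_csv(pd.DataFrame(f.W, index=f.gene_ids, columns=cols),
                     w_path, index_label="gene_id")
    write_matrix_csv(pd.DataFrame(f.H, index=cols, columns=f.cell_ids),
                     h_path, index_label="factor")
    prov_path.write_text(json.dumps({
        "sample_id": f.sample_id, "k": f.k, "seed": f.seed,
        "n_iter": f.n_iter, "converged": f.converged,
        "final_objective": f.final_error,
    }, indent=1, sort_keys=True))
    return [w_path, h_path, prov_path]


def run_pipeline(
    manifest: SampleManifest,
    config: AnalysisConfig,
    out_dir: str | Path,
    nmf_seed: int = DEFAULT_NMF_SEED,
    scoring_seed: int = DEFAULT_SCORING_SEED,
) -> PipelineResult:
    """Load every manifest sample, run the analysis, write all artifacts.

    Artifacts: per-sample factor CSVs, ``programs.gmt``, ``scores.csv``,
    ``correlation.csv`` (dendrogram leaf order), ``metaprograms.json``,
    ``metaprograms.gmt``, ``cell_labels.csv``, ``mp_composition.csv`` and a
    deterministic ``run_provenance.json`` with SHA-256 digests of every
    artifact.  On stage failure, partial outputs are kept under a
    ``failed`` marker file naming the stage and sample.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("metaprog")
    root.addHandler(log_handler)
    stage, sample = "load", ""
    try:
        counts = []
        for e in manifest.entries:
            sample = e.sample_id
            counts.append(read_count_matrix(e.path, sample_id=e.sample_id))
        stage, sample = "analysis", ""
        result = discover_metaprograms(counts, config, nmf_seed, scoring_seed)

        stage = "write"
        artifacts: list[Path] = []
        factors_dir = out / "factors"
        factors_dir.mkdir(exist_ok=True)
        for f in result.factorizations:
            artifacts.extend(_write_factorization(f, factors_dir))

        programs_path = out / "programs.gmt"
        write_gene_sets(programs_to_gene_sets(result.programs), programs_path)
        artifacts.append(programs_path)

        scores_path = out / "scores.csv"
        write_matrix_csv(
            pd.DataFrame(result.score_matrix.scores,
                         index=result.score_matrix.cell_ids,
                         columns=result.score_matrix.program_ids),
            scores_path, index_label="cell_id")
        artifacts.append(scores_path)

        corr_path = out / "correlation.csv"
        order = dendrogram_order(result.correlation, config)
        write_matrix_csv(result.correlation.to_frame(order), corr_path,
                         index_label="program_id")
        artifacts.append(corr_path)

        mp_path = out / "metaprograms.json"
        mp_path.write_text(json.dumps({
            "metaprograms": [{
                "mp_id": mp.mp_id,
                "member_program_ids": mp.member_program_ids,
                "consensus_genes": mp.consensus_genes,
                "gene_frequency": mp.gene_frequency,
                "coherence": mp.coherence,
                "annotation": mp.annotation,
            } for mp in result.metaprograms],
            "unclustered_programs": result.unclustered,
        }, indent=1, sort_keys=True))
        artifacts.append(mp_path)
        if result.metaprograms:
            from .io import GeneSetCollection
            mp_gmt = out / "metaprograms.gmt"
            write_gene_sets(GeneSetCollection(
                sets={mp.mp_id: mp.consensus_genes
                      for mp in result.metaprograms},
                descriptions={mp.mp_id:
                              f"{mp.n_members} member programs"
                              for mp in result.metaprograms}), mp_gmt)
            artifacts.append(mp_gmt)
            labels_path = out / "cell_labels.csv"
            result.labels.to_frame().to_csv(labels_path)
            artifacts.append(labels_path)
            comp_path = out / "mp_composition.csv"
            result.composition.to_csv(comp_path, float_format="%.10g")
            artifacts.append(comp_path)

        (out / "run_provenance.json").write_text(json.dumps({
            "version": __version__,
            "analysis_config": dataclasses.asdict(config),
            "seeds": {"nmf_seed": nmf_seed, "scoring_seed": scoring_seed},
            "samples": manifest.sample_ids(),
            "artifact_digests": {str(p.relative_to(out)): _sha256(p)
                                 for p in artifacts},
        }, indent=1, sort_keys=True))
        return result
    except Exception as exc:
        (out / "failed").write_text(
            f"stage={stage} sample={sample} error={exc!r}\n")
        logger.error("pipeline failed at stage %s (sample %s): %r",
                     stage, sample, exc)
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def simulate_cohort(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic cohort and write it to disk; returns the
    manifest path."""
    matrices, truth = generate_cohort(config)
    return write_cohort(matrices, truth, config, out_dir)
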