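"""Synthetic multi-sample single-cell cohort generator.

Emulates a cohort of tumor-organoid snRNA-seq samples whose cells express a
mixture of cohort-shared transcriptional programs (e.g. cell-cycle-like,
stress/translation-like, stem-like) and patient-private programs, on top of
per-gene baseline rates, with per-cell library-size variation and Poisson
counting noise.  The generator also emits the ground truth (planted gene
memberships and per-cell activities) needed to score recovery.

Generative model
----------------
For cell ``c`` of a sample and gene ``g``::

    rate_gc  = baseline_g * (1 + sum_p activity_cp * weight_gp)
    p_gc     = rate_gc / sum_g rate_gc          (renormalized per cell)
    count_gc ~ Poisson(libsize_c * p_gc)

``weight_gp = program_weight`` for member genes of programs in scope for the
cell's sample, else 0.  ``activity_cp ~ Gamma(activity_shape, activity_scale)``
for a random ``active_fraction`` subset of in-scope cells, else 0.

Shared programs model discrete transcriptional *states*: by default their
active-cell subsets within a sample are sampled mutually exclusively
(a cell occupies at most one shared state), which is what makes the states'
per-cell enrichment scores anti-correlated, as observed for real
meta-programs.  Private programs are patient-specific modules that overlay
any state, so their gates are sampled independently.  Set
``exclusive_states=False`` for fully independent Bernoulli gates.

Randomness
----------
All randomness flows from ``GeneratorConfig.seed`` through one
``numpy.random.Generator`` consumed in a fixed, documented order:

1. per-gene baseline rates (log-normal, shared by all samples);
2. one permutation of gene indices, from which disjoint program gene
   blocks are carved (shared programs first, then per-sample private ones);
3. per sample, in manifest order:
   a. per-cell library sizes (log-normal);
   b. if exclusive states apply: one permutation of cell indices
      (consecutive blocks become the shared programs' active sets),
      then per shared program its gamma activities;
      otherwise per shared program a uniform gate vector then gamma draws;
   c. per private program of the sample: a uniform gate vector, then
      gamma activities.

The same seed therefore yields bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import CountMatrix, pooled_cell_id
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the desk-scale cohort used throughout: 9 tumor-organoid
    samples, 4 cohort-shared programs plus 1 private program per sample, 50
    disjoint member genes per program.  ``active_fraction=0.25`` with 4 shared
    programs tiles each sample's cells into four mutually exclusive states;
    ``program_weight=8`` with mean activity 2 lets an active program claim a
    realistic 20-35%% of a cell's library (compare ribosomal/cell-cycle load
    in real cells).  Library sizes center on ~5,000 counts.
    """

    n_samples: int = 9
    cells_per_sample: int = 400
    n_genes: int = 2000
    n_shared_programs: int = 4
    n_private_programs_per_sample: int = 1
    genes_per_program: int = 50
    program_weight: float = 8.0
    active_fraction: float = 0.25
    activity_shape: float = 8.0
    activity_scale: float = 0.25
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.5
    libsize_log_mean: float = 8.5
    libsize_log_sd: float = 0.35
    seed: int = 1
    exclusive_states: bool = True

    def validate(self) -> None:
        for name in ("n_samples", "cells_per_sample", "n_genes",
                     "genes_per_program"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("n_shared_programs", "n_private_programs_per_sample"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.genes_per_program > self.n_genes:
            raise ConfigurationError(
                "genes_per_program exceeds n_genes "
                f"({self.genes_per_program} > {self.n_genes})")
        planted = (self.n_shared_programs
                   + self.n_samples * self.n_private_programs_per_sample)
        if planted * self.genes_per_program > self.n_genes:
            raise ConfigurationError(
                "disjoint program gene blocks do not fit: "
                f"{planted} programs x {self.genes_per_program} genes "
                f"> {self.n_genes} genes")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ConfigurationError("active_fraction must be in (0, 1]")
        for name in ("program_weight", "activity_shape", "activity_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("baseline_log_sd", "libsize_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Planted program structure emitted alongside a synthetic cohort.

    ``cell_activity`` is sparse: only strictly positive activities are
    stored, keyed by pooled cell id (``sample:barcode``).
    """

    program_genes: dict[str, list[str]]
    program_kind: dict[str, str]                 # "shared" | "private"
    program_sample_scope: dict[str, str]         # sample_id or "all"
    cell_activity: dict[str, dict[str, float]]   # program -> cell -> activity

    def shared_program_ids(self) -> list[str]:
        return [p for p, k in self.program_kind.items() if k == "shared"]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            program_genes={k: list(v) for k, v in d["program_genes"].items()},
            program_kind=dict(d["program_kind"]),
            program_sample_scope=dict(d["program_sample_scope"]),
            cell_activity={p: {c: float(a) for c, a in cells.items()}
                           for p, cells in d["cell_activity"].items()},
        )


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def generate_cohort(
    config: GeneratorConfig,
    return_rates: bool = False,
):
    """Generate one synthetic cohort.

    Returns ``(matrices, truth)``; with ``return_rates=True`` additionally
    returns the per-sample Poisson mean matrices (genes x cells) so tests can
    compare empirical moments against the exact pre-noise generative means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    gene_ids = [f"G{i:05d}" for i in range(G)]
    baseline = rng.lognormal(config.baseline_log_mean,
                             config.baseline_log_sd, size=G)

    # Carve pairwise-disjoint program gene blocks out of one permutation.
    perm = rng.permutation(G)
    program_genes: dict[str, list[str]] = {}
    program_kind: dict[str, str] = {}
    program_scope: dict[str, str] = {}
    program_gene_idx: dict[str, np.ndarray] = {}
    cursor = 0
    sample_ids = _sample_ids(config.n_samples)

    def take_block(pid: str, kind: str, scope: str) -> None:
        nonlocal cursor
        idx = perm[cursor:cursor + config.genes_per_program]
        cursor += config.genes_per_program
        program_gene_idx[pid] = idx
        program_genes[pid] = [gene_ids[i] for i in idx]
        program_kind[pid] = kind
        program_scope[pid] = scope

    shared_ids = [f"SP{j + 1}" for j in range(config.n_shared_programs)]
    for pid in shared_ids:
        take_block(pid, "shared", "all")
    private_ids: dict[str, list[str]] = {}
    for sid in sample_ids:
        private_ids[sid] = []
        for j in range(config.n_private_programs_per_sample):
            pid = f"{sid}_PP{j + 1}"
            private_ids[sid].append(pid)
            take_block(pid, "private", sid)

    exclusive = (
        config.exclusive_states
        and config.n_shared_programs > 0
        and config.n_shared_programs * config.active_fraction <= 1.0 + 1e-12
    )

    matrices: list[CountMatrix] = []
    rates: list[np.ndarray] = []
    cell_activity: dict[str, dict[str, float]] = {
        pid: {} for pid in program_genes
    }

    n_cells = config.cells_per_sample
    for sid in sample_ids:
        cell_ids = [f"c{j:04d}" for j in range(n_cells)]
        libsize = rng.lognormal(config.libsize_log_mean,
                                config.libsize_log_sd, size=n_cells)

        activities: dict[str, np.ndarray] = {}
        if exclusive:
            cell_perm = rng.permutation(n_cells)
            block = int(round(config.active_fraction * n_cells))
            for j, pid in enumerate(shared_ids):
                act = np.zeros(n_cells)
                members = cell_perm[j * block:(j + 1) * block]
                act[members] = rng.gamma(config.activity_shape,
                                         config.activity_scale,
                                         size=members.size)
                activities[pid] = act
        else:
            for pid in shared_ids:
                gate = rng.random(n_cells) < config.active_fraction
                act = np.zeros(n_cells)
                act[gate] = rng.gamma(config.activity_shape,
                                      config.activity_scale,
                                      size=int(gate.sum()))
                activities[pid] = act
        for pid in private_ids[sid]:
            gate = rng.random(n_cells) < config.active_fraction
            act = np.zeros(n_cells)
            act[gate] = rng.gamma(config.activity_shape,
                                  config.activity_scale,
                                  size=int(gate.sum()))
            activities[pid] = act

        effect = np.ones((G, n_cells))
        for pid, act in activities.items():
            gi = program_gene_idx[pid]
            effect[gi, :] += config.program_weight * act[None, :]
            nz = np.nonzero(act)[0]
            for j in nz:
                cell_activity[pid][pooled_cell_id(sid, cell_ids[j])] = \
                    float(act[j])

        rate = baseline[:, None] * effect
        p = rate / rate.sum(axis=0, keepdims=True)
        lam = p * libsize[None, :]
        counts = rng.poisson(lam).astype(np.int64)

        matrices.append(CountMatrix(sid, list(gene_ids), cell_ids, counts))
        if return_rates:
            rates.append(lam)

    truth = GroundTruth(program_genes, program_kind, program_scope,
                        cell_activity)
    if return_rates:
        return matrices, truth, rates
    return matrices, truth


def write_cohort(
    matrices: list[CountMatrix],
    truth: GroundTruth,
    config: GeneratorConfig,
    out_dir: str | Path,
    group: str = "tumor",
) -> Path:
    """Write a cohort as 10x-style sample directories plus sidecar metadata.

    Layout: one ``<out>/<sample_id>/`` directory per sample holding
    ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv``; a YAML
    ``manifest.yaml``; the ground truth as ``ground_truth.json``; and the
    generator configuration as ``generator_config.json``.
    Returns the manifest path.
    """
    from .io import SampleManifest, ManifestEntry, write_count_matrix, \
        write_manifest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in matrices:
        sample_dir = out_dir / m.sample_id
        write_count_matrix(m, sample_dir)
        entries.append(ManifestEntry(m.sample_id, str(sample_dir), group))
    manifest_path = out_dir / "manifest.yaml"
    write_manifest(SampleManifest(entries), manifest_path)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    (out_dir / "generator_config.json").write_text(
        json.dumps(asdict(config), indent=1, sort_keys=True))
    return manifest_path


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Load a ``ground_truth.json`` written by :func:`write_cohort`."""
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
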