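"""Readers and writers for the standard formats the pipeline touches.

Matrix-Market triplets with ``features.tsv`` / ``barcodes.tsv`` sidecars
(10x-style, genes as rows, 1-based indices on disk), GMT gene-set
collections, CSV score/correlation matrices, and YAML sample manifests.
Gzipped ``matrix.mtx.gz`` is accepted transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .containers import CountMatrix
from .errors import FormatError

__all__ = [
    "SampleManifest", "ManifestEntry", "GeneSetCollection",
    "read_count_matrix", "write_count_matrix",
    "read_gene_sets", "write_gene_sets",
    "read_manifest", "write_manifest",
    "read_matrix_csv", "write_matrix_csv",
]


# ---------------------------------------------------------------------------
# Matrix-Market sample directories

def _find(path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        cand = path / name
        if cand.exists():
            return cand
    raise FormatError(f"missing {stem}[.gz] under {path}")


def _read_tsv(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_count_matrix(path: str | Path, sample_id: str | None = None
                      ) -> CountMatrix:
    """Read one sample directory (``matrix.mtx`` + sidecars) into memory.

    The feature table may have 1-3 columns; the first column is the gene
    identifier.  1-based Matrix-Market indices become 0-based positions.
    ``sample_id`` defaults to the directory name.
    """
    path = Path(path)
    mtx_path = _find(path, "matrix.mtx")
    features = _read_tsv(_find(path, "features.tsv"))
    barcodes = _read_tsv(_find(path, "barcodes.tsv"))

    mat = scipy.io.mmread(str(mtx_path))
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape[0] != len(features) or mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix header {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes")
    data = mat.toarray()
    if data.size and not np.all(data == np.round(data)):
        raise FormatError("matrix contains non-integer values")
    if data.size and data.min() < 0:
        raise FormatError("matrix contains negative values")
    return CountMatrix(
        sample_id=sample_id if sample_id is not None else path.name,
        gene_ids=features.iloc[:, 0].tolist(),
        cell_ids=barcodes.iloc[:, 0].tolist(),
        counts=data.astype(np.int64),
    )


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write a sample as ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = scipy.sparse.coo_matrix(m.counts)
    scipy.io.mmwrite(str(path / "matrix.mtx"), coo, field="integer")
    pd.DataFrame({
        0: m.gene_ids, 1: m.gene_ids, 2: ["Gene Expression"] * m.n_genes,
    }).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets

@dataclass
class GeneSetCollection:
    """Named, ordered gene lists with free-text descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def description(self, name: str) -> str:
        return self.descriptions.get(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GeneSetCollection)
                and self.sets == other.sets
                and all(self.description(n) == other.description(n)
                        for n in self.sets))


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a GMT file: one tab-separated line per set (name, description,
    genes...)."""
    lines = []
    for name, genes in collection.sets.items():
        fields = [name, collection.description(name), *genes]
        for f in fields:
            if "\t" in f:
                raise FormatError(f"tab character in GMT field {f!r}")
        lines.append("\t".join(fields))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields: {line!r}")
        name = fields[0]
        if name in sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        sets[name] = fields[2:]
        descriptions[name] = fields[1]
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# YAML sample manifests

@dataclass
class ManifestEntry:
    sample_id: str
    path: str
    group: str = ""


@dataclass
class SampleManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise FormatError("manifest sample_ids are not unique")

    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    payload = {"samples": [
        {"sample_id": e.sample_id, "path": e.path, "group": e.group}
        for e in manifest.entries
    ]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_manifest(path: str | Path, check_paths: bool = True
                  ) -> SampleManifest:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "samples" not in payload:
        raise FormatError("manifest must contain a top-level 'samples' list")
    entries = [ManifestEntry(str(d["sample_id"]), str(d["path"]),
                             str(d.get("group", "")))
               for d in payload["samples"]]
    manifest = SampleManifest(entries)
    if check_paths:
        base = Path(path).parent
        for e in manifest.entries:
            p = Path(e.path)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FormatError(f"manifest path not resolvable: {e.path}")
            e.path = str(p)
    return manifest


# ---------------------------------------------------------------------------
# CSV matrices (scores, correlations, factors)

def write_matrix_csv(df: pd.DataFrame, path: str | Path,
                     index_label: str) -> None:
    df.to_csv(path, index_label=index_label, float_format="%.10g")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
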