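"""Correlation, dendrogram cut, consensus genes, assignment, recovery."""

import numpy as np
import pandas as pd
import pytest

from metaprog import (AnalysisConfig, MetaProgram, Program, ScoreMatrix,
                      assign_cells, build_metaprograms, cluster_programs,
                      program_correlation, recovery_metrics)
from metaprog.consensus import ProgramCorrelation
from metaprog.errors import ContractError
from metaprog.simulate import GroundTruth


def _score_matrix(X, program_ids=None):
    n_cells, n_prog = X.shape
    program_ids = program_ids or [f"P{j}" for j in range(n_prog)]
    return ScoreMatrix([f"S:{i}" for i in range(n_cells)], program_ids,
                       np.asarray(X, dtype=float))


def _prog(pid, genes, sample=None):
    return Program(pid, sample or pid.split("_")[0], 0, list(genes),
                   list(np.linspace(1, 0.5, len(genes))))


# ---------------------------------------------------------------------------
# correlation

def test_column_with_itself_and_negation():
    rng = np.random.default_rng(0)
    v = rng.normal(size=50)
    c = program_correlation(_score_matrix(np.column_stack([v, v, -v])))
    assert c.r[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert c.r[0, 2] == pytest.approx(-1.0, abs=1e-12)
    np.testing.assert_allclose(np.diag(c.r), 1.0)


def test_matches_direct_covariance_formula():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 5))
    c = program_correlation(_score_matrix(X))
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    expected = ((X - mu).T @ (X - mu) / X.shape[0]) / np.outer(sd, sd)
    np.testing.assert_allclose(c.r, expected, atol=1e-12)
    np.testing.assert_allclose(c.r, c.r.T, atol=0)


def test_constant_column_gets_zero_correlation(caplog):
    import logging
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 3))
    X[:, 1] = 4.2
    with caplog.at_level(logging.WARNING):
        c = program_correlation(_score_matrix(X))
    assert c.r[1, 0] == 0.0 and c.r[2, 1] == 0.0 and c.r[1, 1] == 1.0


def test_single_cell_rejected():
    with pytest.raises(ContractError):
        program_correlation(_score_matrix(np.ones((1, 3))))


# ---------------------------------------------------------------------------
# dendrogram cut

def _block_correlation():
    """Two perfect 2-program blocks: r=1 within, r=0 between."""
    r = np.eye(4)
    r[0, 1] = r[1, 0] = 1.0
    r[2, 3] = r[3, 2] = 1.0
    return ProgramCorrelation(["a", "b", "c", "d"], r)


def test_uncorrelated_blocks_merge_at_permissive_cut():
    # within-block distance 0, between-block distance 1.0 < 1.3
    parts = cluster_programs(_block_correlation(),
                             AnalysisConfig(cut_height=1.3))
    assert parts == [["a", "b", "c", "d"]]


def test_uncorrelated_blocks_split_at_strict_cut():
    parts = cluster_programs(_block_correlation(),
                             AnalysisConfig(cut_height=0.5))
    assert parts == [["a", "b"], ["c", "d"]]


def test_identity_correlation_gives_singletons():
    c = ProgramCorrelation(["x", "y", "z"], np.eye(3))
    parts = cluster_programs(c, AnalysisConfig(cut_height=0.5))
    assert parts == [["x"], ["y"], ["z"]]


def test_partition_invariant_under_permutation():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(60, 6))
    base[:, 1] = base[:, 0] + 0.1 * rng.normal(size=60)
    base[:, 4] = -base[:, 0] + 0.1 * rng.normal(size=60)
    s = _score_matrix(base)
    cfg = AnalysisConfig(cut_height=0.8)
    parts = cluster_programs(program_correlation(s), cfg)
    perm = [3, 0, 5, 1, 4, 2]
    s2 = _score_matrix(base[:, perm], [s.program_ids[j] for j in perm])
    parts2 = cluster_programs(program_correlation(s2), cfg)
    assert {frozenset(p) for p in parts} == {frozenset(p) for p in parts2}


# ---------------------------------------------------------------------------
# consensus construction

def test_identical_member_lists_give_that_list():
    genes = [f"g{i}" for i in range(10)]
    members = [_prog("S01_F01", genes, "S01"), _prog("S02_F01", genes, "S02"),
               _prog("S03_F01", genes, "S03")]
    mps, rest = build_metaprograms([[p.program_id for p in members]],
                                   members,
                                   AnalysisConfig(n_consensus=10))
    assert rest == []
    assert mps[0].consensus_genes == genes
    assert all(v == 3 for v in mps[0].gene_frequency.values())


def test_disjoint_members_interleave_by_rank():
    """Two disjoint 50-gene lists, consensus of 50: every frequency is 1 and
    the tie-break keeps the better-ranked half of each list."""
    a = [f"a{i:02d}" for i in range(50)]
    b = [f"b{i:02d}" for i in range(50)]
    members = [_prog("S01_F01", a, "S01"), _prog("S02_F01", b, "S02")]
    cfg = AnalysisConfig(n_consensus=50, min_programs=2)
    mps, _ = build_metaprograms([[p.program_id for p in members]], members,
                                cfg)
    consensus = mps[0].consensus_genes
    assert len(consensus) == 50
    assert set(consensus) == set(a[:25]) | set(b[:25])
    assert all(mps[0].gene_frequency[g] == 1 for g in consensus)


def test_consensus_matches_brute_force_frequency_sort():
    rng = np.random.default_rng(4)
    pool = [f"g{i:02d}" for i in range(30)]
    members = []
    for i in range(4):
        genes = list(rng.permutation(pool)[:12])
        members.append(_prog(f"S{i:02d}_F01", genes, f"S{i:02d}"))
    cfg = AnalysisConfig(n_consensus=8, min_programs=2)
    mps, _ = build_metaprograms([[p.program_id for p in members]], members,
                                cfg)
    freq: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for p in members:
        for r, g in enumerate(p.genes, start=1):
            freq[g] = freq.get(g, 0) + 1
            ranks.setdefault(g, []).append(r)
    expected = sorted(freq, key=lambda g: (-freq[g],
                                           np.mean(ranks[g]), g))[:8]
    assert mps[0].consensus_genes == expected
    union = set().union(*(p.genes for p in members))
    assert set(mps[0].consensus_genes) <= union


def test_consensus_length_is_min_of_budget_and_union():
    members = [_prog("S01_F01", ["x", "y"], "S01"),
               _prog("S02_F01", ["y", "z"], "S02")]
    mps, _ = build_metaprograms([[p.program_id for p in members]], members,
                                AnalysisConfig(n_consensus=50,
                                               min_programs=2))
    assert len(mps[0].consensus_genes) == 3


def test_single_sample_cluster_removed_by_min_samples():
    members = [_prog("S01_F01", ["a"], "S01"), _prog("S01_F02", ["b"], "S01"),
               _prog("S01_F03", ["c"], "S01")]
    mps, rest = build_metaprograms(
        [[p.program_id for p in members]], members,
        AnalysisConfig(min_programs=3, min_samples=2))
    assert mps == [] and len(rest) == 3


def test_incoherent_cluster_removed_by_coherence_filter():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(80, 3))  # mutually uncorrelated score columns
    members = [_prog("S01_F01", ["a"], "S01"), _prog("S02_F01", ["b"], "S02"),
               _prog("S03_F01", ["c"], "S03")]
    s = _score_matrix(X, [p.program_id for p in members])
    corr = program_correlation(s)
    cfg = AnalysisConfig(min_programs=3, min_samples=2, min_coherence=0.3)
    mps, rest = build_metaprograms([[p.program_id for p in members]],
                                   members, cfg, correlation=corr)
    assert mps == [] and len(rest) == 3
    # without a correlation matrix the filter cannot apply
    mps2, _ = build_metaprograms([[p.program_id for p in members]],
                                 members, cfg)
    assert len(mps2) == 1


def test_partition_must_cover_all_programs():
    members = [_prog("S01_F01", ["a"], "S01"), _prog("S02_F01", ["b"], "S02")]
    with pytest.raises(ContractError, match="S02_F01"):
        build_metaprograms([["S01_F01"]], members, AnalysisConfig())


# ---------------------------------------------------------------------------
# cell assignment

def _mp(mp_id, member_ids):
    return MetaProgram(mp_id, member_ids, ["g"], {"g": 1})


def test_single_metaprogram_labels_everything():
    s = _score_matrix(np.random.default_rng(0).normal(size=(6, 2)),
                      ["A_F01", "A_F02"])
    labels, comp = assign_cells(s, [_mp("MP1", ["A_F01", "A_F02"])])
    assert (labels == "MP1").all()
    np.testing.assert_allclose(comp.to_numpy().sum(axis=1), 1.0)


def test_exact_tie_goes_to_lower_mp_id():
    X = np.array([[1.0, -1.0, 0.0, 0.0]])
    s = _score_matrix(X, ["a", "b", "c", "d"])
    labels, _ = assign_cells(s, [_mp("MP1", ["a", "b"]),
                                 _mp("MP2", ["c", "d"])])
    assert labels.iloc[0] == "MP1"


def test_composition_is_per_sample_fraction():
    X = np.array([[2.0, 0.0], [2.0, 0.0], [0.0, 2.0], [0.0, 2.0]])
    s = ScoreMatrix(["A:1", "A:2", "B:1", "B:2"], ["p", "q"], X)
    _, comp = assign_cells(s, [_mp("MP1", ["p"]), _mp("MP2", ["q"])])
    assert comp.loc["A", "MP1"] == 1.0 and comp.loc["B", "MP2"] == 1.0


def test_empty_mp_list_rejected():
    s = _score_matrix(np.ones((2, 1)))
    with pytest.raises(ContractError):
        assign_cells(s, [])


# ---------------------------------------------------------------------------
# recovery metrics

def _truth(sets):
    return GroundTruth(
        program_genes={k: list(v) for k, v in sets.items()},
        program_kind={k: "shared" for k in sets},
        program_sample_scope={k: "all" for k in sets},
        cell_activity={k: {} for k in sets})


def test_identical_sets_score_perfect_jaccard():
    truth = _truth({"SP1": ["a", "b"], "SP2": ["c", "d"]})
    mps = [MetaProgram("MP1", ["x"], ["c", "d"], {}),
           MetaProgram("MP2", ["y"], ["a", "b"], {})]
    rep = recovery_metrics(truth, mps)
    assert rep.mean_jaccard == 1.0
    assert {(m["planted"], m["mp_id"]) for m in rep.matches} == \
        {("SP1", "MP2"), ("SP2", "MP1")}


def test_disjoint_sets_score_zero():
    truth = _truth({"SP1": ["a", "b"]})
    rep = recovery_metrics(truth, [MetaProgram("MP1", ["x"], ["z"], {})])
    assert rep.mean_jaccard == 0.0


def test_jaccard_matches_set_arithmetic():
    rng = np.random.default_rng(6)
    pool = [f"g{i}" for i in range(40)]
    truth = _truth({f"SP{i}": list(rng.permutation(pool)[:10])
                    for i in range(3)})
    mps = [MetaProgram(f"MP{i}", ["m"],
                       list(rng.permutation(pool)[:10]), {})
           for i in range(3)]
    rep = recovery_metrics(truth, mps)
    by_pair = {(m["planted"], m["mp_id"]): m["jaccard"]
               for m in rep.matches}
    for (sp, mp_id), j in by_pair.items():
        a = set(truth.program_genes[sp])
        b = set(next(m.consensus_genes for m in mps if m.mp_id == mp_id))
        assert j == pytest.approx(len(a & b) / len(a | b), abs=1e-12)


def test_label_agreement_counts_matched_cells():
    truth = GroundTruth(
        program_genes={"SP1": ["a"], "SP2": ["b"]},
        program_kind={"SP1": "shared", "SP2": "shared"},
        program_sample_scope={"SP1": "all", "SP2": "all"},
        cell_activity={"SP1": {"S:1": 2.0, "S:2": 1.0},
                       "SP2": {"S:3": 1.0}})
    mps = [MetaProgram("MP1", ["x"], ["a"], {}),
           MetaProgram("MP2", ["y"], ["b"], {})]
    labels = pd.Series(["MP1", "MP2", "MP2"],
                       index=pd.Index(["S:1", "S:2", "S:3"], name="cell_id"))
    rep = recovery_metrics(truth, mps, labels=labels)
    assert rep.label_agreement == pytest.approx(2 / 3)
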