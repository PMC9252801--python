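import numpy as np
import pytest
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from protloc.homology import (
    IdentityEdge,
    build_identity_graph,
    check_test_independence,
    global_identity,
    partition_by_groups,
    partition_by_homology,
)
from protloc.seq_io import LabeledSequence, LocalizationLabelSet, ProteinRecord
from protloc.synthetic import desk_config, generate
from protloc.vocab import AMINO_ACIDS

_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()


def gotoh_optimal_score(a: str, b: str, open_=-11, ext=-1) -> float:
    """Independent quadratic affine-gap global-alignment DP (Gotoh)."""
    la, lb = len(a), len(b)
    NEG = -1e9
    alph = _BLOSUM62.get_alphabet1()
    mat = _BLOSUM62.score_matrix()
    ca = [alph.encode(x) for x in a]
    cb = [alph.encode(x) for x in b]
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)
    Iy = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = open_ + (i - 1) * ext
    for j in range(1, lb + 1):
        Iy[0, j] = open_ + (j - 1) * ext
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = mat[ca[i - 1], cb[j - 1]] + max(
                M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]
            )
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + ext,
                           Iy[i - 1, j] + open_)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + ext,
                           Ix[i, j - 1] + open_)
    return max(M[la, lb], Ix[la, lb], Iy[la, lb])


def test_identity_of_identical_sequences_is_one():
    assert global_identity("MKVLW", "MKVLW") == 1.0


def test_identity_of_dissimilar_sequences_is_zero():
    assert global_identity("AAAA", "CCCC") == 0.0


def test_single_substitution_identity():
    # unambiguous ungapped optimum: 59 matches over 60 columns
    a = "MKVLWAYRQP" * 6
    b = a[:30] + "G" + a[31:]
    assert global_identity(a, b) == pytest.approx(59 / 60)


def test_identity_is_symmetric(rng):
    letters = list(AMINO_ACIDS)
    for _ in range(10):
        a = "".join(rng.choice(letters, size=int(rng.integers(40, 80))))
        b = "".join(rng.choice(letters, size=int(rng.integers(40, 80))))
        assert global_identity(a, b) == global_identity(b, a)


def test_alignment_score_matches_independent_gotoh_dp(rng):
    """The library's alignment attains exactly the DP-optimal global score."""
    letters = list(AMINO_ACIDS)
    for _ in range(6):
        a = "".join(rng.choice(letters, size=60))
        b = "".join(rng.choice(letters, size=int(rng.integers(40, 80))))
        aln = align_optimal(
            ProteinSequence(a), ProteinSequence(b), _BLOSUM62,
            gap_penalty=(-11, -1), terminal_penalty=True, max_number=1,
        )[0]
        assert aln.score == gotoh_optimal_score(a, b)


def test_identity_denominator_includes_gap_columns():
    # optimal alignment is 5 matched columns + 5 terminal gap columns
    a = "MKVLW"
    b = "MKVLWAAAAA"
    ident = global_identity(a, b)
    assert ident == pytest.approx(5 / 10)


def test_graph_links_identical_pair_only():
    seqs = [ProteinRecord("A", "MKVLWAYRQP" * 5),
            ProteinRecord("B", "MKVLWAYRQP" * 5),
            ProteinRecord("C", "GGSTNHEDCF" * 5)]
    edges = build_identity_graph(seqs, threshold=0.30)
    assert [(e.id_a, e.id_b) for e in edges] == [("A", "B")]


def test_graph_threshold_is_strict():
    seqs = [ProteinRecord("A", "MKVLWAYRQP" * 5),
            ProteinRecord("B", "MKVLWAYRQP" * 5)]
    # identity 1.0 is not > 1.0; just below, only exactly-identical pairs link
    assert build_identity_graph(seqs, threshold=1.0) == []
    edges = build_identity_graph(seqs, threshold=0.999)
    assert len(edges) == 1 and edges[0].identity == 1.0


def test_ten_singletons_balance_perfectly():
    seqs = [ProteinRecord(f"S{i}", "MKVLWAYRQP" * (3 + i)) for i in range(10)]
    assignment = partition_by_homology(seqs, edges=[], n_folds=5)
    sizes = np.bincount(list(assignment.folds.values()), minlength=5)
    assert list(sizes) == [2] * 5


def test_component_assigned_whole_to_one_fold():
    seqs = [ProteinRecord(f"S{i}", "MKVLWAYRQP" * 5) for i in range(10)]
    edges = [IdentityEdge(f"S{i}", f"S{i+1}", 0.9) for i in range(5)]  # S0..S5
    assignment = partition_by_homology(seqs, edges, n_folds=5)
    component_folds = {assignment.folds[f"S{i}"] for i in range(6)}
    assert len(component_folds) == 1


def test_edge_endpoints_always_share_a_fold(rng):
    seqs = [ProteinRecord(f"S{i}", "MKVLWAYRQP" * 4) for i in range(30)]
    edges = []
    for _ in range(25):
        i, j = rng.choice(30, size=2, replace=False)
        edges.append(IdentityEdge(f"S{i}", f"S{j}", 0.8))
    assignment = partition_by_homology(seqs, edges, n_folds=5)
    for e in edges:
        assert assignment.folds[e.id_a] == assignment.folds[e.id_b]
    assert set(assignment.folds) == {f"S{i}" for i in range(30)}


def test_generated_families_connect_exactly_within_families():
    cfg = desk_config(n=15, family_size=5)
    corpus = generate(cfg, seed=3)
    edges = build_identity_graph([ls.record for ls in corpus], threshold=0.30)
    fam = {ls.record.id: ls.family for ls in corpus}
    linked = {frozenset((e.id_a, e.id_b)) for e in edges}
    expected = {
        frozenset((a.record.id, b.record.id))
        for i, a in enumerate(corpus) for b in corpus[i + 1:]
        if fam[a.record.id] == fam[b.record.id]
    }
    assert linked == expected


def test_independence_check_empty_on_partitioner_split():
    cfg = desk_config(n=24, family_size=4)
    corpus = generate(cfg, seed=5)
    records = [ls.record for ls in corpus]
    edges = build_identity_graph(records, threshold=0.30)
    assignment = partition_by_homology(records, edges, n_folds=3)
    for ls in corpus:
        ls.partition = assignment.folds[ls.record.id]
    test_set = [ls for ls in corpus if ls.partition == 0]
    train_set = [ls for ls in corpus if ls.partition != 0]
    assert check_test_independence(test_set, train_set) == []


def test_partition_by_groups_keeps_groups_atomic():
    groups = ["a", "a", "a", "b", "b", "c", "d", "e"]
    ids = [f"S{i}" for i in range(8)]
    assignment = partition_by_groups(groups, ids, n_folds=3)
    assert len({assignment.folds[i] for i, g in zip(ids, groups) if g == "a"}) == 1
    assert len({assignment.folds[i] for i, g in zip(ids, groups) if g == "b"}) == 1
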