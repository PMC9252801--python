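"""Global sequence identity, the identity graph, and homology-aware folds.

Cross-validation on protein corpora leaks information unless homologous
sequences are confined to one fold.  Here homology means >30% global sequence
identity under Needleman-Wunsch alignment (BLOSUM62, gap open 11, gap extend
1), with identity defined as matches divided by the full alignment length
including gap columns -- the stricter of the common conventions, and the one
that stays well-defined for unequal sequence lengths.  Sequences are linked
into a graph by that criterion; connected components are assigned whole to
folds by greedy size balancing, so no two folds ever share a homologous pair.

The all-pairs path is quadratic and intended for corpora up to a few thousand
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .seq_io import LabeledSequence, ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "IdentityEdge",
    "FoldAssignment",
    "global_identity",
    "build_identity_graph",
    "partition_by_homology",
    "partition_by_groups",
    "check_test_independence",
]

GAP_OPEN = -11
GAP_EXTEND = -1
DEFAULT_IDENTITY_THRESHOLD = 0.30

_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class IdentityEdge:
    id_a: str
    id_b: str
    identity: float


@dataclass
class FoldAssignment:
    """Map from sequence id to fold, with the component structure kept."""

    folds: dict[str, int]
    component_map: dict[str, int]
    n_folds: int


def _align_identity(a: str, b: str) -> float:
    seq_a = ProteinSequence(a)
    seq_b = ProteinSequence(b)
    aln = align_optimal(
        seq_a,
        seq_b,
        _BLOSUM62,
        gap_penalty=(GAP_OPEN, GAP_EXTEND),
        terminal_penalty=True,
        max_number=1,
    )[0]
    trace = aln.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    codes_a = np.frombuffer(a.encode(), dtype=np.uint8)[trace[both, 0]]
    codes_b = np.frombuffer(b.encode(), dtype=np.uint8)[trace[both, 1]]
    matches = int(np.sum(codes_a == codes_b))
    return matches / trace.shape[0]


def global_identity(a: str, b: str) -> float:
    """Global (Needleman-Wunsch) identity between two sequences, in [0, 1].

    The pair is aligned in a canonical order so the value is symmetric even
    when several co-optimal alignments exist.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if (len(a), a) <= (len(b), b):
        return _align_identity(a, b)
    return _align_identity(b, a)


def build_identity_graph(
    seqs: Sequence[ProteinRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[IdentityEdge]:
    """All pairs whose global identity strictly exceeds ``threshold``."""
    ids = [r.id for r in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    edges: list[IdentityEdge] = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident = global_identity(seqs[i].sequence, seqs[j].sequence)
            if ident > threshold:
                edges.append(
                    IdentityEdge(id_a=ids[i], id_b=ids[j], identity=ident)
                )
    return edges


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _greedy_balance(
    components: list[list[str]], n_folds: int
) -> tuple[dict[str, int], dict[str, int]]:
    """Assign components whole to folds: largest first, to the currently
    smallest fold, ties to the lowest fold index."""
    order = sorted(
        range(len(components)),
        key=lambda k: (-len(components[k]), min(components[k])),
    )
    fold_sizes = [0] * n_folds
    folds: dict[str, int] = {}
    component_map: dict[str, int] = {}
    for comp_id, k in enumerate(order):
        target = int(np.argmin(fold_sizes))  # lowest index wins ties
        for sid in components[k]:
            folds[sid] = target
            component_map[sid] = comp_id
        fold_sizes[target] += len(components[k])
    return folds, component_map


def partition_by_homology(
    seqs: Sequence[ProteinRecord],
    edges: Sequence[IdentityEdge],
    n_folds: int = 5,
) -> FoldAssignment:
    """Assign connected components of the identity graph whole to folds.

    Guarantees that no pair above the identity threshold is split across
    folds.  A component larger than ceil(n / n_folds) is unavoidable
    imbalance and is logged, not rejected.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    ids = [r.id for r in seqs]
    id_set = set(ids)
    for e in edges:
        if e.id_a not in id_set or e.id_b not in id_set:
            raise ValueError(f"edge endpoint not among sequences: {e}")
    uf = _UnionFind(ids)
    for e in edges:
        uf.union(e.id_a, e.id_b)
    groups: dict[str, list[str]] = {}
    for sid in ids:
        groups.setdefault(uf.find(sid), []).append(sid)
    components = list(groups.values())
    cap = ceil(len(ids) / n_folds)
    for comp in components:
        if len(comp) > cap:
            logger.warning(
                "component of size %d exceeds the balanced fold size %d",
                len(comp), cap,
            )
    folds, component_map = _greedy_balance(components, n_folds)
    return FoldAssignment(folds=folds, component_map=component_map, n_folds=n_folds)


def partition_by_groups(
    groups: Sequence[str], ids: Sequence[str], n_folds: int = 5
) -> FoldAssignment:
    """Fold assignment from precomputed group labels (e.g. generator families),
    using the same greedy balancing as the identity-graph path."""
    by_group: dict[str, list[str]] = {}
    for g, sid in zip(groups, ids):
        by_group.setdefault(g, []).append(sid)
    components = list(by_group.values())
    folds, component_map = _greedy_balance(components, n_folds)
    return FoldAssignment(folds=folds, component_map=component_map, n_folds=n_folds)


def check_test_independence(
    test: Sequence[LabeledSequence],
    train: Sequence[LabeledSequence],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[tuple[str, str, float]]:
    """Every (test_id, train_id, identity) pair exceeding the threshold.

    An empty list certifies that the test set is independent of the training
    set at the given global-identity level.
    """
    violations: list[tuple[str, str, float]] = []
    for t in test:
        for r in train:
            ident = global_identity(t.record.sequence, r.record.sequence)
            if ident > identity_threshold:
                violations.append((t.record.id, r.record.id, ident))
    return violations
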