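"""Desk-scale family grouping: Needleman-Wunsch global alignment,
identity-based distance matrices, neighbor joining, Newick output.

This is a distance-based stand-in for maximum-likelihood tree building: no
bootstrap support, no substitution-model selection.  Distances come from
pairwise (not multiple) alignment identity, which is adequate for the short
mature peptides this package produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ContractError, SequenceAlphabetError

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class AlignScoring:
    gap: float = -8.0  # linear gap penalty per residue

    def score(self, a: str, b: str) -> float:
        try:
            return float(_BLOSUM62[a, b])
        except (KeyError, IndexError) as exc:
            raise SequenceAlphabetError(f"residue pair {a}{b} not scorable") from exc


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_fraction: float


def global_align(
    a: str, b: str, scoring: AlignScoring | None = None
) -> AlignmentResult:
    """Optimal global alignment (Needleman-Wunsch), BLOSUM62 + linear gaps.

    Deterministic tie-breaking in the traceback: diagonal, then up (gap in
    ``b``), then left (gap in ``a``).  Identity is computed over columns
    where both sequences have a residue.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or AlignScoring()
    for ch in set(a) | set(b):
        if ch not in _BLOSUM62.alphabet:
            raise SequenceAlphabetError(f"character {ch!r} outside alphabet")
    n, m = len(a), len(b)
    gap = scoring.gap
    F = np.empty((n + 1, m + 1))
    F[0, :] = np.arange(m + 1) * gap
    F[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            F[i, j] = max(
                F[i - 1, j - 1] + scoring.score(a[i - 1], b[j - 1]),
                F[i - 1, j] + gap,
                F[i, j - 1] + gap,
            )
    # traceback, preferring diagonal > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and F[i, j] == F[i - 1, j - 1] + scoring.score(a[i - 1], b[j - 1])
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    both = [
        (x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"
    ]
    identity = (
        sum(1 for x, y in both if x == y) / len(both) if both else 0.0
    )
    return AlignmentResult(aligned_a, aligned_b, float(F[n, m]), identity)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ContractError("matrix shape does not match labels")


def pairwise_distance_matrix(
    peptides: Sequence[tuple[str, str]], scoring: AlignScoring | None = None
) -> DistanceMatrix:
    """Distance = 1 - identity_fraction of the global alignment; computed
    once per pair, hence symmetric by construction."""
    if len(peptides) < 2:
        raise ValueError("need at least two sequences")
    labels = [pid for pid, _ in peptides]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate ids: {dup}")
    k = len(peptides)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = global_align(peptides[i][1], peptides[j][1], scoring)
            values[i, j] = values[j, i] = 1.0 - res.identity_fraction
    return DistanceMatrix(labels, values)


@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root (classic NJ output)."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()


def _clamp(length: float) -> float:
    if length < 0:
        warnings.warn(
            f"negative NJ branch length {length:.6f} clamped to 0", stacklevel=3
        )
        return 0.0
    return length


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Classical neighbor joining (Saitou-Nei Q-criterion).

    Ties in Q are broken by the lexicographically smallest pair of cluster
    representatives (the minimal leaf label under each cluster), so the
    topology is reproducible.  Negative branch-length estimates are clamped
    to zero with a warning.
    """
    k = len(matrix.labels)
    if k < 3:
        raise ContractError("neighbor joining needs at least 3 taxa")
    if not np.allclose(matrix.values, matrix.values.T):
        raise ContractError("distance matrix must be symmetric")
    if not np.allclose(np.diag(matrix.values), 0.0):
        raise ContractError("distance matrix must have a zero diagonal")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=lab) for i, lab in enumerate(matrix.labels)
    }
    rep: dict[int, str] = {i: lab for i, lab in enumerate(matrix.labels)}
    D: dict[int, dict[int, float]] = {
        i: {j: float(matrix.values[i, j]) for j in range(k) if j != i}
        for i in range(k)
    }
    next_id = k
    active = sorted(nodes)

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i][j] - r[i] - r[j]
                key = (q, tuple(sorted((rep[i], rep[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i][j]
        limb_i = _clamp(dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2)))
        limb_j = _clamp(dij - (dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))))
        u = next_id
        next_id += 1
        nodes[u] = TreeNode(children=[(nodes[i], limb_i), (nodes[j], limb_j)])
        rep[u] = min(rep[i], rep[j])
        D[u] = {}
        for m in active:
            if m in (i, j):
                continue
            d = (D[i][m] + D[j][m] - dij) / 2.0
            D[u][m] = d
            D[m][u] = d
        active = sorted(x for x in active if x not in (i, j)) + [u]
        for m in active:
            D[m].pop(i, None)
            D[m].pop(j, None)
        del D[i], D[j], nodes[i], nodes[j]

    a, b, c = sorted(active, key=lambda x: rep[x])
    la = _clamp((D[a][b] + D[a][c] - D[b][c]) / 2.0)
    lb = _clamp((D[a][b] + D[b][c] - D[a][c]) / 2.0)
    lc = _clamp((D[a][c] + D[b][c] - D[a][b]) / 2.0)
    root = TreeNode(
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )
    return PhyloTree(root=root)


def _newick_label(label: str) -> str:
    if any(ch in label for ch in " ,();:'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _to_newick(node: TreeNode) -> str:
    if not node.children:
        return _newick_label(node.label or "")
    inner = ",".join(
        f"{_to_newick(child)}:{length:.6f}" for child, length in node.children
    )
    return f"({inner})"


def tree_to_newick(tree: PhyloTree) -> str:
    return _to_newick(tree.root) + ";"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Standard Newick with branch lengths at 6 decimal places."""
    Path(path).write_text(tree_to_newick(tree) + "\n")
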