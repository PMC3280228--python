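"""Distance matrices, progressive alignment, NJ trees and bootstrap.

The tree-building path mirrors the classic ClustalW/MEGA workflow:
pairwise p-distances feed a neighbor-joining guide tree, a progressive
profile-profile alignment produces the MSA, and a second NJ on the MSA's
p-distance matrix gives the final tree. Bootstrap support for each
internal bipartition of the full-data tree is the percentage of
column-resampled replicate trees containing that bipartition (the
MEGA-style convention, not a consensus tree).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .classify import DEFAULT_SCORING, Scoring, global_align
from .errors import InputError
from .records import AMINO_ACIDS, ProteinRecord

GAP = "-"


@dataclass
class Msa:
    """A multiple alignment: parallel lists of ids and gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise InputError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self) -> dict[str, str]:
        return {i: r.replace(GAP, "") for i, r in zip(self.ids, self.rows)}

    def resample_columns(self, cols: Sequence[int]) -> "Msa":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Msa(list(self.ids), rows)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")

    @classmethod
    def read(cls, path: str | Path) -> "Msa":
        ids, rows, cur = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if cur:
                        rows.append("".join(cur))
                        cur = []
                    ids.append(line[1:].split()[0])
                elif line:
                    cur.append(line)
        if cur:
            rows.append("".join(cur))
        return cls(ids, rows)


# ---------------------------------------------------------------------------
# p-distance

def pdistance(msa: Msa) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix of an alignment.

    d(i,j) = mismatched columns / columns where both rows hold residues.
    """
    n = len(msa.ids)
    arr = np.array([list(r) for r in msa.rows])
    isres = arr != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = isres[i] & isres[j]
            comp = int(both.sum())
            if comp == 0:
                raise InputError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}")
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / comp
    return DistanceMatrix(d, ids=msa.ids)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining (Q-criterion) on a distance matrix.

    Ties in Q are broken by the lexicographically smallest taxon pair
    (a merged node is keyed by the smallest leaf label beneath it).
    Negative branch lengths are clamped to zero; the number of clamped
    branches is recorded as ``tree.n_clamped``.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    data = np.asarray(dm.data, dtype=float)
    if not np.allclose(data, data.T):
        raise InputError("distance matrix is not symmetric")

    d: dict[str, dict[str, float]] = {
        a: {b: float(data[i, j]) for j, b in enumerate(ids) if b != a}
        for i, a in enumerate(ids)
    }
    nodes: dict[str, TreeNode] = {a: TreeNode(name=a) for a in ids}
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    active = sorted(ids)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d[a][b]
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        parent = TreeNode()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = clamp(la)
        nb.length = clamp(lb)
        parent.extend([na, nb])
        label = min(a, b)
        nodes[label] = parent
        new_d = {}
        for c in active:
            if c in (a, b):
                continue
            new_d[c] = (d[a][c] + d[b][c] - dab) / 2
        for c, val in new_d.items():
            d[c][label] = val
        d[label] = new_d
        active = sorted(c for c in active if c not in (a, b))
        active.append(label)
        active.sort()

    a, b, c = active
    root = TreeNode()
    na, nb, nc = nodes[a], nodes[b], nodes[c]
    na.length = clamp((d[a][b] + d[a][c] - d[b][c]) / 2)
    nb.length = clamp((d[a][b] + d[b][c] - d[a][c]) / 2)
    nc.length = clamp((d[a][c] + d[b][c] - d[a][b]) / 2)
    root.extend([na, nb, nc])
    root.n_clamped = n_clamped
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized as the
    side not containing the lexicographically smallest taxon."""
    taxa = frozenset(t.name for t in tree.tips())
    ref = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def forms_clade(tree: TreeNode, taxa: set[str]) -> bool:
    """Whether a taxon set sits on one side of some edge (unrooted sense)."""
    all_taxa = frozenset(t.name for t in tree.tips())
    want = frozenset(taxa)
    if len(want) in (1, len(all_taxa)):
        return True
    comp = all_taxa - want
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == want or side == comp:
            return True
    return False


# ---------------------------------------------------------------------------
# Progressive multiple alignment

_SUBMAT_CACHE: dict[str, tuple[np.ndarray, dict[str, int]]] = {}


def _submatrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    if name not in _SUBMAT_CACHE:
        mat = substitution_matrices.load(name)
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        S = np.zeros((20, 20))
        for a, i in idx.items():
            for b, j in idx.items():
                S[i, j] = mat[a][b]
        _SUBMAT_CACHE[name] = (S, idx)
    return _SUBMAT_CACHE[name]


def _profile_counts(rows: list[str], idx: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    L = len(rows[0])
    counts = np.zeros((L, 20))
    for r in rows:
        for k, ch in enumerate(r):
            if ch != GAP:
                counts[k, idx[ch]] += 1
    return counts, counts.sum(axis=1)


def _profile_align(
    rows_a: list[str], rows_b: list[str], scoring: Scoring, gap_penalty: float,
) -> tuple[list[str], list[str]]:
    """Align two profiles with mean substitution scores, linear gaps."""
    S, idx = _submatrix(scoring.matrix)
    ca, na = _profile_counts(rows_a, idx)
    cb, nb = _profile_counts(rows_b, idx)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (ca @ S @ cb.T) / denom
    s = np.where(denom > 0, s, 0.0)
    La, Lb = len(na), len(nb)
    g = gap_penalty
    H = np.zeros((La + 1, Lb + 1))
    H[0, :] = -g * np.arange(Lb + 1)
    H[:, 0] = -g * np.arange(La + 1)
    ar = np.arange(Lb + 1) * g
    for i in range(1, La + 1):
        U = np.empty(Lb + 1)
        U[0] = H[i, 0]
        U[1:] = np.maximum(H[i - 1, :-1] + s[i - 1], H[i - 1, 1:] - g)
        H[i] = np.maximum.accumulate(U + ar) - ar
    # Traceback by score consistency.
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = La, Lb
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and np.isclose(h, H[i - 1, j - 1] + s[i - 1, j - 1]):
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(h, H[i - 1, j] - g):
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            i -= 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            j -= 1
    return (["".join(reversed(r)) for r in out_a],
            ["".join(reversed(r)) for r in out_b])


def progressive_msa(
    records: Sequence[ProteinRecord],
    scoring: Scoring = DEFAULT_SCORING,
    gap_penalty: float = 8.0,
) -> Msa:
    """Guide-tree progressive alignment.

    The guide tree is NJ on pairwise global-alignment p-distances
    (1 - identity); profiles are merged up the tree with mean
    substitution scores and a linear gap penalty. Two sequences reduce
    to the pairwise global aligner.
    """
    if not records:
        raise InputError("no sequences to align")
    if len(records) == 1:
        warnings.warn("single sequence: returned unaligned", stacklevel=2)
        return Msa([records[0].id], [records[0].seq])
    if len(records) == 2:
        aln = global_align(records[0].seq, records[1].seq, scoring)
        return Msa([records[0].id, records[1].id], [aln.a, aln.b])

    ids = [r.id for r in records]
    seqs = {r.id: r.seq for r in records}
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].seq, records[j].seq, scoring)
            d[i, j] = d[j, i] = 1.0 - aln.identity
    guide = nj_tree(DistanceMatrix(d, ids=ids))

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [seqs[node.name]]
        child_profiles = [merge(ch) for ch in node.children]
        acc_ids, acc_rows = child_profiles[0]
        for nxt_ids, nxt_rows in child_profiles[1:]:
            left, right = _profile_align(acc_rows, nxt_rows, scoring, gap_penalty)
            acc_ids, acc_rows = acc_ids + nxt_ids, left + right
        return acc_ids, acc_rows

    got_ids, got_rows = merge(guide)
    order = {g: k for k, g in enumerate(got_ids)}
    rows = [got_rows[order[i]] for i in ids]
    return Msa(ids, rows)


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(
    msa: Msa, n_reps: int = 1000, seed: int = 0,
) -> TreeNode:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal edge of the full-data tree is the percentage of
    replicate NJ trees containing its bipartition. Deterministic for a
    given seed.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    if msa.n_cols < 2:
        raise InputError("alignment has fewer than 2 columns")
    tree = nj_tree(pdistance(msa))
    taxa = frozenset(msa.ids)
    ref = min(taxa)
    node_bips: list[tuple[TreeNode, frozenset[str]]] = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            node_bips.append((node, side))
    counts = {side: 0 for _, side in node_bips}
    rng = np.random.default_rng(seed)
    L = msa.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = msa.resample_columns(list(cols))
        try:
            rep_bips = bipartitions(nj_tree(pdistance(rep)))
        except InputError:
            continue  # replicate with an incomparable pair supports nothing
        for side in counts:
            if side in rep_bips:
                counts[side] += 1
    for node, side in node_bips:
        node.support = 100.0 * counts[side] / n_reps
    tree.supports_from = f"{n_reps} bootstrap replicates"
    return tree


# ---------------------------------------------------------------------------
# Newick I/O (supports written as internal node labels)

def write_newick(tree: TreeNode, path_or_handle) -> None:
    """Write a tree; supports appear as internal node labels (scikit-bio
    writes ``node.support`` in label position when the name is unset)."""
    tree.write(path_or_handle, format="newick")


def read_newick(path_or_handle) -> TreeNode:
    tree = TreeNode.read(path_or_handle, format="newick")
    tree.assign_supports()  # numeric internal labels -> node.support
    return tree


def newick_string(tree: TreeNode) -> str:
    buf = io.StringIO()
    write_newick(tree, buf)
    return buf.getvalue().strip()
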