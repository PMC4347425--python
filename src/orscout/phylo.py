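"""Pairwise amino-acid identity and distance-based phylogeny.

Percent identity between two proteins is computed from a global affine-gap
alignment (BLOSUM62): terminal-gap columns are stripped, then
identity = 100 * identical columns / remaining columns, so internal gaps
count against identity.  Trees are built by canonical neighbor joining on
d = (100 - identity) / 100, with a deterministic lowest-index tie-break,
and branch support comes from column-bootstrap of an alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq import ProtSeq


# ---------------------------------------------------------------------------
# identity matrix


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # square, percent

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        self.values = v

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_distances(self) -> np.ndarray:
        return (100.0 - self.values) / 100.0

    @property
    def off_diagonal_range(self) -> tuple[float, float]:
        n = len(self.labels)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].min()), float(self.values[mask].max())


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _identity_from_gapped(row_a: str, row_b: str) -> float:
    """Identity over columns after stripping terminal-gap columns; both-gap
    columns are ignored; remaining gap columns count against identity."""
    cols = [(x, y) for x, y in zip(row_a, row_b) if not (x == "-" and y == "-")]
    lo = 0
    while lo < len(cols) and "-" in cols[lo]:
        lo += 1
    hi = len(cols)
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    core = cols[lo:hi]
    if not core:
        return 0.0
    same = sum(1 for x, y in core if x == y and x != "-")
    return 100.0 * same / len(core)


def pairwise_identity_matrix(
    prots: Sequence[ProtSeq], mode: str = "pairwise_global"
) -> IdentityMatrix:
    """Symmetric percent-identity matrix, diagonal 100.

    ``pairwise_global`` aligns every pair with Needleman-Wunsch (affine gaps,
    BLOSUM62); ``from_msa`` expects pre-aligned equal-length sequences and
    applies the same column rule per pair.  Each unordered pair is aligned
    once (canonical order), so the matrix is exactly symmetric.
    """
    if len(prots) < 2:
        raise ValueError("need at least two sequences")
    ids = [p.id for p in prots]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    for p in prots:
        if not p.residues:
            raise ValueError(f"{p.id}: empty sequence")
    n = len(prots)
    vals = np.full((n, n), 100.0)
    if mode == "pairwise_global":
        aligner = _make_aligner()
        seqs = [p.residues.rstrip("*") for p in prots]
        for i, j in itertools.combinations(range(n), 2):
            al = aligner.align(seqs[i], seqs[j])[0]
            vals[i, j] = vals[j, i] = _identity_from_gapped(str(al[0]), str(al[1]))
    elif mode == "from_msa":
        lens = {len(p.residues) for p in prots}
        if len(lens) != 1:
            raise ValueError("from_msa mode requires equal-length aligned sequences")
        for i, j in itertools.combinations(range(n), 2):
            vals[i, j] = vals[j, i] = _identity_from_gapped(
                prots[i].residues, prots[j].residues
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return IdentityMatrix(labels=list(ids), values=vals)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    name: Optional[str] = None  # leaf label
    children: list = field(default_factory=list)  # list[TreeNode]
    length: float = 0.0  # branch to parent, clamped >= 0
    raw_length: float = 0.0  # pre-clamp NJ estimate
    support: Optional[float] = None  # percent, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"

    def to_newick(self, with_support: bool = True) -> str:
        inner = ",".join(c._newick(with_support) for c in self.children)
        return f"({inner});"


@dataclass
class PhyloTree:
    root: TreeNode  # unrooted tree stored with a (tri/bi)furcating root
    labels: list[str]

    def to_newick(self, with_support: bool = True) -> str:
        return self.root.to_newick(with_support)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the leaf set not containing labels[0]."""
        full = set(self.labels)
        ref = self.labels[0]
        out: set[frozenset] = set()

        def walk(node: TreeNode):
            for child in node.children:
                side = set(child.leaves())
                if 2 <= len(side) <= len(full) - 2:
                    if ref in side:
                        side = full - side
                    out.add(frozenset(side))
                walk(child)

        walk(self.root)
        return out

    def internal_nodes(self):
        ref = self.labels[0]
        full = set(self.labels)
        out = []

        def walk(node: TreeNode):
            for child in node.children:
                if not child.is_leaf:
                    side = set(child.leaves())
                    if 2 <= len(side) <= len(full) - 2:
                        key = frozenset(full - side if ref in side else side)
                        out.append((key, child))
                    walk(child)

        walk(self.root)
        return out


def _check_distance_matrix(dist: np.ndarray):
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def build_nj_tree(dist: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Canonical neighbor joining (Saitou-Nei with the standard Q criterion).

    Deterministic: the joined pair is the lowest-(i, j) minimizer of Q.
    Negative branch-length estimates are clamped to 0 with the raw value
    retained on the node.  The result is an unrooted tree serialized with a
    trifurcating root (bifurcating for fewer than four taxa).
    """
    d = _check_distance_matrix(dist).copy()
    labels = list(labels)
    if len(labels) != d.shape[0]:
        raise ValueError("labels do not match matrix size")
    if len(labels) < 2:
        raise ValueError("need at least two taxa")

    nodes: list[TreeNode] = [TreeNode(name=lb) for lb in labels]
    active = list(range(len(labels)))

    def set_len(node: TreeNode, raw: float):
        node.raw_length = float(raw)
        node.length = max(0.0, float(raw))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index minimizer: argmin of the flattened row-major matrix
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, n)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        u = TreeNode(children=[nodes[i], nodes[j]])
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d[i, active] = new_row
        d[active, i] = new_row
        d[i, i] = 0.0
        nodes[i] = u
        active.remove(j)

    if len(active) == 2:
        i, j = active
        root = TreeNode(children=[nodes[i], nodes[j]])
        set_len(nodes[i], d[i, j] / 2.0)
        set_len(nodes[j], d[i, j] / 2.0)
    else:
        a, b, c = active
        root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
        set_len(nodes[a], 0.5 * (d[a, b] + d[a, c] - d[b, c]))
        set_len(nodes[b], 0.5 * (d[a, b] + d[b, c] - d[a, c]))
        set_len(nodes[c], 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    return PhyloTree(root=root, labels=labels)


def nj_tree_from_identity(matrix: IdentityMatrix) -> PhyloTree:
    return build_nj_tree(matrix.to_distances(), matrix.labels)


def bootstrap_support(
    msa: Sequence[ProtSeq], n_reps: int = 100, seed: int = 0
) -> PhyloTree:
    """Column-bootstrap branch support on the full-data NJ tree.

    Each replicate resamples alignment columns with replacement, recomputes
    the identity matrix (``from_msa`` rule, so all-gap resampled columns are
    simply ignored), rebuilds the NJ tree, and each bipartition of the
    full-data tree is supported by the percentage of replicates containing
    it.  Seeded and reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ncols = len(msa[0].residues)
    if ncols < 1:
        raise ValueError("alignment has no columns")
    full_matrix = pairwise_identity_matrix(msa, mode="from_msa")
    tree = nj_tree_from_identity(full_matrix)
    target = {key: node for key, node in tree.internal_nodes()}
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    rows = [p.residues for p in msa]
    ids = [p.id for p in msa]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        boot = [
            ProtSeq(ids[i], "".join(rows[i][c] for c in cols))
            for i in range(len(msa))
        ]
        bm = pairwise_identity_matrix(boot, mode="from_msa")
        bt = nj_tree_from_identity(bm)
        present = bt.bipartitions()
        for key in counts:
            if key in present:
                counts[key] += 1
    for key, node in target.items():
        node.support = 100.0 * counts[key] / n_reps
    return tree


def write_identity_matrix(matrix: IdentityMatrix, path, header_lines: Sequence[str] = ()):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.to_dataframe().round(2).to_csv(fh, sep="\t", index_label="gene_id")
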