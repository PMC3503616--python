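"""Genetic distances, UPGMA dendrograms, bootstrap support, clusters.

Two distances feed the dendrograms: the Nei–Li / Dice association distance
on 0/1 allele-presence profiles (d = 1 - 2a/(2a+b+c), shared absences
ignored — the natural choice for dominant/presence-absence markers), and
the p-distance with pairwise deletion for aligned sequences.  UPGMA
agglomeration is size-weighted average linkage with node height = merge
distance / 2 and a deterministic lowest-index tie-break.  Bootstrap support
of an internal node is the percentage of column-resampled replicate trees
containing the same leaf bipartition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype import BinaryMatrix

_MISSING = {"-", "N", "?", "."}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and nonnegative")

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])


@dataclass
class TreeNode:
    """Node of a rooted ultrametric dendrogram."""

    height: float
    name: str | None = None                 # leaf label
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None            # bootstrap %, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out += c.leaves()
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class UltrametricTree:
    root: TreeNode
    ids: list[str]
    linkage: np.ndarray  # (n-1, 4): child_i, child_j, merge distance, size

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, parent_h: float) -> str:
            bl = parent_h - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{bl:.6g}"

        r = self.root
        inner = ",".join(fmt(c, r.height) for c in r.children)
        label = f"{r.support:g}" if (with_support and r.support is not None) else ""
        return f"({inner}){label};"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distance: twice the height of the LCA."""
        names = self.ids
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def rec(node: TreeNode) -> list[int]:
            if node.is_leaf:
                return [idx[node.name]]
            groups = [rec(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[a, b] = d[b, a] = 2 * node.height
            return [x for g in groups for x in g]

        rec(self.root)
        return DistanceMatrix(list(names), d)


@dataclass(frozen=True)
class ClusterSummary:
    label: str
    members: tuple[str, ...]
    within_mean: float
    within_sd: float
    between_mean: float
    between_sd: float


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def binary_association_distance(matrix: BinaryMatrix, method: str = "neili") -> DistanceMatrix:
    """Association distance between 0/1 allele-presence rows.

    ``neili`` (default): with a = shared 1s, b/c = 1s private to either row,
    similarity S = 2a/(2a+b+c) and d = 1 - S; shared absences carry no
    signal.  ``simple`` uses simple matching, S = (matches)/(columns).
    A pair with no 1s at all in either row has no shared alleles; its
    Nei–Li distance is defined as 1 (logged).
    """
    X = np.asarray(matrix.cells, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 strains")
    if method == "neili":
        a = X @ X.T
        rs = X.sum(axis=1)
        denom = rs[:, None] + rs[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(denom > 0, 2 * a / denom, 0.0)
        if (denom == 0).any():
            warnings.warn("strain pair(s) with no alleles at all: distance set to 1")
        d = 1.0 - S
    elif method == "simple":
        n_cols = X.shape[1]
        a = X @ X.T
        z = (1 - X) @ (1 - X).T
        d = 1.0 - (a + z) / n_cols
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 1.0)
    return DistanceMatrix(list(matrix.strain_ids), d)


def encode_alignment(seqs: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Aligned sequences -> integer matrix; missing symbols coded -1."""
    ids = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences not aligned: lengths {sorted(lengths)}")
    lut = np.full(256, -2, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    for b in _MISSING:
        lut[ord(b)] = -1
    mat = np.vstack([
        lut[np.frombuffer(seqs[i].upper().encode(), dtype=np.uint8)] for i in ids
    ])
    mat[mat == -2] = -1  # unknown residues treated as missing
    return ids, mat


def p_distance(seqs: Mapping[str, str]) -> DistanceMatrix:
    """Proportion of differing sites with pairwise deletion of missing data."""
    ids, mat = encode_alignment(seqs)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    d = np.zeros((n, n))
    present = mat >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            diff = int(((mat[i] != mat[j]) & both).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> UltrametricTree:
    """Unweighted pair-group agglomeration with arithmetic-mean linkage.

    Node height is half the merge distance, so the tree is ultrametric and
    cophenetic distances are on the scale of the input.  When several pairs
    tie for the minimum, the lexicographically smallest index pair (in the
    current cluster ordering) is merged — the run is fully deterministic.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need >= 2 ids")
    D = dm.d.copy()
    nodes = [TreeNode(0.0, name=i) for i in dm.ids]
    sizes = [1] * n
    active = list(range(n))
    linkage = []
    big = np.inf
    work = D.copy()
    np.fill_diagonal(work, big)
    while len(active) > 1:
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)  # row-major: first minimum = lowest index pair
        i_loc, j_loc = divmod(int(flat), len(active))
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        new = TreeNode(dij / 2, children=[nodes[i], nodes[j]])
        linkage.append((i, j, float(dij), sizes[i] + sizes[j]))
        # size-weighted average linkage update, new cluster takes slot i
        for k in active:
            if k in (i, j):
                continue
            dk = (sizes[i] * work[i, k] + sizes[j] * work[j, k]) / (sizes[i] + sizes[j])
            work[i, k] = work[k, i] = dk
        nodes[i] = new
        sizes[i] += sizes[j]
        active.remove(j)
    root = nodes[active[0]]
    return UltrametricTree(root, list(dm.ids), np.array(linkage))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: UltrametricTree) -> dict[int, frozenset]:
    """Canonical leaf bipartition per internal node (smaller side kept)."""
    all_leaves = frozenset(tree.ids)
    out = {}
    for idx, node in enumerate(tree.internal_nodes()):
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[idx] = canon
    return out


def _binary_distance_from_cells(cells: np.ndarray, ids: list[str], method: str) -> DistanceMatrix:
    bm = BinaryMatrix(ids, [("c", k) for k in range(cells.shape[1])], cells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return binary_association_distance(bm, method=method)


def bootstrap_support(
    data: BinaryMatrix | Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    method: str = "neili",
) -> UltrametricTree:
    """UPGMA tree with bootstrap supports from column resampling.

    Columns of the data (binary allele columns, or alignment columns) are
    resampled with replacement ``n_reps`` times; the support of an internal
    node is the percentage of replicate trees containing the same leaf
    bipartition.  Reproducible for a given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(data, BinaryMatrix):
        ids = list(data.strain_ids)
        cells = np.asarray(data.cells)
        # canonical column order: resampling then depends only on the column
        # multiset, making supports exactly invariant to column permutation
        cells = cells[:, np.lexsort(cells[::-1, :])]
        base = binary_association_distance(data, method=method)

        def replicate_dm() -> DistanceMatrix:
            cols = rng.integers(0, cells.shape[1], size=cells.shape[1])
            return _binary_distance_from_cells(cells[:, cols], ids, method)
    else:
        ids, mat = encode_alignment(data)
        mat = mat[:, np.lexsort(mat[::-1, :])]
        base = p_distance(data)

        def replicate_dm() -> DistanceMatrix:
            cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
            sub = mat[:, cols]
            return p_distance({i: _decode_row(sub[k]) for k, i in enumerate(ids)})

    tree = upgma(base)
    parts = _bipartitions(tree)
    counts = {idx: 0 for idx in parts}
    for _ in range(n_reps):
        rep_tree = upgma(replicate_dm())
        rep_parts = set(_bipartitions(rep_tree).values())
        for idx, part in parts.items():
            if part in rep_parts:
                counts[idx] += 1
    for idx, node in enumerate(tree.internal_nodes()):
        node.support = 100.0 * counts[idx] / n_reps
    return tree


def _decode_row(row: np.ndarray) -> str:
    alpha = np.array(list("ACGT-"))
    return "".join(alpha[np.where(row >= 0, row, 4)])


# ---------------------------------------------------------------------------
# cluster extraction and summaries
# ---------------------------------------------------------------------------

def extract_clusters(
    tree: UltrametricTree,
    k: int | None = None,
    height: float | None = None,
) -> dict[str, int]:
    """Cut the dendrogram into flat clusters.

    With ``k``, the cut undoes the k-1 highest merges (warning if merge
    heights tie at the boundary — the lowest consistent cutting height is
    used); with ``height``, every merge at height <= cutoff is kept.
    Returns strain -> cluster label (1.., by first member occurrence).
    """
    n = len(tree.ids)
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError("k out of range")
        n_merges = n - k
        heights = sorted(float(h) for h in tree.linkage[:, 2])
        if 0 < n_merges < n - 1 and np.isclose(heights[n_merges - 1], heights[n_merges]):
            warnings.warn("tied merge heights at the cut: lowest cutting height used")
        order = np.argsort(tree.linkage[:, 2], kind="stable")[:n_merges]
        keep = set(int(o) for o in order)
    else:
        keep = {m for m in range(len(tree.linkage)) if tree.linkage[m, 2] / 2 <= height}

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in sorted(keep):
        i, j = int(tree.linkage[m, 0]), int(tree.linkage[m, 1])
        parent[find(j)] = find(i)

    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for idx, sid in enumerate(tree.ids):
        r = find(idx)
        if r not in root_label:
            root_label[r] = len(root_label) + 1
        labels[sid] = root_label[r]
    return labels


def cluster_distance_summary(dm: DistanceMatrix, members: Iterable[str], label: str = "") -> ClusterSummary:
    """Within- vs between-cluster genetic distance (mean ± sample sd)."""
    members = list(members)
    missing = [m for m in members if m not in dm.ids]
    if missing:
        raise ValueError(f"members not in distance matrix: {missing}")
    if len(members) < 2:
        raise ValueError("need >= 2 members")
    idx = [dm.ids.index(m) for m in members]
    rest = [i for i in range(len(dm.ids)) if i not in set(idx)]
    within = [dm.d[a, b] for ai, a in enumerate(idx) for b in idx[ai + 1:]]
    between = [dm.d[a, b] for a in idx for b in rest]
    w = np.array(within, dtype=float)
    b = np.array(between, dtype=float)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return ClusterSummary(
        label or "+".join(members[:3]), tuple(members),
        float(w.mean()), sd(w),
        float(b.mean()) if len(b) else float("nan"), sd(b),
    )
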