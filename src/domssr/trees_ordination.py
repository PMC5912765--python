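"""Neighbor-Joining trees with marker-bootstrap support, and PCoA.

The NJ agglomeration uses the rate-corrected Q criterion with ties broken
on the lexicographically smallest pair of cluster representatives (the
minimum leaf label inside each cluster). Negative branch lengths are kept
as produced (a warning is emitted) so path distances stay additive.
Bootstrap support resamples band columns with replacement and counts leaf
bipartitions. PCoA is the classical Gower double-centering
eigendecomposition; negative eigenvalues are counted and reported, and
percent-explained is taken relative to the sum of positive eigenvalues.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix, pairwise_jaccard_arrays
from .errors import SizeError
from .genotype_io import BinaryGenotypeMatrix


@dataclass
class Tree:
    """Unrooted tree as an undirected adjacency map with branch lengths.

    Leaves are their label strings; internal nodes are opaque ids. Supports,
    when attached, are percentages keyed by canonical bipartition (the leaf
    side not containing the reference leaf = smallest label).
    """

    adj: dict[object, dict[object, float]]
    leaves: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    # -- traversal helpers ------------------------------------------------

    def _side_leaves(self, a, b) -> frozenset:
        """Leaves reachable from ``b`` when the edge (a, b) is removed."""
        seen = {a, b}
        stack = [b]
        out = []
        leafset = self._leafset
        while stack:
            v = stack.pop()
            if v in leafset:
                out.append(v)
            for w in self.adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(out)

    @property
    def _leafset(self) -> set:
        return set(self.leaves)

    def _canonical(self, side: frozenset) -> frozenset:
        ref = min(self.leaves)
        return frozenset(self._leafset - side) if ref in side else side

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial leaf bipartitions (internal edges only)."""
        out = set()
        n = len(self.leaves)
        leafset = self._leafset
        for a in self.adj:
            for b in self.adj[a]:
                if a in leafset or b in leafset:
                    continue  # pendant edges are trivial
                side = self._side_leaves(a, b)
                if 2 <= len(side) <= n - 2:
                    out.add(self._canonical(side))
        return out

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs."""
        n = len(self.leaves)
        vals = np.zeros((n, n))
        pos = {l: i for i, l in enumerate(self.leaves)}
        for leaf in self.leaves:
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                v = stack.pop()
                for w, length in self.adj[v].items():
                    if w not in dist:
                        dist[w] = dist[v] + length
                        stack.append(w)
            for other in self.leaves:
                vals[pos[leaf], pos[other]] = dist[other]
        return DistanceMatrix(labels=list(self.leaves), values=vals)

    def to_newick(self, with_support: bool = False) -> str:
        """Serialize rooted at an arbitrary internal node (or sole edge)."""
        leafset = self._leafset
        root = next((v for v in self.adj if v not in leafset), self.leaves[0])

        def emit(v, parent) -> str:
            children = [w for w in self.adj[v] if w != parent]
            if not children:
                return f"{v}:{self.adj[v][parent]:.6f}"
            inner = ",".join(emit(w, v) for w in children)
            label = ""
            if with_support and parent is not None:
                side = self._side_leaves(parent, v)
                if 2 <= len(side) <= len(self.leaves) - 2:
                    sup = self.supports.get(self._canonical(side))
                    if sup is not None:
                        label = str(int(round(sup)))
            length = f":{self.adj[v][parent]:.6f}" if parent is not None else ""
            return f"({inner}){label}{length}"

        return emit(root, None) + ";"


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Classical Saitou-Nei NJ (Studier-Keppler update)."""
    labels = list(dist.labels)
    n = len(labels)
    if n < 3:
        raise SizeError("NJ needs at least three taxa")
    d = np.array(dist.values, dtype=float)
    nodes: list[object] = list(labels)  # leaf nodes are their labels
    reps: list[str] = list(labels)  # min leaf label per cluster, for ties
    active = list(range(n))
    adj: dict[object, dict[object, float]] = {lab: {} for lab in labels}
    next_id = 0

    def connect(u, v, length):
        adj[u][v] = length
        adj[v][u] = length

    while len(active) > 2:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in zip(*np.where(q <= qmin + 1e-12))
            if i < j
        ]
        _, bi, bj = min(candidates)
        i_glob, j_glob = active[bi], active[bj]
        dij = sub[bi, bj]
        li = 0.5 * dij + (row_sums[bi] - row_sums[bj]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            warnings.warn("negative NJ branch length retained", stacklevel=2)

        new_node = f"__nj{next_id}"
        next_id += 1
        adj[new_node] = {}
        connect(new_node, nodes[i_glob], li)
        connect(new_node, nodes[j_glob], lj)

        new_d = 0.5 * (d[i_glob, active] + d[j_glob, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_d
        d[active, k] = new_d
        d[k, k] = 0.0
        nodes.append(new_node)
        reps.append(min(reps[i_glob], reps[j_glob]))
        active = [a for a in active if a not in (i_glob, j_glob)] + [k]

    a, b = active
    connect(nodes[a], nodes[b], d[a, b])
    return Tree(adj=adj, leaves=labels)


def bootstrap_tree(
    matrix: BinaryGenotypeMatrix, B: int, seed: int | None = None
) -> Tree:
    """NJ tree on the full data with band-bootstrap bipartition supports.

    Replicates whose resampled Jaccard matrix has an undefined pair are
    skipped; more than 10% skipped replicates is a failure.
    """
    if B < 1:
        raise SizeError("need at least one bootstrap replicate")
    d_full, union, _ = pairwise_jaccard_arrays(matrix.values)
    off = ~np.eye(len(d_full), dtype=bool)
    if np.isnan(d_full[off]).any():
        raise SizeError("full-data distance matrix has an undefined pair")
    main = neighbor_joining(
        DistanceMatrix(labels=list(matrix.individuals), values=d_full)
    )

    rng = np.random.default_rng(seed)
    m = matrix.n_bands
    counts: Counter = Counter()
    skipped = 0
    for _ in range(B):
        cols = rng.integers(0, m, size=m)
        d, union, _ = pairwise_jaccard_arrays(matrix.values[:, cols])
        if np.isnan(d[off]).any():
            skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = neighbor_joining(
                DistanceMatrix(labels=list(matrix.individuals), values=d)
            )
        counts.update(rep.bipartitions())
    if skipped > 0.1 * B:
        raise SizeError(f"{skipped}/{B} bootstrap replicates skipped")
    used = B - skipped
    main.supports = {
        bp: 100.0 * counts.get(bp, 0) / used for bp in main.bipartitions()
    }
    return main


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # individuals x retained positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_explained: np.ndarray  # per positive axis, sums to 100
    n_negative: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _cailliez_constant(d: np.ndarray) -> float:
    n = d.shape[0]
    d1 = _gower_center(d)
    # center of -0.5*d (not squared)
    j = np.eye(n) - np.ones((n, n)) / n
    d2 = j @ (-0.5 * d) @ j
    block = np.block(
        [[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]]
    )
    eig = np.linalg.eigvals(block)
    return float(np.max(eig.real))


def pcoa(
    dist: DistanceMatrix, n_axes: int | None = None, correction: str | None = None
) -> PcoaResult:
    """Principal coordinate analysis of a dissimilarity matrix.

    ``correction='cailliez'`` adds the Cailliez constant to off-diagonal
    distances before decomposition; by default negative eigenvalues are
    simply counted and excluded from percent-explained.
    """
    d = np.array(dist.values, dtype=float)
    if correction == "cailliez":
        c = _cailliez_constant(d)
        if c > 0:
            d = d + c
            np.fill_diagonal(d, 0.0)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    b = _gower_center(d)
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * max(abs(eigval.max(initial=0)), 1.0))
    pos = eigval > tol
    n_pos = int(pos.sum())
    n_negative = int(np.count_nonzero(eigval < -tol))
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes]) if n_axes else np.zeros((len(d), 0))
    pos_sum = eigval[pos].sum() if n_pos else 1.0
    percent = 100.0 * eigval[:n_pos] / pos_sum if n_pos else np.array([])
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords,
            index=dist.labels,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        ),
        eigenvalues=eigval,
        percent_explained=percent,
        n_negative=n_negative,
    )
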