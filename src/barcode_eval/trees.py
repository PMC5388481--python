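"""Neighbour-joining trees, bootstrap supports, and species monophyly.

The NJ agglomeration follows the classic recipe: repeatedly join the pair
(i, j) minimising

    Q(i, j) = (m - 2) * d(i, j) - sum_k d(i, k) - sum_k d(j, k)

over the m active clusters, with branch lengths from the standard limb
formulas and the reduced matrix d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2.
On an additive distance matrix this recovers the generating topology and
its path lengths exactly.  Ties in Q are broken by the smallest (row,
column) index pair so results are deterministic; negative limb lengths
are clamped to zero (the raw deficit is logged).

Bootstrap support of an internal edge of the full-data tree is the
percentage of column-resampled replicate trees containing the same
bipartition of tip labels.

Trees are unrooted; bipartitions are stored canonically as the tip-label
side not containing the lexicographically smallest tip, which makes
supports invariant to the arbitrary rooting used for Newick export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .distances import (DistanceMatrix, counts_matrix, distances_from_counts,
                        distance_matrix)
from .errors import InputError, TreeError
from .io import LocusDataset

logger = logging.getLogger(__name__)


class Tree:
    """Unrooted phylogeny over specimen tip labels.

    ``edges`` is a list of (u, v, length) over integer node ids;
    ``leaf_labels`` maps leaf node ids to tip labels; ``supports`` maps
    canonical bipartitions (frozensets of tip labels) to percentages.
    """

    def __init__(self, edges: list[tuple[int, int, float]],
                 leaf_labels: Mapping[int, str],
                 supports: dict[frozenset, float] | None = None):
        self.edges = [(u, v, float(w)) for u, v, w in edges]
        self.leaf_labels = dict(leaf_labels)
        self.supports = dict(supports or {})
        self._adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in self.edges:
            self._adj.setdefault(u, []).append((v, w))
            self._adj.setdefault(v, []).append((u, w))
        if len(self.leaf_labels) != len(set(self.leaf_labels.values())):
            raise TreeError("duplicate tip labels")
        for node, label in self.leaf_labels.items():
            if node in self._adj and len(self._adj[node]) != 1:
                raise TreeError(f"tip {label!r} has degree != 1")
        self._anchor = min(self.leaf_labels.values())

    @property
    def tips(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    @property
    def n_tips(self) -> int:
        return len(self.leaf_labels)

    def canonical(self, side: frozenset) -> frozenset:
        """Canonical form of a bipartition: the side without the anchor tip."""
        if self._anchor in side:
            return frozenset(self.tips) - side
        return side

    def _side_leafsets(self) -> list[tuple[int, int, frozenset]]:
        """For every edge (u, v): tip labels in the component of v."""
        out = []
        for u, v, _ in self.edges:
            seen = {u, v}
            stack = [v]
            labels = set()
            while stack:
                node = stack.pop()
                if node in self.leaf_labels:
                    labels.add(self.leaf_labels[node])
                for nbr, _w in self._adj.get(node, ()):
                    if nbr not in seen:
                        seen.add(nbr)
                        stack.append(nbr)
            out.append((u, v, frozenset(labels)))
        return out

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical bipartitions of the tree's edges.

        Non-trivial bipartitions (both sides ≥ 2 tips) correspond to
        internal edges; trivial ones to pendant edges.
        """
        n = self.n_tips
        out = set()
        for _u, _v, side in self._side_leafsets():
            if include_trivial or 2 <= len(side) <= n - 2:
                out.add(self.canonical(side))
        return out

    def path_length_matrix(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise tip-to-tip path lengths (the tree's additive metric)."""
        ids = list(ids) if ids is not None else self.tips
        node_of = {lbl: node for node, lbl in self.leaf_labels.items()}
        index = {lbl: i for i, lbl in enumerate(ids)}
        out = np.zeros((len(ids), len(ids)))
        for lbl in ids:
            dist = {node_of[lbl]: 0.0}
            stack = [node_of[lbl]]
            while stack:
                node = stack.pop()
                for nbr, w in self._adj.get(node, ()):
                    if nbr not in dist:
                        dist[nbr] = dist[node] + w
                        stack.append(nbr)
            for other in ids:
                out[index[lbl], index[other]] = dist[node_of[other]]
        return out

    # -- Newick -----------------------------------------------------------

    def to_newick(self, include_supports: bool = True,
                  length_fmt: str = "%.10g") -> str:
        """Deterministic Newick string, supports as internal node labels."""
        anchor_node = next(n for n, l in self.leaf_labels.items()
                           if l == self._anchor)
        if not self._adj:
            return f"{self._anchor};"
        root = self._adj[anchor_node][0][0]
        tips_all = frozenset(self.tips)

        def render(node: int, parent: int, length: float) -> tuple[str, frozenset]:
            if node in self.leaf_labels:
                lbl = self.leaf_labels[node]
                return (f"{lbl}:{length_fmt % length}", frozenset([lbl]))
            parts = []
            below: set = set()
            for nbr, w in sorted(self._adj[node], key=lambda t: t[0]):
                if nbr == parent:
                    continue
                txt, side = render(nbr, node, w)
                parts.append((min(side), txt))
                below |= side
            parts.sort()
            inner = ",".join(txt for _k, txt in parts)
            label = ""
            if include_supports:
                sup = self.supports.get(self.canonical(frozenset(below)))
                if sup is not None and len(below) >= 2 and len(tips_all - below) >= 2:
                    label = "%g" % sup
            return (f"({inner}){label}:{length_fmt % length}", frozenset(below))

        parts = []
        for nbr, w in sorted(self._adj[root], key=lambda t: t[0]):
            txt, side = render(nbr, root, w)
            parts.append((min(side), txt))
        parts.sort()
        return "(" + ",".join(txt for _k, txt in parts) + ");"

    def write(self, path: str | Path, include_supports: bool = True) -> None:
        Path(path).write_text(self.to_newick(include_supports) + "\n")


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbour-joining tree from a distance matrix.

    Requires ≥ 3 taxa and no undefined pairs among them (use
    :func:`exclude_undefined` first when the matrix has saturated pairs).
    """
    if dm.undefined_pairs:
        pairs = sorted(tuple(sorted(p)) for p in dm.undefined_pairs)
        raise TreeError(f"undefined distances among taxa: {pairs}")
    n = len(dm.ids)
    if n < 3:
        raise TreeError(f"NJ needs >= 3 taxa, got {n}")
    D = dm.values.astype(float).copy()
    active = list(range(n))            # tree node id of each current cluster
    next_node = n
    edges: list[tuple[int, int, float]] = []
    while len(active) > 2:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))       # row-major argmin = smallest (i, j) tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        for lbl, val in (("first", li), ("second", lj)):
            if val < 0:
                logger.debug("clamping negative NJ branch (%s of join %d): %g",
                             lbl, next_node, val)
        edges.append((next_node, active[i], max(li, 0.0)))
        edges.append((next_node, active[j], max(lj, 0.0)))
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [next_node]
        next_node += 1
    edges.append((active[0], active[1], max(D[0, 1], 0.0)))
    return Tree(edges, {k: dm.ids[k] for k in range(n)})


def exclude_undefined(dm: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Drop the fewest specimens needed to remove all undefined pairs.

    Greedy: repeatedly drop the specimen involved in the most undefined
    pairs.  Returns the reduced matrix and the roster of excluded ids.
    """
    undef = {p for p in dm.undefined_pairs}
    excluded: list[str] = []
    while undef:
        count: dict[str, int] = {}
        for pair in undef:
            for sid in pair:
                count[sid] = count.get(sid, 0) + 1
        worst = max(sorted(count), key=lambda s: count[s])
        excluded.append(worst)
        undef = {p for p in undef if worst not in p}
    if excluded:
        logger.warning("excluding %d specimens with undefined distances: %s",
                       len(excluded), excluded)
        keep = [sid for sid in dm.ids if sid not in set(excluded)]
        return dm.submatrix(keep), excluded
    return dm, []


def bootstrap_supports(dataset: LocusDataset, model: str = "k2p",
                       n_reps: int = 1000,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> Tree:
    """Full-data NJ tree annotated with bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times;
    each replicate tree's bipartitions are counted and the support of an
    internal edge of the full-data tree is 100 × its frequency among
    retained replicates.  Replicates whose resampled matrix contains an
    undefined distance are dropped (a warning is issued above 10%).
    Passing the same seed yields identical supports.
    """
    if n_reps <= 0:
        raise InputError("n_reps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dm = distance_matrix(dataset, model)
    dm, excluded = exclude_undefined(dm)
    tree = nj_tree(dm)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    sub = dataset.matrix.subset(dm.ids)
    codes = sub.codes
    L = codes.shape[1]
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        n_comp, n_ts, n_tv = counts_matrix(codes[:, cols])
        values = distances_from_counts(n_comp, n_ts, n_tv, model)
        if np.isnan(values).any():
            dropped += 1
            continue
        rep_tree = nj_tree(DistanceMatrix(list(dm.ids), model, values))
        for bp in rep_tree.bipartitions() & target:
            counts[bp] += 1
    kept = n_reps - dropped
    if dropped > 0.1 * n_reps:
        logger.warning("dropped %d/%d bootstrap replicates with undefined "
                       "distances", dropped, n_reps)
    if kept == 0:
        raise TreeError("every bootstrap replicate had undefined distances")
    tree.supports = {bp: 100.0 * c / kept for bp, c in counts.items()}
    tree.excluded_specimens = excluded
    tree.bootstrap_dropped = dropped
    tree.bootstrap_kept = kept
    return tree


@dataclass(frozen=True)
class MonophylyResult:
    """Monophyly verdict for one species on one tree.

    ``support`` is the bootstrap percentage of the edge separating the
    species from all other tips; None when the tree carries no supports,
    when the species is a singleton, or when it is not monophyletic.
    Splits whose complement is a single tip occur in every possible tree
    and are reported with support 100.
    """

    species: str
    monophyletic: bool
    support: float | None
    n_tips: int

    def well_supported(self, threshold: float = 70.0) -> bool:
        return bool(self.monophyletic and self.support is not None
                    and self.support > threshold)


def test_monophyly(tree: Tree, species_map: Mapping[str, str],
                   support_threshold: float = 70.0) -> list[MonophylyResult]:
    """Test every species with tips on the tree for monophyly.

    A species with ≥ 2 tips is monophyletic iff some edge's removal
    bipartitions the tips into exactly that species versus the rest;
    singletons are trivially monophyletic with support N/A.
    ``support_threshold`` is carried for report writers that flag
    well-supported species; it does not alter the verdicts.
    """
    del support_threshold  # verdicts are threshold-free; kept for API symmetry
    tips = set(tree.tips)
    unmapped = sorted(t for t in tips if t not in species_map)
    if unmapped:
        raise InputError(f"tips missing from species map: {unmapped}")
    groups: dict[str, set[str]] = {}
    for t in tips:
        groups.setdefault(species_map[t], set()).add(t)
    all_sides = tree.bipartitions(include_trivial=True)
    results = []
    for sp in sorted(groups):
        members = frozenset(groups[sp])
        n = len(members)
        if n == 1:
            results.append(MonophylyResult(sp, True, None, 1))
            continue
        mono = tree.canonical(members) in all_sides
        support: float | None = None
        if mono:
            if len(tips) - n == 1:
                support = 100.0    # complement is one tip: split is universal
            else:
                support = tree.supports.get(tree.canonical(members))
        results.append(MonophylyResult(sp, mono, support, n))
    return results


# -- Newick import -------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a Newick string; internal node labels are read as supports."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)
    return _from_dendropy(dtree)


def read_tree(path: str | Path,
              expected_tips: Sequence[str] | None = None) -> Tree:
    """Read a Newick file (e.g. an externally built ML tree).

    When ``expected_tips`` is given the tree's tip set must match it
    exactly, so monophyly tests run against the same specimen roster.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"tree file not found: {path}")
    tree = parse_newick(path.read_text())
    if expected_tips is not None and set(tree.tips) != set(expected_tips):
        extra = sorted(set(tree.tips) - set(expected_tips))
        missing = sorted(set(expected_tips) - set(tree.tips))
        raise InputError(f"tree/dataset tip mismatch: extra={extra}, "
                         f"missing={missing}")
    return tree


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    dtree.is_rooted = False
    node_ids: dict = {}
    leaf_labels: dict[int, str] = {}
    edges: list[tuple[int, int, float]] = []
    for k, node in enumerate(dtree.preorder_node_iter()):
        node_ids[node] = k
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise InputError("Newick tree has an unlabeled tip")
            leaf_labels[k] = node.taxon.label
    raw_supports: list[tuple[frozenset, float]] = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        w = node.edge.length if node.edge.length is not None else 0.0
        edges.append((node_ids[node.parent_node], node_ids[node], w))
        if not node.is_leaf() and node.label not in (None, ""):
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
            if sup is not None:
                below = frozenset(lf.taxon.label for lf in node.leaf_iter())
                raw_supports.append((below, sup))
    # dendropy keeps a degree-2 root for unrooted newick with two top-level
    # children; collapse it so internal nodes have degree >= 3
    root = next(iter(dtree.preorder_node_iter()))
    root_id = node_ids[root]
    incident = [(u, v, w) for (u, v, w) in edges if root_id in (u, v)]
    if len(incident) == 2 and root_id not in leaf_labels:
        (u1, v1, w1), (u2, v2, w2) = incident
        a = v1 if u1 == root_id else u1
        b = v2 if u2 == root_id else u2
        edges = [e for e in edges if root_id not in (e[0], e[1])]
        edges.append((a, b, w1 + w2))
    tree = Tree(edges, leaf_labels)
    supports = {}
    for below, sup in raw_supports:
        if 2 <= len(below) <= tree.n_tips - 2:
            supports[tree.canonical(below)] = sup
    tree.supports = supports
    return tree
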