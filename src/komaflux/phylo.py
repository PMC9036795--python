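"""Distance-based least-squares phylogeny.

Trees are unrooted with binary internal nodes (degree 3), held on a
networkx graph with branch lengths as edge attributes.  Branch lengths for
a fixed topology are fitted by the Fitch-Margoliash weighted least-squares
criterion

    sum_{i<j} ((d_ij - p_ij) / d_ij)^2

where p_ij is the tree path length between leaves i and j (weights 1/d^2,
the classical power-2 weighting).  Negative branch lengths are forbidden:
the fit is a nonnegative least-squares problem in the edge lengths, which
are linear in the path lengths.

Topology search mirrors the classical distance-tree heuristic: taxa are
added stepwise in a randomized ("jumbled") order, each placed on the
criterion-minimizing branch, followed by nearest-neighbor-interchange
passes until no rearrangement improves the criterion; the best tree over
all jumble rounds is returned.  Deterministic for a fixed jumble seed.
"""

from __future__ import annotations

import io as _io
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import scipy.optimize
from Bio import Phylo as BioPhylo


class PhyloTree:
    """Unrooted tree over named leaves; internal nodes are integers."""

    def __init__(self, graph: nx.Graph, criterion: float | None = None):
        self.g = graph
        self.criterion = criterion

    # -- construction -------------------------------------------------------

    @classmethod
    def star(cls, leaves: list[str]) -> "PhyloTree":
        g = nx.Graph()
        center = 0
        for leaf in leaves:
            g.add_edge(leaf, center, length=0.0)
        return cls(g)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.g.copy(), self.criterion)

    # -- basic queries ------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.g.nodes if isinstance(n, str))

    def _new_internal(self) -> int:
        ints = [n for n in self.g.nodes if isinstance(n, int)]
        return (max(ints) + 1) if ints else 0

    def path_lengths(self, labels: list[str] | None = None) -> pd.DataFrame:
        labels = labels or self.leaves
        n = len(labels)
        P = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            path = nx.shortest_path(self.g, labels[i], labels[j])
            plen = sum(self.g.edges[u, v]["length"]
                       for u, v in zip(path[:-1], path[1:]))
            P[i, j] = P[j, i] = plen
        return pd.DataFrame(P, index=labels, columns=labels)

    # -- topology edits -----------------------------------------------------

    def attach_leaf(self, leaf: str, edge: tuple) -> "PhyloTree":
        """Return a copy with ``leaf`` attached to the middle of ``edge``."""
        t = self.copy()
        u, v = edge
        length = t.g.edges[u, v]["length"]
        w = t._new_internal()
        t.g.remove_edge(u, v)
        t.g.add_edge(u, w, length=length / 2)
        t.g.add_edge(w, v, length=length / 2)
        t.g.add_edge(w, leaf, length=length / 2 if length > 0 else 0.0)
        return t

    def internal_edges(self) -> list[tuple]:
        return [(u, v) for u, v in self.g.edges
                if isinstance(u, int) and isinstance(v, int)]

    def nni_neighbors(self, edge: tuple) -> list["PhyloTree"]:
        """The two nearest-neighbor interchanges across an internal edge."""
        u, v = edge
        u_nb = [x for x in self.g.neighbors(u) if x != v]
        v_nb = [x for x in self.g.neighbors(v) if x != u]
        if len(u_nb) != 2 or len(v_nb) != 2:
            raise ValueError("NNI requires degree-3 endpoints")
        out = []
        b = u_nb[1]
        for c in v_nb:
            t = self.copy()
            lb = t.g.edges[u, b]["length"]
            lc = t.g.edges[v, c]["length"]
            t.g.remove_edge(u, b)
            t.g.remove_edge(v, c)
            t.g.add_edge(u, c, length=lc)
            t.g.add_edge(v, b, length=lb)
            out.append(t)
        return out

    # -- newick -------------------------------------------------------------

    def to_newick(self) -> str:
        root = next((n for n in self.g.nodes if isinstance(n, int)), None)
        if root is None:  # two-leaf degenerate tree
            a, b = self.leaves
            return f"({a}:{self.g.edges[a, b]['length']:.10g},{b}:0);"

        def render(node, parent) -> str:
            children = [x for x in self.g.neighbors(node) if x != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{render(c, node)}:{self.g.edges[node, c]['length']:.10g}"
                for c in children)
            return f"({inner})"

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            bt = BioPhylo.read(_io.StringIO(text), "newick")
        except Exception as exc:
            raise ValueError(f"newick parse error: {exc}") from exc
        g = nx.Graph()
        counter = itertools.count()

        def walk(clade):
            if clade.is_terminal():
                return str(clade.name)
            node = next(counter)
            for child in clade.clades:
                cn = walk(child)
                g.add_edge(node, cn,
                           length=float(child.branch_length or 0.0))
            return node

        root = walk(bt.root)
        # suppress degree-2 internal nodes left by rooted serializations
        for node in [n for n in list(g.nodes)
                     if isinstance(n, int) and g.degree[n] == 2]:
            a, b = list(g.neighbors(node))
            total = g.edges[node, a]["length"] + g.edges[node, b]["length"]
            g.remove_node(node)
            g.add_edge(a, b, length=total)
        del root
        return cls(g)


# ---------------------------------------------------------------------------
# Fitch-Margoliash fitting

def _pair_weights(d: np.ndarray, zero_epsilon: float = 1e-6) -> np.ndarray:
    d_safe = np.where(d <= 0, zero_epsilon, d)
    return 1.0 / d_safe


def evaluate_tree(tree: PhyloTree, D: pd.DataFrame,
                  zero_epsilon: float = 1e-6) -> PhyloTree:
    """Fit nonnegative branch lengths minimizing the FM criterion.

    Returns a copy of the tree with fitted ``length`` attributes and the
    criterion value stored on ``.criterion``.  A zero off-diagonal distance
    would give an infinite weight; its weight is computed with
    ``zero_epsilon`` substituted instead.
    """
    labels = list(D.index)
    if set(labels) != set(tree.leaves):
        raise ValueError("tree leaves do not match distance-matrix labels")
    t = tree.copy()
    edges = list(t.g.edges)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}
    A = np.zeros((len(pairs), len(edges)))
    for p, (i, j) in enumerate(pairs):
        path = nx.shortest_path(t.g, labels[i], labels[j])
        for u, v in zip(path[:-1], path[1:]):
            A[p, edge_index[frozenset((u, v))]] = 1.0
    d = np.array([D.iloc[i, j] for i, j in pairs], dtype=float)
    w = _pair_weights(d, zero_epsilon)
    b, _ = scipy.optimize.nnls(A * w[:, None], d * w)
    for k, (u, v) in enumerate(edges):
        t.g.edges[u, v]["length"] = float(b[k])
    resid = (d - A @ b) * w
    t.criterion = float(resid @ resid)
    return t


def build_tree(D: pd.DataFrame, n_jumbles: int = 10,
               jumble_seed: int = 23893) -> PhyloTree:
    """Least-squares topology search with jumbled stepwise addition + NNI."""
    labels = list(D.index)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(jumble_seed)
    best: PhyloTree | None = None
    for _ in range(max(1, n_jumbles)):
        order = [labels[i] for i in rng.permutation(n)]
        tree = evaluate_tree(PhyloTree.star(order[:3]),
                             D.loc[order[:3], order[:3]])
        for m, taxon in enumerate(order[3:], start=4):
            sub = D.loc[order[:m], order[:m]]
            candidates = [evaluate_tree(tree.attach_leaf(taxon, e), sub)
                          for e in tree.g.edges]
            tree = min(candidates, key=lambda t: t.criterion)
        tree = _nni_search(tree, D)
        if best is None or tree.criterion < best.criterion - 1e-15:
            best = tree
    return best


def _nni_search(tree: PhyloTree, D: pd.DataFrame) -> PhyloTree:
    """Repeated NNI passes until no rearrangement improves the criterion."""
    current = evaluate_tree(tree, D)
    improved = True
    while improved:
        improved = False
        for edge in current.internal_edges():
            for cand in current.nni_neighbors(edge):
                fitted = evaluate_tree(cand, D)
                if fitted.criterion < current.criterion - 1e-12:
                    current = fitted
                    improved = True
                    break
            if improved:
                break
    return current


def enumerate_topologies(labels: list[str]):
    """Yield every unrooted binary topology over the labels (oracle; small n).

    Built by the standard recursive edge-insertion enumeration:
    (2n-5)!! topologies for n leaves.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    base = PhyloTree.star(labels[:3])
    stack = [(base, 3)]
    while stack:
        tree, m = stack.pop()
        if m == len(labels):
            yield tree
            continue
        for edge in list(tree.g.edges):
            stack.append((tree.attach_leaf(labels[m], edge), m + 1))
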