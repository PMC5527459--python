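"""Sector phylogenies by exact binary-character parsimony.

Each tumor sector is a taxon, each validated mutation a binary character,
and the matched normal tissue the all-zero outgroup.  For binary
characters the minimum-changes (Wagner) criterion coincides with Fitch
small parsimony; on polytomies the Hartigan generalization applies.  At
the scale of such studies (five sectors plus an outgroup: 105 unrooted
topologies) an exhaustive search over topologies is exact and instant, so
no heuristic search is needed; a guard refuses more than nine taxa.

Ties are summarized by the strict consensus of all minimum-score
topologies, rooted on the outgroup edge.  Mutations are then placed on the
consensus tree by a deterministic two-pass state reconstruction whose edge
change counts sum to the tree's parsimony score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CharacterMatrix",
    "SectorTree",
    "TreeNode",
    "enumerate_topologies",
    "parsimony_score",
    "best_tree",
    "to_newick",
]

MAX_TAXA = 9


def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


@dataclass
class CharacterMatrix:
    """Taxa-by-characters binary state matrix with a designated outgroup."""

    df: pd.DataFrame  # rows: taxa, cols: characters
    outgroup: str

    def __post_init__(self) -> None:
        if self.outgroup not in self.df.index:
            raise ValueError(f"outgroup {self.outgroup!r} not among taxa")
        vals = self.df.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("character states must be binary")
        if (self.df.loc[self.outgroup] != 0).any():
            raise ValueError("outgroup must carry the ancestral (0) state everywhere")
        if self.df.shape[0] < 3:
            raise ValueError("need >= 3 taxa for a non-degenerate tree")
        self.df = self.df.astype(int)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def characters(self) -> list[str]:
        return list(self.df.columns)


# ----------------------------------------------------------------------
# topology enumeration
#
# An unrooted topology is an adjacency dict: leaves are taxon names,
# internal nodes are negative integers, every internal node has degree 3.


def enumerate_topologies(taxa: list[str] | int) -> list[dict]:
    """All distinct unrooted binary topologies over the given taxa.

    Generated by stepwise addition (each new leaf subdivides every edge of
    every smaller tree), which yields exactly (2n-5)!! distinct trees.
    """
    if isinstance(taxa, int):
        taxa = [f"t{i+1}" for i in range(taxa)]
    n = len(taxa)
    if not 3 <= n <= MAX_TAXA:
        raise ValueError(f"taxon count must lie in [3, {MAX_TAXA}], got {n}")

    first = {taxa[0]: {-1}, taxa[1]: {-1}, taxa[2]: {-1}, -1: {taxa[0], taxa[1], taxa[2]}}
    trees = [first]
    next_internal = -2
    for leaf in taxa[3:]:
        new_trees = []
        for t in trees:
            edges = set()
            for u, nbrs in t.items():
                for v in nbrs:
                    if (v, u) not in edges:
                        edges.add((u, v))
            for u, v in edges:
                nt = {k: set(vs) for k, vs in t.items()}
                w = next_internal
                nt[u].discard(v)
                nt[v].discard(u)
                nt[u].add(w)
                nt[v].add(w)
                nt[w] = {u, v, leaf}
                nt[leaf] = {w}
                new_trees.append(nt)
        trees = new_trees
        next_internal -= 1
    return trees


def _rooted_children(topology: dict, root_leaf) -> tuple[list, dict]:
    """Orient an unrooted topology away from ``root_leaf``.

    Returns a post-order node list and a children mapping for the tree
    rooted at the (single) neighbor of ``root_leaf``; the root leaf itself
    becomes a child of that node.
    """
    start = next(iter(topology[root_leaf]))
    children: dict = {}
    order: list = []
    stack = [(start, root_leaf)]
    while stack:
        node, parent = stack.pop()
        kids = [v for v in topology[node] if v != parent]
        children[node] = kids
        order.append(node)
        for k in kids:
            stack.append((k, node))
    # post-order: reverse of the DFS push order works because children are
    # always pushed after their parent
    order.reverse()
    children[start] = list(topology[start] - {root_leaf}) + [root_leaf]
    children[root_leaf] = []
    if root_leaf not in order:
        order.insert(0, root_leaf)
    return order, children


def _hartigan_counts(
    order: list, children: dict, root, states: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Hartigan bottom-up over all characters at once.

    ``states`` maps each leaf taxon to a 0/1 vector over characters.
    Returns (per-character minimum change counts, root preferred-state
    bitmasks) where mask bit 1 = state 0, bit 2 = state 1, 3 = either.
    """
    n_chars = len(next(iter(states.values())))
    V: dict = {}
    score = np.zeros(n_chars, dtype=np.int64)
    for node in order:
        kids = children[node]
        if not kids:
            s = states[node]
            V[node] = np.where(s == 1, 2, 1).astype(np.int8)
            continue
        k0 = np.zeros(n_chars, dtype=np.int32)
        k1 = np.zeros(n_chars, dtype=np.int32)
        for c in kids:
            k0 += (V[c] & 1) > 0
            k1 += (V[c] & 2) > 0
        K = np.maximum(k0, k1)
        V[node] = ((k0 == K) * 1 + (k1 == K) * 2).astype(np.int8)
        score += len(kids) - K
    return score, V[root]


def _leaf_states(matrix: CharacterMatrix) -> dict[str, np.ndarray]:
    return {t: matrix.df.loc[t].to_numpy(dtype=np.int8) for t in matrix.taxa}


def parsimony_score(topology: dict, matrix: CharacterMatrix) -> tuple[np.ndarray, int]:
    """Minimum state changes per character and in total for one topology."""
    leaves = {k for k in topology if not isinstance(k, int) or k >= 0}
    if leaves != set(matrix.taxa):
        raise ValueError("topology taxa do not match the character matrix")
    order, children = _rooted_children(topology, matrix.taxa[0])
    root = next(iter(topology[matrix.taxa[0]]))
    per_char, _ = _hartigan_counts(order, children, root, _leaf_states(matrix))
    return per_char, int(per_char.sum())


# ----------------------------------------------------------------------
# rooted result tree


@dataclass
class TreeNode:
    name: str | None = None  # taxon name for leaves, None for internal
    children: list["TreeNode"] = field(default_factory=list)
    length: int = 0  # state changes assigned to the edge above this node
    mutations: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SectorTree:
    """Outgroup-rooted parsimony tree with per-edge mutation placements."""

    root: TreeNode
    outgroup: str
    score: int
    n_optimal_topologies: int
    optimal_newicks: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaves())

    def edges(self) -> list[tuple[frozenset, int, list[str]]]:
        """(clade leaf set, length, mutations) for every edge, post-order."""
        out = []

        def rec(node: TreeNode) -> None:
            for c in node.children:
                rec(c)
                out.append((frozenset(c.leaves()), c.length, list(c.mutations)))

        rec(self.root)
        return out

    def trunk(self) -> TreeNode:
        """The tumor-clade child of the root (the edge opposite the outgroup)."""
        for c in self.root.children:
            if not (c.is_leaf and c.name == self.outgroup):
                return c
        raise ValueError("degenerate tree with no tumor clade")


def _splits(topology: dict, taxa: list[str], outgroup: str) -> frozenset:
    """Nontrivial bipartitions, each canonicalized as the outgroup-free side."""
    all_taxa = set(taxa)
    splits = set()
    seen_edges = set()
    for u, nbrs in topology.items():
        for v in nbrs:
            if (v, u) in seen_edges:
                continue
            seen_edges.add((u, v))
            if not (_is_internal(u) and _is_internal(v)):
                continue
            # leaves on v's side of the edge
            side = set()
            stack = [(v, u)]
            while stack:
                node, parent = stack.pop()
                if not _is_internal(node):
                    side.add(node)
                    continue
                for w in topology[node]:
                    if w != parent:
                        stack.append((w, node))
            if outgroup in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                splits.add(frozenset(side))
    return frozenset(splits)


def _is_internal(node) -> bool:
    return isinstance(node, int) and node < 0


def _tree_from_clades(taxa: list[str], outgroup: str, clades: set[frozenset]) -> TreeNode:
    """Rooted tree: root -> (outgroup, tumor clade refined by nested clades)."""
    sectors = [t for t in taxa if t != outgroup]
    top = frozenset(sectors)
    nested = sorted((c for c in clades if c != top), key=len, reverse=True)
    nodes: dict[frozenset, TreeNode] = {top: TreeNode()}
    order: list[frozenset] = [top]
    for c in nested:
        parent = min((p for p in order if c < p), key=len, default=top)
        node = TreeNode()
        nodes[parent].children.append(node)
        nodes[c] = node
        order.append(c)
    for t in sorted(sectors):
        containing = [c for c in order if t in c]
        parent = min(containing, key=len)
        nodes[parent].children.append(TreeNode(name=t))
    root = TreeNode()
    root.children = [TreeNode(name=outgroup), nodes[top]]
    return root


def _place_mutations(root: TreeNode, matrix: CharacterMatrix) -> int:
    """Assign states top-down and record changes on edges; returns total.

    Bottom-up Hartigan preferred-state sets, then a deterministic uppass
    that keeps the parent's state whenever it is among a node's preferred
    states (for binary characters this pins a unique minimal
    reconstruction once the root is fixed at the outgroup state).
    """
    chars = matrix.characters
    n_chars = len(chars)
    states = _leaf_states(matrix)

    # collect nodes and children in post-order over the rooted TreeNode
    order: list[TreeNode] = []

    def rec(n: TreeNode) -> None:
        for c in n.children:
            rec(c)
        order.append(n)

    rec(root)
    V: dict[int, np.ndarray] = {}
    for node in order:
        if node.is_leaf:
            s = states[node.name]
            V[id(node)] = np.where(s == 1, 2, 1).astype(np.int8)
        else:
            k0 = np.zeros(n_chars, dtype=np.int32)
            k1 = np.zeros(n_chars, dtype=np.int32)
            for c in node.children:
                k0 += (V[id(c)] & 1) > 0
                k1 += (V[id(c)] & 2) > 0
            K = np.maximum(k0, k1)
            V[id(node)] = ((k0 == K) * 1 + (k1 == K) * 2).astype(np.int8)

    total = 0
    assigned: dict[int, np.ndarray] = {}
    root_mask = V[id(root)]
    # root prefers the ancestral state (the outgroup is attached here)
    assigned[id(root)] = np.where((root_mask & 1) > 0, 0, 1).astype(np.int8)
    stack = [root]
    while stack:
        node = stack.pop()
        pstate = assigned[id(node)]
        for c in node.children:
            mask = V[id(c)]
            keep = ((mask & (1 << pstate.astype(np.int32))) > 0).astype(bool)
            cstate = np.where(keep, pstate, np.where((mask & 2) > 0, 1, 0)).astype(np.int8)
            changed = cstate != pstate
            c.length = int(changed.sum())
            c.mutations = [chars[i] for i in np.nonzero(changed)[0]]
            assigned[id(c)] = cstate
            total += c.length
            if not c.is_leaf:
                stack.append(c)
    return total


def best_tree(matrix: CharacterMatrix) -> SectorTree:
    """Exhaustive-search maximum-parsimony tree, rooted on the outgroup.

    All minimum-score topologies are found; the reported primary tree is
    their strict consensus (the unique optimum when there are no ties),
    with mutations placed on its edges and edge lengths equal to the
    changes assigned.  The tied optimal topologies are also returned as
    Newick strings.
    """
    taxa = matrix.taxa
    topologies = enumerate_topologies(taxa)
    best = None
    optimal: list[dict] = []
    for topo in topologies:
        _, total = parsimony_score(topo, matrix)
        if best is None or total < best:
            best = total
            optimal = [topo]
        elif total == best:
            optimal.append(topo)

    common = _splits(optimal[0], taxa, matrix.outgroup)
    for topo in optimal[1:]:
        common = common & _splits(topo, taxa, matrix.outgroup)
    root = _tree_from_clades(taxa, matrix.outgroup, set(common))
    score = _place_mutations(root, matrix)
    tree = SectorTree(
        root=root,
        outgroup=matrix.outgroup,
        score=score,
        n_optimal_topologies=len(optimal),
        optimal_newicks=[_unrooted_newick(t, matrix.outgroup) for t in optimal],
    )
    return tree


def _unrooted_newick(topology: dict, outgroup: str) -> str:
    start = next(iter(topology[outgroup]))

    def rec(node, parent) -> str:
        if not _is_internal(node):
            return str(node)
        kids = sorted(
            (rec(v, node) for v in topology[node] if v != parent),
        )
        return "(" + ",".join(kids) + ")"

    kids = sorted(rec(v, start) for v in topology[start] if v != outgroup)
    return "(" + outgroup + "," + ",".join(kids) + ");"


def to_newick(tree: SectorTree) -> str:
    """Newick with integer branch lengths (= assigned state changes)."""

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length}"
        inner = ",".join(rec(c) for c in sorted(node.children, key=_sort_key))
        return f"({inner}):{node.length}"

    inner = ",".join(rec(c) for c in sorted(tree.root.children, key=_sort_key))
    return f"({inner});"


def _sort_key(node: TreeNode):
    return sorted(node.leaves())


def presence_to_character_matrix(
    presence: pd.DataFrame, outgroup: str = "N"
) -> CharacterMatrix:
    """Sector presence matrix (mutations x sectors) -> taxa-by-character matrix."""
    df = presence.T.copy()
    df.loc[outgroup] = 0
    return CharacterMatrix(df, outgroup)
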