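"""Tree containers and Newick I/O.

Three containers back the whole package:

* :class:`SpeciesTree` -- a rooted binary tree with uniquely labeled leaves,
  equipped with constant-time lca queries (Euler tour + sparse table), depths
  and the ancestor partial order.
* :class:`RootedGeneTree` -- a rooted binary tree whose leaves carry species
  names (repeats allowed).
* :class:`UnrootedGeneTree` -- an undirected tree with nodes of degree 1
  (leaves) or 3 (internal); every edge is a potential root position.

Newick parsing is delegated to dendropy; the containers use dense integer
node ids in Newick reading (preorder) order, which also fixes every
deterministic tie-break downstream.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "TreeFormatError",
    "LabelError",
    "InvariantError",
    "LabelMapRule",
    "SpeciesTree",
    "RootedGeneTree",
    "UnrootedGeneTree",
    "parse_species_newick",
    "parse_rooted_gene_newick",
    "parse_gene_newick",
    "write_newick",
    "read_gene_tree_lines",
]


class TreeFormatError(ValueError):
    """Input tree violates a structural requirement (non-binary, too small...)."""


class LabelError(ValueError):
    """A gene leaf label cannot be resolved to a species-tree leaf."""


class InvariantError(RuntimeError):
    """An internal consistency check failed; indicates a bug, not bad input."""


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,='\"]")


def _quote_label(label: str) -> str:
    if label and not _QUOTE_NEEDED.search(label):
        return label
    return "'" + label.replace("'", "''") + "'"


@dataclass(frozen=True)
class LabelMapRule:
    """Rule mapping gene-tree leaf labels to species names.

    ``identity`` uses the label as-is; ``prefix`` keeps the part of the label
    before the first occurrence of ``separator`` (e.g. ``HUMAN_gene42`` ->
    ``HUMAN`` with separator ``_``).
    """

    mode: str = "identity"
    separator: str = "_"

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "prefix"):
            raise ValueError(f"unknown label rule mode: {self.mode!r}")

    def apply(self, label: str) -> str:
        if self.mode == "identity":
            return label
        return label.split(self.separator, 1)[0]

    @classmethod
    def from_string(cls, text: str) -> "LabelMapRule":
        if text == "identity":
            return cls("identity")
        if text.startswith("prefix:") and len(text) > len("prefix:"):
            return cls("prefix", text.split(":", 1)[1])
        raise ValueError(f"cannot parse label rule {text!r}; "
                         "expected 'identity' or 'prefix:<sep>'")


IDENTITY_RULE = LabelMapRule("identity")


def _parse_dendropy(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeFormatError(f"cannot parse Newick input: {exc}") from exc


class _RootedArrays:
    """Shared array-based rooted-tree plumbing (ids in preorder)."""

    def __init__(self, parent, children, labels):
        self.parent = parent          # list[int | None], parent[root] is None
        self.children = children      # list[tuple[int, ...]], () for leaves
        self.labels = labels          # list[str | None], species name at leaves
        self.root = 0
        self.n_nodes = len(parent)
        self.depth = [0] * self.n_nodes
        order = [self.root]
        for v in order:
            for c in self.children[v]:
                self.depth[c] = self.depth[v] + 1
                order.append(c)
        self.preorder = order
        self.postorder = list(reversed(order))

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaves(self):
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_labels(self):
        return [self.labels[v] for v in self.leaves]

    def _newick_of(self, v: int) -> str:
        if not self.children[v]:
            return _quote_label(self.labels[v])
        return "(" + ",".join(self._newick_of(c) for c in self.children[v]) + ")"

    def newick(self) -> str:
        if self.n_nodes == 0:
            raise TreeFormatError("cannot serialize an empty tree")
        return self._newick_of(self.root) + ";"


def _arrays_from_dendropy(tree: dendropy.Tree):
    """Flatten a dendropy tree into (parent, children, labels) preorder arrays."""
    parent, children, labels = [], [], []
    index = {}
    for node in tree.preorder_node_iter():
        idx = len(parent)
        index[node] = idx
        parent.append(None if node.parent_node is None else index[node.parent_node])
        children.append(())
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise TreeFormatError("leaf without a label")
            labels.append(label)
        else:
            labels.append(None)
    for node in tree.preorder_node_iter():
        kids = tuple(index[c] for c in node.child_nodes())
        children[index[node]] = kids
    return parent, children, labels


class SpeciesTree(_RootedArrays):
    """Rooted binary species tree with uniquely labeled leaves.

    Supplies the ancestor order (``is_ancestor``), lca queries, node depths
    (root depth 0) and path edge-counts used by every reconciliation cost.
    """

    def __init__(self, parent, children, labels):
        super().__init__(parent, children, labels)
        for v in range(self.n_nodes):
            k = len(self.children[v])
            if k not in (0, 2):
                raise TreeFormatError(
                    f"species tree must be binary; node over leaves "
                    f"{sorted(self.clade_leaf_labels(v))} has {k} children")
        if self.n_leaves < 2:
            raise TreeFormatError("species tree must have at least 2 leaves")
        seen = {}
        for v in self.leaves:
            if self.labels[v] in seen:
                raise LabelError(f"duplicate species label {self.labels[v]!r}")
            seen[self.labels[v]] = v
        self.leaf_index = seen
        self._build_lca()
        # postorder index, used as the canonical species-node order
        self.postorder_index = [0] * self.n_nodes
        for i, v in enumerate(self.postorder):
            self.postorder_index[v] = i

    # -- lca machinery: Euler tour + sparse table ---------------------------
    def _build_lca(self) -> None:
        euler, first = [], [-1] * self.n_nodes
        stack = [(self.root, iter(self.children[self.root]))]
        euler.append(self.root)
        first[self.root] = 0
        while stack:
            v, it = stack[-1]
            c = next(it, None)
            if c is None:
                stack.pop()
                if stack:
                    euler.append(stack[-1][0])
                continue
            euler.append(c)
            if first[c] < 0:
                first[c] = len(euler) - 1
            stack.append((c, iter(self.children[c])))
        self._euler = np.asarray(euler, dtype=np.int32)
        self._first = np.asarray(first, dtype=np.int32)
        d = np.asarray([self.depth[v] for v in euler], dtype=np.int32)
        m = len(euler)
        levels = max(1, m.bit_length())
        table = np.empty((levels, m), dtype=np.int32)
        table[0] = np.arange(m)
        for j in range(1, levels):
            span = 1 << j
            prev = table[j - 1]
            n = m - span + 1
            if n <= 0:
                table[j] = table[j - 1]
                continue
            left = prev[:n]
            right = prev[(span >> 1): (span >> 1) + n]
            take_right = d[right] < d[left]
            table[j, :n] = np.where(take_right, right, left)
            table[j, n:] = prev[n:]
        self._sparse = table
        self._euler_depth = d

    def lca(self, a: int, b: int) -> int:
        i, j = int(self._first[a]), int(self._first[b])
        if i > j:
            i, j = j, i
        span = j - i + 1
        k = span.bit_length() - 1
        x = int(self._sparse[k, i])
        y = int(self._sparse[k, j - (1 << k) + 1])
        if self._euler_depth[y] < self._euler_depth[x]:
            x = y
        return int(self._euler[x])

    def lca_many(self, nodes) -> int:
        it = iter(nodes)
        try:
            acc = next(it)
        except StopIteration:
            raise ValueError("lca of an empty node set is undefined")
        for v in it:
            acc = self.lca(acc, v)
        return acc

    # -- ancestor order -----------------------------------------------------
    def is_ancestor(self, anc: int, desc: int) -> bool:
        """True iff ``desc`` ≼ ``anc`` (``anc`` on the path from desc to root)."""
        return self.lca(anc, desc) == anc

    def path_edges(self, a: int, b: int) -> int:
        """Number of edges on the path connecting a and b (‖a,b‖)."""
        return self.depth[a] + self.depth[b] - 2 * self.depth[self.lca(a, b)]

    def child_toward(self, anc: int, desc: int) -> int:
        """The child of ``anc`` on the path toward strict descendant ``desc``."""
        if anc == desc or not self.is_ancestor(anc, desc):
            raise ValueError("child_toward requires a strict descendant")
        v = desc
        while self.parent[v] != anc:
            v = self.parent[v]
        return v

    def path_up(self, bottom: int, top: int):
        """Species nodes on the path bottom..top inclusive (bottom first)."""
        if not self.is_ancestor(top, bottom):
            raise ValueError("path_up requires bottom ≼ top")
        out, v = [bottom], bottom
        while v != top:
            v = self.parent[v]
            out.append(v)
        return out

    def clade_leaf_labels(self, v: int):
        """Sorted leaf labels below (and including) node v."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.children[u]:
                stack.extend(self.children[u])
            else:
                out.append(self.labels[u])
        return sorted(out)

    def leaf(self, label: str) -> int:
        try:
            return self.leaf_index[label]
        except KeyError:
            raise LabelError(f"species {label!r} not in species tree") from None


class RootedGeneTree(_RootedArrays):
    """Rooted binary gene tree; leaf labels are species names, repeats allowed.

    ``source_nodes`` (optional) maps each node back to the node of the
    unrooted gene tree it came from (None for a root created by rooting an
    edge); it lets episode/candidate machinery talk about unrooted nodes.
    """

    def __init__(self, parent, children, labels, source_nodes=None):
        super().__init__(parent, children, labels)
        for v in range(self.n_nodes):
            if len(self.children[v]) not in (0, 2):
                raise TreeFormatError("gene tree must be binary")
        if self.n_leaves < 2:
            raise TreeFormatError("gene tree must have at least 2 leaves")
        self.source_nodes = source_nodes

    def species(self):
        return sorted(set(self.leaf_labels()))


class UnrootedGeneTree:
    """Unrooted gene tree: undirected, nodes of degree 1 (leaves) or 3.

    Edges are stored as ``(u, v)`` tuples with ``u < v`` in a deterministic
    construction order; each edge is a potential root position.
    """

    def __init__(self, adjacency, labels):
        self.adj = [tuple(nbrs) for nbrs in adjacency]  # neighbor lists
        self.labels = list(labels)                      # str at leaves else None
        self.n_nodes = len(self.adj)
        edges, seen = [], set()
        for v in range(self.n_nodes):
            deg = len(self.adj[v])
            if deg not in (1, 3):
                raise TreeFormatError(
                    f"unrooted gene tree node has degree {deg}; must be 1 or 3")
            if deg == 1 and self.labels[v] is None:
                raise TreeFormatError("leaf without a label")
            for w in self.adj[v]:
                e = (v, w) if v < w else (w, v)
                if e not in seen:
                    seen.add(e)
                    edges.append(e)
        self.edges = edges
        if len(edges) != self.n_nodes - 1:
            raise TreeFormatError("unrooted gene tree must be a tree "
                                  "(edge count = node count - 1)")
        if sum(1 for v in range(self.n_nodes) if len(self.adj[v]) == 1) < 3:
            raise TreeFormatError("unrooted gene tree needs at least 3 leaves")

    @property
    def leaves(self):
        return [v for v in range(self.n_nodes) if len(self.adj[v]) == 1]

    @property
    def internal_nodes(self):
        return [v for v in range(self.n_nodes) if len(self.adj[v]) == 3]

    def species(self):
        return sorted({self.labels[v] for v in self.leaves})

    def edge(self, u: int, v: int):
        e = (u, v) if u < v else (v, u)
        if e not in set(self.edges):
            raise KeyError(f"{e} is not an edge of this gene tree")
        return e

    def side_nodes(self, e, endpoint: int):
        """Nodes of the component containing ``endpoint`` when e is cut."""
        u, v = e
        if endpoint not in (u, v):
            raise ValueError("endpoint must belong to the edge")
        other = v if endpoint == u else u
        comp, stack = {endpoint}, [endpoint]
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y != other or x != endpoint:
                    if y not in comp:
                        comp.add(y)
                        stack.append(y)
        # the guard above only blocks crossing e itself
        return comp

    def side_leaf_labels(self, e, endpoint: int):
        comp = self.side_nodes(e, endpoint)
        return sorted(self.labels[v] for v in comp if len(self.adj[v]) == 1)

    def bipartition(self, e) -> str:
        """Edge serialized as the sorted leaf-label bipartition ``a,b|c,d``."""
        u, v = e
        a = ",".join(self.side_leaf_labels(e, u))
        b = ",".join(self.side_leaf_labels(e, v))
        return "|".join(sorted((a, b)))

    def edge_by_bipartition(self, text: str):
        for e in self.edges:
            if self.bipartition(e) == text:
                return e
        raise KeyError(f"no edge with bipartition {text!r}")

    # -- rooting ------------------------------------------------------------
    def root_at_edge(self, e) -> RootedGeneTree:
        """Rooting G_e: subdivide edge e with a new degree-2 root."""
        u, v = self.edge(*e)
        parent = [None]
        children = [()]
        labels = [None]
        source = [None]
        index = {}

        def build(node: int, came_from: int, par: int) -> int:
            idx = len(parent)
            parent.append(par)
            children.append(())
            labels.append(self.labels[node])
            source.append(node)
            index[node] = idx
            kids = [w for w in self.adj[node] if w != came_from]
            children[idx] = tuple(build(w, node, idx) for w in kids)
            return idx

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * self.n_nodes + 100))
        try:
            left = build(u, v, 0)
            right = build(v, u, 0)
        finally:
            sys.setrecursionlimit(old)
        children[0] = (left, right)
        return RootedGeneTree(parent, children, labels, source_nodes=source)

    def newick(self) -> str:
        """Serialize with a trifurcation at the first internal node."""
        center = self.internal_nodes[0]

        def sub(node: int, came_from: int) -> str:
            if len(self.adj[node]) == 1:
                return _quote_label(self.labels[node])
            parts = [sub(w, node) for w in self.adj[node] if w != came_from]
            return "(" + ",".join(parts) + ")"

        parts = [sub(w, center) for w in self.adj[center]]
        return "(" + ",".join(parts) + ");"


# ---------------------------------------------------------------------------
# parsing entry points
# ---------------------------------------------------------------------------

def parse_species_newick(text: str) -> SpeciesTree:
    """Parse a single Newick string into a :class:`SpeciesTree`.

    Branch lengths and internal labels are accepted and discarded; a
    non-binary internal node or duplicate leaf label is an error.
    """
    tree = _parse_dendropy(text)
    parent, children, labels = _arrays_from_dendropy(tree)
    return SpeciesTree(parent, children, labels)


def parse_rooted_gene_newick(text: str, rule: LabelMapRule = IDENTITY_RULE) -> RootedGeneTree:
    """Parse a rooted binary gene tree, rewriting leaf labels via ``rule``."""
    tree = _parse_dendropy(text)
    parent, children, labels = _arrays_from_dendropy(tree)
    labels = [rule.apply(x) if x is not None else None for x in labels]
    return RootedGeneTree(parent, children, labels)


def parse_gene_newick(text: str, rule: LabelMapRule = IDENTITY_RULE) -> UnrootedGeneTree:
    """Parse a gene tree as unrooted.

    A rooted binary input (two children at the top) is unrooted by
    suppressing the degree-2 root; an input with a top-level trifurcation is
    taken as-is. Leaf labels are rewritten via ``rule``.
    """
    tree = _parse_dendropy(text)
    parent, children, labels = _arrays_from_dendropy(tree)
    labels = [rule.apply(x) if x is not None else None for x in labels]
    n = len(parent)
    top_kids = children[0]
    adj = [[] for _ in range(n)]
    for v in range(1, n):
        adj[parent[v]].append(v)
        adj[v].append(parent[v])
    if len(top_kids) == 2:
        if sum(1 for x in labels if x is not None) < 3:
            raise TreeFormatError("an unrooted gene tree needs at least 3 leaves")
        a, b = top_kids
        adj[a] = [x for x in adj[a] if x != 0] + [b]
        adj[b] = [b_n for b_n in adj[b] if b_n != 0]
        adj[b].insert(0, a)
        keep = list(range(1, n))
    elif len(top_kids) == 3:
        keep = list(range(n))
    else:
        raise TreeFormatError(
            f"gene tree top node has {len(top_kids)} children; expected a "
            "rooted binary tree or a single top-level trifurcation")
    remap = {old: new for new, old in enumerate(keep)}
    adjacency = [[remap[w] for w in adj[old]] for old in keep]
    new_labels = [labels[old] for old in keep]
    return UnrootedGeneTree(adjacency, new_labels)


def unroot(tree: RootedGeneTree) -> UnrootedGeneTree:
    """Suppress the root of a rooted binary gene tree."""
    return parse_gene_newick(tree.newick())


def write_newick(tree) -> str:
    """Serialize a tree container back to Newick."""
    return tree.newick()


def validate_labels(gene_tree, S: SpeciesTree) -> None:
    """Check ℒ(gene tree) ⊆ ℒ(species tree); raise LabelError listing offenders."""
    if isinstance(gene_tree, UnrootedGeneTree):
        labels = {gene_tree.labels[v] for v in gene_tree.leaves}
    else:
        labels = set(gene_tree.leaf_labels())
    missing = sorted(labels - set(S.leaf_index))
    if missing:
        raise LabelError(f"gene leaf labels not in species tree: {missing}")


def read_gene_tree_lines(text: str):
    """Yield Newick strings from a collection file: one tree per line,
    blank lines and '#' comments skipped."""
    for line in io.StringIO(text):
        line = line.strip()
        if line and not line.startswith("#"):
            yield line
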