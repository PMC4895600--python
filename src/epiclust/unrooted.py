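"""All-rootings analysis of an unrooted gene tree against a species tree.

For an unrooted gene tree G every edge e is a potential root position; the
rooting G_e induces duplication (D) and duplication-loss (DL) costs. The
machinery here computes, in one pass, the lca-image of the subtree hanging
on each side of every edge, classifies edges as *empty* / *single* /
*double* with respect to the top species node ⊤, classifies the star around
each internal node (S1..S5), computes the per-edge cost profiles, extracts
the D- and DL-plateaus (the connected sets of cost-minimal edges), and
locates an empty or double edge by greedy descent without scanning all
rootings.

⊤ is taken as the lca in S of all species appearing in G. For gene trees
spanning the whole species set this is root(S); for non-spanning trees the
convention keeps every definition well-formed (every rooting's root maps to
⊤ either way).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import reconcile
from .trees import InvariantError, SpeciesTree, UnrootedGeneTree, validate_labels

__all__ = [
    "top_node",
    "directed_edge_maps",
    "EdgeClasses",
    "classify_edges",
    "classify_stars",
    "rooting_cost_profile",
    "naive_cost_profile",
    "Plateau",
    "plateau",
    "find_opt_edge",
]

EMPTY = "empty"
SINGLE = "single"
DOUBLE = "double"


def top_node(G: UnrootedGeneTree, S: SpeciesTree) -> int:
    """⊤ for G: the lca in S of all species present in G."""
    return S.lca_many(S.leaf(G.labels[v]) for v in G.leaves)


def directed_edge_maps(G: UnrootedGeneTree, S: SpeciesTree):
    """Map (v, w) -> lca-image of the subtree on the w side of edge {v, w}.

    All 2·|E| directed images are computed with an inward (leaf-to-center)
    pass followed by an outward pass, O(|G|) lca operations total.
    """
    validate_labels(G, S)
    root = G.internal_nodes[0]
    # orient away from `root`
    parent = {root: None}
    order = [root]
    for v in order:
        for w in G.adj[v]:
            if w != parent[v]:
                parent[w] = v
                order.append(w)
    img = {}
    for w in reversed(order):          # inward pass: images toward the leaves
        p = parent[w]
        if p is None:
            continue
        if len(G.adj[w]) == 1:
            img[(p, w)] = S.leaf(G.labels[w])
        else:
            x, y = [u for u in G.adj[w] if u != p]
            img[(p, w)] = S.lca(img[(w, x)], img[(w, y)])
    for w in order:                    # outward pass: images toward the center
        p = parent[w]
        if p is None:
            continue
        acc = None
        for u in G.adj[p]:
            if u == w:
                continue
            # img[(p, u)] exists: inward pass for child directions, and the
            # outward pass already handled p itself for the parent direction
            m = img[(p, u)]
            acc = m if acc is None else S.lca(acc, m)
        img[(w, p)] = acc
    return img


@dataclass
class EdgeClasses:
    """Per-edge class and, for singles, the incoming endpoint.

    Edge {v, w} is *empty* when both side-images differ from ⊤, *double*
    when both equal ⊤, otherwise *single*; a single edge is v-incoming when
    the component containing v misses ⊤.
    """

    top: int
    classes: dict = field(default_factory=dict)     # edge -> class
    incoming: dict = field(default_factory=dict)    # edge -> incoming endpoint
    maps: dict = field(default_factory=dict)        # directed edge maps

    def empty_edges(self):
        return [e for e in self.classes if self.classes[e] == EMPTY]

    def double_edges(self):
        return [e for e in self.classes if self.classes[e] == DOUBLE]


def classify_edges(G: UnrootedGeneTree, S: SpeciesTree, maps=None) -> EdgeClasses:
    if maps is None:
        maps = directed_edge_maps(G, S)
    top = top_node(G, S)
    ec = EdgeClasses(top=top, maps=maps)
    for e in G.edges:
        v, w = e
        side_v = maps[(w, v)]      # image of the component containing v
        side_w = maps[(v, w)]
        if side_v != top and side_w != top:
            ec.classes[e] = EMPTY
        elif side_v == top and side_w == top:
            ec.classes[e] = DOUBLE
        else:
            ec.classes[e] = SINGLE
            ec.incoming[e] = v if side_v != top else w
    return ec


_STAR_TABLE = {
    # (n_incoming_at_center, n_outgoing_at_center, n_empty, n_double): type
    (1, 2, 0, 0): "S1",
    (0, 2, 1, 0): "S2",
    (0, 2, 0, 1): "S3",
    (0, 0, 0, 3): "S4",
    (0, 1, 0, 2): "S5",
}


def classify_stars(G: UnrootedGeneTree, S: SpeciesTree, ec: EdgeClasses | None = None):
    """Type (S1..S5) of the star around each internal node."""
    if ec is None:
        ec = classify_edges(G, S)
    stars = {}
    for v in G.internal_nodes:
        n_in = n_out = n_empty = n_double = 0
        for w in G.adj[v]:
            e = (v, w) if v < w else (w, v)
            cls = ec.classes[e]
            if cls == EMPTY:
                n_empty += 1
            elif cls == DOUBLE:
                n_double += 1
            elif ec.incoming[e] == v:
                n_in += 1
            else:
                n_out += 1
        key = (n_in, n_out, n_empty, n_double)
        if key not in _STAR_TABLE:
            raise InvariantError(
                f"impossible star at node {v}: incoming={n_in} outgoing={n_out} "
                f"empty={n_empty} double={n_double}")
        stars[v] = _STAR_TABLE[key]
    return stars


def naive_cost_profile(G: UnrootedGeneTree, S: SpeciesTree, kind: str = "D"):
    """Oracle profile: root at every edge and reconcile from scratch."""
    cost = reconcile.dup_cost if kind == "D" else reconcile.dl_cost
    return {e: cost(G.root_at_edge(e), S) for e in G.edges}


def _dup_status(G, S, img, u, p) -> bool:
    """Is internal node u a duplication when its parent direction is p?"""
    m = img[(p, u)]
    return any(m == img[(u, c)] for c in G.adj[u] if c != p)


def _root_dup(S, img, e) -> bool:
    v, w = e
    mv, mw = img[(w, v)], img[(v, w)]
    return S.lca(mv, mw) in (mv, mw)


def rooting_cost_profile(G: UnrootedGeneTree, S: SpeciesTree, kind: str = "D"):
    """Per-edge rooting cost, edge -> D(G_e, S) (or DL).

    The D profile is computed incrementally: the base edge is costed in full
    and moving the root across an adjacent edge changes only the status of
    the shared node and of the root. The DL profile re-roots per edge.
    Either way the value at e equals ``dup_cost(root_at_edge(e), S)``
    (respectively ``dl_cost``).
    """
    if kind == "DL":
        return naive_cost_profile(G, S, "DL")
    if kind != "D":
        raise ValueError(f"unknown cost kind {kind!r}")
    img = directed_edge_maps(G, S)
    e0 = G.edges[0]
    v0, w0 = e0
    # full cost at the base edge
    base = int(_root_dup(S, img, e0))
    parent = {v0: w0, w0: v0}
    order = [v0, w0]
    for x in order:
        for y in G.adj[x]:
            if y != parent[x]:
                parent[y] = x
                order.append(y)
    for u in G.internal_nodes:
        base += _dup_status(G, S, img, u, parent[u])
    profile = {e0: base}
    stack = [e0]
    while stack:
        e = stack.pop()
        v, w = e
        for shared, other_end in ((w, v), (v, w)):
            if len(G.adj[shared]) == 1:
                continue
            for x in G.adj[shared]:
                if x == other_end:
                    continue
                e2 = (shared, x) if shared < x else (x, shared)
                if e2 in profile:
                    continue
                profile[e2] = (profile[e]
                               - int(_root_dup(S, img, e))
                               - int(_dup_status(G, S, img, shared, other_end))
                               + int(_dup_status(G, S, img, shared, x))
                               + int(_root_dup(S, img, e2)))
                stack.append(e2)
    return profile


@dataclass(frozen=True)
class Plateau:
    """Minimal-cost rooting edges of one cost kind; always a connected subtree."""

    kind: str
    cost: int
    edges: tuple

    def __contains__(self, e) -> bool:
        return e in self.edges

    def __len__(self) -> int:
        return len(self.edges)


def plateau(G: UnrootedGeneTree, S: SpeciesTree, kind: str = "D",
            profile=None) -> Plateau:
    """Extract the set of cost-minimal edges and verify it is connected."""
    if profile is None:
        profile = rooting_cost_profile(G, S, kind)
    best = min(profile.values())
    edges = tuple(e for e in G.edges if profile[e] == best)
    nodes = {x for e in edges for x in e}
    seen, stack = {next(iter(nodes))}, [next(iter(nodes))]
    edge_set = set(edges)
    while stack:
        x = stack.pop()
        for y in G.adj[x]:
            e = (x, y) if x < y else (y, x)
            if e in edge_set and y not in seen:
                seen.add(y)
                stack.append(y)
    if seen != nodes:
        raise InvariantError(f"{kind}-plateau is not connected")
    return Plateau(kind=kind, cost=best, edges=edges)


def find_opt_edge(G: UnrootedGeneTree, S: SpeciesTree):
    """Locate an empty edge if one exists, else a double edge, by greedy descent.

    Starting from an arbitrary internal node, an S1 star always points
    across its incoming edge toward the region of the tree mapping to ⊤;
    following those arrows reaches a node incident to an empty or double
    edge. One of the two always exists, and the walk visits each node at
    most once.
    """
    ec = classify_edges(G, S)
    v = G.internal_nodes[0]
    visited = set()
    while True:
        if v in visited:
            raise InvariantError("greedy descent revisited a node")
        visited.add(v)
        walk = None
        for w in G.adj[v]:
            e = (v, w) if v < w else (w, v)
            cls = ec.classes[e]
            if cls in (EMPTY, DOUBLE):
                return e
            if ec.incoming[e] == v:
                walk = w               # ⊤-mass lies beyond w (S1 star)
        if walk is None:
            raise InvariantError("greedy descent stuck at an all-outgoing star")
        v = walk
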