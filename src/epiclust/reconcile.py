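"""Rooted gene tree / species tree reconciliation under the duplication-loss model.

The lca-mapping M sends each gene-tree node to the least common ancestor of
the species below it. An internal gene node g with children a, b is a
*duplication* when M(g) = M(a) or M(g) = M(b); all other internal nodes are
*speciations*. Costs:

* D(T,S)  -- number of duplications,
* L(T,S)  = 2 D(T,S) + Σ_g (‖M(a),M(b)‖ − 2)  over internal g with children
  a, b, where ‖x,y‖ is the edge count of the path between x and y in S,
* DL(T,S) = D(T,S) + L(T,S).
"""

from __future__ import annotations

from .trees import RootedGeneTree, SpeciesTree, validate_labels

__all__ = [
    "DUPLICATION",
    "SPECIATION",
    "lca_map",
    "classify_events",
    "dup_cost",
    "loss_cost",
    "dl_cost",
]

DUPLICATION = "duplication"
SPECIATION = "speciation"


def lca_map(T: RootedGeneTree, S: SpeciesTree):
    """Lca-mapping M: gene node -> species node, as a list indexed by node id."""
    validate_labels(T, S)
    M = [None] * T.n_nodes
    for v in T.postorder:
        if T.is_leaf(v):
            M[v] = S.leaf(T.labels[v])
        else:
            a, b = T.children[v]
            M[v] = S.lca(M[a], M[b])
    return M


def classify_events(T: RootedGeneTree, S: SpeciesTree, M=None):
    """Label every internal node duplication/speciation; leaves get None."""
    if M is None:
        M = lca_map(T, S)
    events = [None] * T.n_nodes
    for v in range(T.n_nodes):
        if not T.is_leaf(v):
            a, b = T.children[v]
            events[v] = DUPLICATION if M[v] in (M[a], M[b]) else SPECIATION
    return events


def dup_cost(T: RootedGeneTree, S: SpeciesTree, M=None) -> int:
    """D(T,S): the total number of duplication nodes."""
    events = classify_events(T, S, M)
    return sum(1 for e in events if e == DUPLICATION)


def loss_cost(T: RootedGeneTree, S: SpeciesTree, M=None) -> int:
    """L(T,S) = 2 D + Σ (‖M(a),M(b)‖ − 2) over internal nodes."""
    if M is None:
        M = lca_map(T, S)
    d = dup_cost(T, S, M)
    total = 2 * d
    for v in range(T.n_nodes):
        if not T.is_leaf(v):
            a, b = T.children[v]
            total += S.path_edges(M[a], M[b]) - 2
    return total


def dl_cost(T: RootedGeneTree, S: SpeciesTree, M=None) -> int:
    """DL(T,S) = D(T,S) + L(T,S)."""
    if M is None:
        M = lca_map(T, S)
    return dup_cost(T, S, M) + loss_cost(T, S, M)
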