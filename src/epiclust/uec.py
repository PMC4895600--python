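"""Unrooted episode clustering: rooting whole collections of unrooted gene trees.

Rootings are restricted to each tree's D-plateau (anything else inflates the
duplication count). The search space is then shrunk in two steps:

* *Candidate pool.* A tree with a double edge contributes one canonical
  plateau edge (all its plateau rootings are interchangeable); a tree with
  an empty edge e* contributes e* plus the plateau edges of the at-most-two
  S2 stars flanking it — never more than five edges in total.
* *Interval dominance.* A tree's contribution to any joint clustering is
  fully determined by the multiset of its duplication intervals (the
  root-directed species paths its duplications may map into), so a rooting
  whose every interval contains some interval of a competitor can never
  beat that competitor and is discarded. Dominance is evaluated separately
  under the two exhaustive scenarios — the final clustering does or does
  not place an episode at root(S) — which keeps the with-root candidate
  lists at one edge for most trees.

A tree is *ambiguous* when two or more with-root candidates survive; with k
ambiguous trees the exact solver evaluates at most 2^k rooted instances
plus the without-root branch (a single all-empty-rootings instance for
species-spanning inputs). The heuristic solves the unique-candidate
subcollection first and certifies optimality when the full collection can
be rooted at the same cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from . import episodes, reconcile, unrooted
from .trees import InvariantError, SpeciesTree, UnrootedGeneTree

__all__ = [
    "CandidateSet",
    "candidate_rootings",
    "count_k",
    "UECResult",
    "EnumerationCapError",
    "uec_exact",
    "uec_heuristic",
    "uec_brute",
    "single_uec",
]


class EnumerationCapError(RuntimeError):
    """2^k exceeds the configured cap; use the heuristic instead."""


@dataclass(frozen=True)
class CandidateSet:
    """Candidate rooting edges for one unrooted gene tree.

    ``case`` is ``"double"`` or ``"empty"``. ``full_candidates`` is the
    unpruned pool: the empty-edge rooting plus every non-empty edge of the
    (at most two) S2 stars flanking it, or the single canonical plateau edge
    in the double case; it never exceeds five. ``choices`` is the pool
    restricted to the D-plateau and pruned by interval dominance under the
    assumption that the final clustering has an episode at root(S); it
    drives the exponential branch of the exact solver. ``no_root_choices``
    is the analogous pruned pool for clusterings without a root episode
    (empty when every rooting of this tree forces one). ``branch_b`` lists
    the surviving with-root alternatives other than the empty rooting.
    ``ambiguous`` marks trees with two or more with-root choices.
    """

    case: str
    empty_edge: tuple | None
    branch_b: tuple
    full_candidates: tuple
    choices: tuple
    no_root_choices: tuple
    ambiguous: bool

    @property
    def enumeration_choices(self) -> tuple:
        """Edges this tree contributes to the exact enumeration."""
        return self.choices


def _interval_paths(G, S, e):
    T = G.root_at_edge(e)
    return [frozenset(iv.path) for iv in episodes.dup_intervals(T, S)]


def _dominated_by(A, B, root, assume_root):
    """Is rooting A at least as good as rooting B in every collection context?

    A location set stabbing all of B's duplication intervals must stab all of
    A's. That holds when every interval of A contains some interval of B
    (the stabber of the contained interval works). Under ``assume_root`` the
    root of S is taken to be a selected location, so root-containing
    intervals of A are covered for free; without it, interval containment is
    checked with the root excluded (solutions avoiding a root episode stab
    every interval strictly below the root).
    """
    for a in A:
        if assume_root and root in a:
            continue
        if assume_root:
            if not any(b <= a for b in B):
                return False
        else:
            if not any(b - {root} <= a for b in B):
                return False
    return True


def _prune_dominated(G, S, pool, ivs, root, assume_root):
    """Keep only undominated pool members; mutual domination (ties) keeps
    the earliest member in canonical edge order."""
    keep = []
    for i, e in enumerate(pool):
        dominated = False
        for j, f in enumerate(pool):
            if i == j:
                continue
            if _dominated_by(ivs[f], ivs[e], root, assume_root):
                if not _dominated_by(ivs[e], ivs[f], root, assume_root) or j < i:
                    dominated = True
                    break
        if not dominated:
            keep.append(e)
    return keep


def candidate_rootings(G: UnrootedGeneTree, S: SpeciesTree) -> CandidateSet:
    maps = unrooted.directed_edge_maps(G, S)
    ec = unrooted.classify_edges(G, S, maps)
    empties = ec.empty_edges()
    if not empties:
        e = unrooted.find_opt_edge(G, S)
        if ec.classes[e] != unrooted.DOUBLE:
            raise InvariantError("no empty edge yet descent found a non-double")
        ivs = _interval_paths(G, S, e)
        feasible = all(iv != frozenset({S.root}) for iv in ivs)
        return CandidateSet(case="double", empty_edge=None, branch_b=(e,),
                            full_candidates=(e,), choices=(e,),
                            no_root_choices=(e,) if feasible else (),
                            ambiguous=False)
    if len(empties) > 1:
        raise InvariantError("more than one empty edge")
    e_star = empties[0]
    plat = unrooted.plateau(G, S, "D")
    full = [e_star]
    for end in e_star:
        if len(G.adj[end]) == 1:
            continue
        for w in G.adj[end]:
            e = (end, w) if end < w else (w, end)
            if e != e_star:
                full.append(e)
    pool = [e for e in full if e in plat.edges]
    ivs = {e: _interval_paths(G, S, e) for e in pool}
    choices = _prune_dominated(G, S, pool, ivs, S.root, assume_root=True)
    feasible = [e for e in pool
                if all(iv != frozenset({S.root}) for iv in ivs[e])]
    no_root = _prune_dominated(G, S, feasible, ivs, S.root, assume_root=False)
    branch_b = tuple(e for e in choices if e != e_star)
    return CandidateSet(case="empty", empty_edge=e_star, branch_b=branch_b,
                        full_candidates=tuple(full), choices=tuple(choices),
                        no_root_choices=tuple(no_root),
                        ambiguous=len(choices) >= 2)


def count_k(collection, S: SpeciesTree, candsets=None) -> int:
    """k: number of trees with two refined candidates (ambiguous trees)."""
    if candsets is None:
        candsets = [candidate_rootings(G, S) for G in collection]
    return sum(1 for cs in candsets if cs.ambiguous)


@dataclass(frozen=True)
class UECResult:
    """Chosen rootings and episode clustering for a collection."""

    edges: tuple                   # rooting edge per gene tree
    solution: episodes.EpisodeSolution
    method: str                    # "exact" | "heuristic"
    optimal: bool
    enumerated: int                # EC instances actually evaluated
    k: int

    @property
    def count(self) -> int:
        return self.solution.count


def _ec_of(collection, S, edges):
    trees = [G.root_at_edge(e) for G, e in zip(collection, edges)]
    return episodes.ec_greedy(trees, S)


def uec_exact(collection, S: SpeciesTree, max_enum: int = 2 ** 20) -> UECResult:
    """Exact solver.

    Any optimal clustering either places an episode at root(S) or does not;
    each case is enumerated over the corresponding per-tree pruned candidate
    lists (the with-root product is at most 2^k for k ambiguous trees, the
    without-root product degenerates to the all-empty-rootings instance for
    species-spanning inputs). The overall minimum, with witnessing rooting
    edges, is returned.
    """
    collection = list(collection)
    candsets = [candidate_rootings(G, S) for G in collection]
    k = count_k(collection, S, candsets)
    with_root = [cs.choices for cs in candsets]
    no_root = [cs.no_root_choices for cs in candsets]
    n_combos = 1
    for c in with_root:
        n_combos *= len(c)
    if all(no_root):
        n2 = 1
        for c in no_root:
            n2 *= len(c)
        n_combos += n2
    if n_combos > max_enum:
        raise EnumerationCapError(
            f"{n_combos} candidate combinations exceed the cap {max_enum}; "
            "consider uec_heuristic")
    best_edges = best_sol = None
    evaluated = 0
    seen = set()
    branches = [with_root]
    if all(no_root):
        branches.append(no_root)
    for branch in branches:
        for combo in itertools.product(*branch):
            if combo in seen:
                continue
            seen.add(combo)
            sol = _ec_of(collection, S, combo)
            evaluated += 1
            if best_sol is None or sol.count < best_sol.count:
                best_edges, best_sol = tuple(combo), sol
    return UECResult(edges=best_edges, solution=best_sol, method="exact",
                     optimal=True, enumerated=evaluated, k=k)


def uec_heuristic(collection, S: SpeciesTree, max_enum: int = 2 ** 20) -> UECResult:
    """Unique-candidates-first heuristic with an optimality certificate.

    Solves the unambiguous subcollection exactly (one extra candidate set at
    most), then extends tree by tree, preferring the candidate whose
    duplication intervals are already stabbed by the selected locations.
    When the full collection matches the subcollection's cost, that cost is
    provably optimal.
    """
    collection = list(collection)
    candsets = [candidate_rootings(G, S) for G in collection]
    k = count_k(collection, S, candsets)
    unique_idx = [i for i, cs in enumerate(candsets) if not cs.ambiguous]
    ambi_idx = [i for i, cs in enumerate(candsets) if cs.ambiguous]
    edges: dict = {}
    if unique_idx:
        sub = uec_exact([collection[i] for i in unique_idx], S, max_enum)
        for i, e in zip(unique_idx, sub.edges):
            edges[i] = e
        c0 = sub.count
        locations = sub.solution.locations
        evaluated = sub.enumerated
    else:
        c0 = 0
        locations = frozenset()
        evaluated = 0
    for i in ambi_idx:
        options = candsets[i].enumeration_choices
        chosen = None
        for e in options:
            T = collection[i].root_at_edge(e)
            ivs = episodes.dup_intervals(T, S)
            if all(any(s in iv for s in locations) for iv in ivs):
                chosen = e
                break
        edges[i] = chosen if chosen is not None else options[0]
    ordered = tuple(edges[i] for i in range(len(collection)))
    sol = _ec_of(collection, S, ordered)
    evaluated += 1
    return UECResult(edges=ordered, solution=sol, method="heuristic",
                     optimal=sol.count == c0 or not ambi_idx,
                     enumerated=evaluated, k=k)


def uec_brute(collection, S: SpeciesTree, max_combos: int = 200_000) -> UECResult:
    """Test oracle: minimum episode count over the full Cartesian product of
    all D-plateau rootings of every tree."""
    collection = list(collection)
    plats = [unrooted.plateau(G, S, "D") for G in collection]
    n = 1
    for p in plats:
        n *= len(p.edges)
    if n > max_combos:
        raise ValueError(f"{n} plateau combinations exceed {max_combos}")
    best_edges = best_sol = None
    evaluated = 0
    for combo in itertools.product(*(p.edges for p in plats)):
        sol = _ec_of(collection, S, combo)
        evaluated += 1
        if best_sol is None or sol.count < best_sol.count:
            best_edges, best_sol = tuple(combo), sol
    return UECResult(edges=best_edges, solution=best_sol, method="brute",
                     optimal=True, enumerated=evaluated,
                     k=count_k(collection, S))


def single_uec(G: UnrootedGeneTree, S: SpeciesTree):
    """Minimal episode count over all D-plateau rootings of a single tree,
    with the set of edges achieving it."""
    plat = unrooted.plateau(G, S, "D")
    costs = {e: episodes.ec_greedy([G.root_at_edge(e)], S).count
             for e in plat.edges}
    best = min(costs.values())
    return best, frozenset(e for e, c in costs.items() if c == best)
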