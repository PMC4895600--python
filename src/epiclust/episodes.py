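"""Rooted episode clustering: valid mappings and minimal episode locations.

Gene duplications may be relocated upward in the species tree to model
multiple-gene-duplication episodes. A mapping F from gene-tree nodes to
species-tree nodes is *valid* when

1. F(a) ≼ F(b) whenever a ≼ b              (time consistency),
2. F(a) = M(a) for every speciation a      (fixed speciations),
3. F(a) ≽ M(a) for every duplication a     (duplications can be raised),
4. F(a) ≺ M(b) for every speciation b with a ≺ b
                                           (duplication count preserved).

Conditions 2-4 confine each duplication d to a root-directed species path
[M(d), top(d)] (its :class:`DupInterval`); the episode-clustering problem
asks for valid mappings of a whole collection of rooted gene trees that
minimize the number of distinct species nodes receiving duplications.
``ec_greedy`` solves it by stabbing the pooled intervals deepest-top first;
``ec_brute`` is the exhaustive oracle for small inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from . import reconcile
from .trees import InvariantError, RootedGeneTree, SpeciesTree

__all__ = [
    "DupInterval",
    "dup_intervals",
    "EpisodeSolution",
    "valid_mapping_violations",
    "ec_greedy",
    "ec_brute",
    "ec_percent_locations",
]


@dataclass(frozen=True)
class DupInterval:
    """Allowed placements for one duplication: the species path bottom..top.

    ``bottom`` is the lca-mapping image M(d); ``top`` is the species node
    just below the image of d's nearest speciation ancestor, or root(S) when
    no speciation ancestor exists. ``path`` lists the species nodes of the
    interval, bottom first.
    """

    node: int
    bottom: int
    top: int
    path: tuple

    def __contains__(self, s: int) -> bool:
        return s in self.path


def dup_intervals(T: RootedGeneTree, S: SpeciesTree, M=None, events=None):
    """One :class:`DupInterval` per duplication node of T."""
    if M is None:
        M = reconcile.lca_map(T, S)
    if events is None:
        events = reconcile.classify_events(T, S, M)
    out = []
    for d in range(T.n_nodes):
        if events[d] != reconcile.DUPLICATION:
            continue
        b = T.parent[d]
        while b is not None and events[b] != reconcile.SPECIATION:
            b = T.parent[b]
        if b is None:
            top = S.root
        else:
            if M[b] == M[d]:
                raise InvariantError(
                    "speciation ancestor shares the lca-image of a descendant "
                    "duplication; lca-map monotonicity violated")
            top = S.child_toward(M[b], M[d])
        out.append(DupInterval(node=d, bottom=M[d], top=top,
                               path=tuple(S.path_up(M[d], top))))
    return out


@dataclass(frozen=True)
class EpisodeSolution:
    """Episode locations plus the per-tree valid mappings that realize them."""

    locations: frozenset           # species nodes receiving duplications
    mappings: tuple                # one dict (gene node -> species node) per tree

    @property
    def count(self) -> int:
        return len(self.locations)


def valid_mapping_violations(T: RootedGeneTree, S: SpeciesTree, F,
                             M=None, events=None):
    """Independent checker of the four validity conditions; returns a list of
    human-readable violations (empty = valid)."""
    if M is None:
        M = reconcile.lca_map(T, S)
    if events is None:
        events = reconcile.classify_events(T, S, M)
    bad = []
    for a in range(T.n_nodes):
        p = T.parent[a]
        if p is not None and not S.is_ancestor(F[p], F[a]):
            bad.append(f"time consistency: F({a}) ⋠ F({p})")
        if events[a] == reconcile.SPECIATION and F[a] != M[a]:
            bad.append(f"fixed speciations: F({a}) != M({a})")
        if events[a] == reconcile.DUPLICATION and not S.is_ancestor(F[a], M[a]):
            bad.append(f"raisability: F({a}) ⋡ M({a})")
        # condition 4 against every speciation ancestor
        b = T.parent[a]
        while b is not None:
            if events[b] == reconcile.SPECIATION and not (
                    F[a] != M[b] and S.is_ancestor(M[b], F[a])):
                bad.append(f"strict cap: F({a}) ⊀ M({b})")
                break
            b = T.parent[b]
    return bad


def _full_mapping(T, M, events, placement):
    """F over all nodes: duplications from ``placement``, the rest fixed at M."""
    F = list(M)
    for d, s in placement.items():
        F[d] = s
    return F


def _tree_infos(trees, S):
    infos = []
    for T in trees:
        M = reconcile.lca_map(T, S)
        events = reconcile.classify_events(T, S, M)
        infos.append((T, M, events, dup_intervals(T, S, M, events)))
    return infos


def ec_greedy(trees, S: SpeciesTree) -> EpisodeSolution:
    """Minimal episode locations by deepest-top greedy interval stabbing.

    Pools the duplication intervals of all trees; repeatedly places an
    episode at the top of the interval whose top is deepest (ties broken by
    the canonical postorder species-node order) and discards every interval
    containing that node. Each duplication is then assigned the deepest
    selected location inside its interval, and the resulting mappings are
    re-checked against the four validity conditions.
    """
    infos = _tree_infos(trees, S)
    pool = [(ti, iv) for ti, info in enumerate(infos) for iv in info[3]]
    remaining = list(pool)
    locations = []
    while remaining:
        _, pick = min(remaining,
                      key=lambda x: (-S.depth[x[1].top], S.postorder_index[x[1].top]))
        s = pick.top
        locations.append(s)
        remaining = [(ti, iv) for ti, iv in remaining if s not in iv]
    placements = []
    for ti, (T, M, events, ivs) in enumerate(infos):
        placement = {}
        for iv in ivs:
            inside = [s for s in locations if s in iv]
            if not inside:
                raise InvariantError("greedy left an interval unstabbed")
            placement[iv.node] = max(inside, key=lambda s: S.depth[s])
        placements.append(placement)
    sol = _make_solution(infos, placements, locations)
    _verify(infos, sol, S)
    return sol


def _make_solution(infos, placements, locations) -> EpisodeSolution:
    mappings = []
    used = set()
    for (T, M, events, ivs), placement in zip(infos, placements):
        F = _full_mapping(T, M, events, placement)
        mappings.append({v: F[v] for v in range(T.n_nodes)})
        used.update(placement.values())
    return EpisodeSolution(locations=frozenset(used), mappings=tuple(mappings))


def _verify(infos, sol: EpisodeSolution, S: SpeciesTree) -> None:
    for (T, M, events, _), F in zip(infos, sol.mappings):
        bad = valid_mapping_violations(T, S, [F[v] for v in range(T.n_nodes)],
                                       M, events)
        if bad:
            raise InvariantError("solver produced an invalid mapping: "
                                 + "; ".join(bad))


def ec_brute(trees, S: SpeciesTree, limit: int = 10) -> EpisodeSolution:
    """Exhaustive oracle: try every placement of every duplication inside its
    interval, keep a validity-respecting assignment with fewest locations."""
    infos = _tree_infos(trees, S)
    all_ivs = [(ti, iv) for ti, info in enumerate(infos) for iv in info[3]]
    if len(all_ivs) > limit:
        raise ValueError(
            f"ec_brute limited to {limit} duplications, got {len(all_ivs)}")
    best = None
    for combo in itertools.product(*(iv.path for _, iv in all_ivs)):
        placements = [dict() for _ in infos]
        for (ti, iv), s in zip(all_ivs, combo):
            placements[ti][iv.node] = s
        ok = True
        for (T, M, events, _), placement in zip(infos, placements):
            F = _full_mapping(T, M, events, placement)
            if valid_mapping_violations(T, S, F, M, events):
                ok = False
                break
        if not ok:
            continue
        locs = set(combo)
        if best is None or len(locs) < best[0]:
            best = (len(locs), placements, locs)
    if best is None:
        raise InvariantError("no valid placement exists; conditions violated")
    _, placements, locs = best
    sol = _make_solution(infos, placements, sorted(locs))
    _verify(infos, sol, S)
    return sol


def ec_percent_locations(count: int, S: SpeciesTree) -> float:
    """Episodes as a percentage of species-tree nodes (2·leaves − 1)."""
    if count < 0:
        raise ValueError("episode count must be non-negative")
    return 100.0 * count / (2 * S.n_leaves - 1)
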