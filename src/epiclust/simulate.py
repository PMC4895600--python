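"""Fixture generation: random species trees, duplication-loss gene trees and
curated hand-built fixtures.

The gene-tree generator walks the species tree from the root with a
gene-lineage population: on every species branch each surviving lineage is
lost with probability ``loss_prob`` and otherwise duplicates with
probability ``dup_prob`` (both daughters continue down the same branch); at
every speciation each lineage splits into both child branches. Surviving
leaves, with lost lineages pruned and unary nodes suppressed, form the true
rooted gene tree; suppressing its root gives the unrooted version. A stem
branch above the species root allows root duplications. All randomness
flows from a single ``random.Random(seed)`` per call.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import NamedTuple

from .trees import (RootedGeneTree, SpeciesTree, UnrootedGeneTree,
                    parse_gene_newick, parse_rooted_gene_newick,
                    parse_species_newick)

__all__ = [
    "SimConfig",
    "SimulationError",
    "random_species_tree",
    "simulate_gene_tree",
    "Fixture",
    "fixture_suite",
]


class SimulationError(RuntimeError):
    """The generator could not produce a tree under the configured rates."""


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs: per-branch event probabilities and size limits."""

    dup_prob: float = 0.3
    loss_prob: float = 0.2
    seed: int = 0
    min_leaves: int = 3
    max_leaves: int = 500
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.dup_prob <= 1.0 and 0.0 <= self.loss_prob <= 1.0):
            raise ValueError("event probabilities must lie in [0, 1]")
        if self.min_leaves < 3:
            raise ValueError("min_leaves must be at least 3")


def random_species_tree(n: int, seed: int) -> SpeciesTree:
    """Random binary topology over leaves s1..sn by sequential random edge
    attachment; deterministic per seed."""
    if n < 3:
        raise ValueError("species tree needs at least 3 leaves")
    rng = random.Random(seed)
    # nested-list representation; edges enumerated as (parent, index) slots
    tree = ["s1", "s2"]

    def edges(node, acc, path):
        for i, child in enumerate(node):
            acc.append(path + (i,))
            if isinstance(child, list):
                edges(child, acc, path + (i,))

    for i in range(3, n + 1):
        acc = []
        edges(tree, acc, ())
        acc.append(None)  # the stem: attach above the current root
        slot = rng.choice(acc)
        leaf = f"s{i}"
        if slot is None:
            tree = [tree, leaf]
        else:
            node = tree
            for j in slot[:-1]:
                node = node[j]
            node[slot[-1]] = [node[slot[-1]], leaf]

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    return parse_species_newick(to_newick(tree) + ";")


class GeneTreeSim(NamedTuple):
    rooted: RootedGeneTree
    unrooted: UnrootedGeneTree
    n_duplications: int            # duplication events drawn (incl. later-lost)
    n_losses: int


def simulate_gene_tree(S: SpeciesTree, cfg: SimConfig) -> GeneTreeSim:
    """Evolve one gene family down S under the per-branch duplication-loss
    process; retries until at least ``cfg.min_leaves`` leaves survive."""
    rng = random.Random(cfg.seed)
    for _ in range(cfg.max_retries):
        counts = {"dup": 0, "loss": 0, "leaves": 0}

        def enter_branch(s: int):
            if rng.random() < cfg.loss_prob:
                counts["loss"] += 1
                return None
            if rng.random() < cfg.dup_prob:
                counts["dup"] += 1
                a = at_node(s)
                b = at_node(s)
                if a is None:
                    return b
                if b is None:
                    return a
                return (a, b)
            return at_node(s)

        def at_node(s: int):
            if counts["leaves"] > cfg.max_leaves:
                return None
            if S.is_leaf(s):
                counts["leaves"] += 1
                return S.labels[s]
            left, right = S.children[s]
            a = enter_branch(left)
            b = enter_branch(right)
            if a is None:
                return b
            if b is None:
                return a
            return (a, b)

        history = enter_branch(S.root)
        if counts["leaves"] > cfg.max_leaves:
            continue

        def count_leaves(node) -> int:
            if isinstance(node, str):
                return 1
            return count_leaves(node[0]) + count_leaves(node[1])

        if history is None or count_leaves(history) < cfg.min_leaves:
            continue

        def to_newick(node) -> str:
            if isinstance(node, str):
                return node
            return f"({to_newick(node[0])},{to_newick(node[1])})"

        text = to_newick(history) + ";"
        rooted = parse_rooted_gene_newick(text)
        unrooted_tree = parse_gene_newick(text)
        return GeneTreeSim(rooted, unrooted_tree,
                           counts["dup"], counts["loss"])
    raise SimulationError(
        f"no surviving gene tree with >= {cfg.min_leaves} leaves after "
        f"{cfg.max_retries} attempts; lower the loss probability")


@dataclass(frozen=True)
class Fixture:
    """A hand-built (gene tree, species tree) pair with known expectations.

    ``expected`` records, keyed by name: edge classes and plateau membership
    (edges as sorted leaf-label bipartition strings), the refined candidate
    count, the ambiguity flag and the single-tree UEC episode count.
    """

    name: str
    gene_newick: str
    species_newick: str
    expected: dict

    @property
    def G(self) -> UnrootedGeneTree:
        return parse_gene_newick(self.gene_newick)

    @property
    def S(self) -> SpeciesTree:
        return parse_species_newick(self.species_newick)


def fixture_suite():
    """Curated fixtures covering the empty-edge, double-edge, one-S2-star and
    two-S2-star (ambiguous) situations."""
    fixtures = [
        Fixture(
            name="star3_empty",
            gene_newick="(a,b,c);",
            species_newick="((a,b),c);",
            expected={
                "empty_edges": ["a,b|c"],
                "double_edges": [],
                "d_plateau": ["a,b|c"],
                "d_plateau_cost": 0,
                "branch_b": [],
                "ambiguous": False,
                "single_uec_count": 0,
                "single_uec_edges": ["a,b|c"],
            },
        ),
        Fixture(
            name="double_edge",
            gene_newick="((a,c),(b,c));",
            species_newick="((a,b),c);",
            expected={
                "empty_edges": [],
                "double_edges": ["a,c|b,c"],
                "d_plateau": ["a,c|b,c"],
                "d_plateau_cost": 1,
                "branch_b": ["a,c|b,c"],
                "ambiguous": False,
                "single_uec_count": 1,
                "single_uec_edges": ["a,c|b,c"],
            },
        ),
        Fixture(
            name="one_s2_star",
            gene_newick="((a,b),(a,c));",
            species_newick="((a,b),c);",
            expected={
                "empty_edges": ["a,a,b|c"],
                "double_edges": [],
                "d_plateau": ["a,a,b|c", "a,b|a,c", "a|a,b,c"],
                "d_plateau_cost": 1,
                "branch_b": ["a,b|a,c"],
                "ambiguous": False,
                "single_uec_count": 1,
                "single_uec_edges": ["a,a,b|c", "a,b|a,c", "a|a,b,c"],
            },
        ),
        Fixture(
            name="two_s2_stars",
            gene_newick="(((a,b),a),((c,d),c));",
            species_newick="((a,b),(c,d));",
            expected={
                "empty_edges": ["a,a,b|c,c,d"],
                "double_edges": [],
                "d_plateau": ["a,a,b|c,c,d", "a,b|a,c,c,d", "a|a,b,c,c,d",
                              "a,a,b,c|c,d", "a,a,b,c,d|c"],
                "d_plateau_cost": 2,
                "branch_b": ["a,b|a,c,c,d", "a,a,b,c|c,d"],
                "ambiguous": True,
                "single_uec_count": 2,
            },
        ),
    ]
    return {f.name: f for f in fixtures}
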