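"""Shared fixtures: curated tree pairs and cached simulated populations."""

from __future__ import annotations

import functools

import pytest

import epiclust as ep


@pytest.fixture(scope="session")
def suite():
    return ep.fixture_suite()


@pytest.fixture(scope="session")
def abc_species():
    return ep.parse_species_newick("((a,b),c);")


@functools.lru_cache(maxsize=None)
def sim_population(n, leaf_lo=5, leaf_hi=10, dup=0.3, loss=0.2, seed0=0,
                   max_leaves=500):
    """n simulated (species tree, gene tree sim) pairs, deterministic per
    argument tuple and cached for the whole test session."""
    span = leaf_hi - leaf_lo + 1
    out = []
    for i in range(n):
        S = ep.random_species_tree(leaf_lo + i % span, seed=seed0 + 1000 + i)
        sim = ep.simulate_gene_tree(
            S, ep.SimConfig(dup_prob=dup, loss_prob=loss, seed=seed0 + 2000 + i,
                            max_leaves=max_leaves))
        out.append((S, sim))
    return out


@functools.lru_cache(maxsize=None)
def sim_collections(n, n_trees_lo=2, n_trees_hi=4, leaf_lo=5, leaf_hi=8,
                    seed0=0, max_leaves=12, dup=0.3, loss=0.2):
    """n (species tree, [unrooted gene trees]) collections for UEC tests."""
    import random

    span = leaf_hi - leaf_lo + 1
    out = []
    for i in range(n):
        rng = random.Random(seed0 + i)
        S = ep.random_species_tree(leaf_lo + i % span, seed=seed0 + 5000 + i)
        col = [ep.simulate_gene_tree(
                   S, ep.SimConfig(seed=seed0 + 6000 + 31 * i + j,
                                   dup_prob=dup, loss_prob=loss,
                                   max_leaves=max_leaves)).unrooted
               for j in range(rng.randint(n_trees_lo, n_trees_hi))]
        out.append((S, col))
    return out


def unrooted_shape(G):
    """Topology proxy for isomorphism checks: sorted multiset of leaf-label
    bipartitions over all edges."""
    return sorted(G.bipartition(e) for e in G.edges)
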