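# epiclust

Multiple gene duplication episodes — whole-genome or large segmental
duplications — leave their trace as many single gene duplications scattered
across gene family trees. `epiclust` locates the minimal set of species-tree
positions that can host all of those duplications, for collections of
**rooted** gene trees (episode clustering, EC) and, its main purpose, for
collections of **unrooted** gene trees (unrooted episode clustering, UEC),
the form in which maximum-likelihood and neighbor-joining pipelines actually
deliver them. It is aimed at phylogenomics practitioners studying
duplication history and at method developers who need a reference
implementation with exhaustive oracles.

## The model

Given a rooted binary species tree *S* and a rooted binary gene tree *T*
with leaves labeled by species, the lca-mapping M sends each gene node to
the least common ancestor in *S* of its species; an internal node *g* with
children *a*, *b* is a *duplication* when M(*g*) ∈ {M(*a*), M(*b*)}, else a
*speciation*. Costs: D = number of duplications,
L = 2D + Σ(‖M(*a*),M(*b*)‖ − 2), DL = D + L.

Duplications may be relocated upward through a *valid mapping*
F : V(T) → V(S) satisfying (1) F monotone along ancestry, (2) F = M on
speciations, (3) F ≽ M on duplications, (4) F(*a*) ≺ M(*b*) for every
speciation ancestor *b* of *a*. These conditions confine each duplication to
a root-directed species path (its *interval*); EC asks for valid mappings of
all trees minimizing the number of distinct species nodes that receive
duplications, solved here by deepest-top greedy interval stabbing.

For an unrooted gene tree every edge is a rooting site; the edges of minimal
duplication cost form a connected subtree, the *D-plateau* (likewise the
DL-plateau, always contained in it). Edges classify as *empty*, *single* or
*double* by whether the subtrees on their two sides reach the top species
node, and the stars S1–S5 around internal nodes organize those classes. UEC
restricts rootings to the D-plateau and minimizes EC over the joint choice.
The exact solver reduces each tree to at most five candidate rootings (the
empty edge plus the flanking S2-star edges, or one canonical plateau edge
when a double edge exists), prunes candidates whose duplication-interval
multisets are dominated, and enumerates about 2^k combinations, where k is
the number of trees left ambiguous; a unique-candidates-first heuristic with
an optimality certificate covers large k.

## Worked example

Species tree `((a,b),c);` and two unrooted gene families, one with a
duplicated *a* (`((a,b),(a,c));`) and one with a duplicated *c*
(`((a,c),(b,c));`):

```sh
$ epiclust uec --species species.nwk --genes genes.nwk --format json
{
  "count": 1,
  "locations": ["a,b,c"],
  "percent_locations": 20.0,
  "rootings": ["a,b|a,c", "a,c|b,c"],
  "k": 0,
  "enumerated": 1,
  "optimal": true,
  "method": "exact"
}
```

A single duplication episode at the species root (the clade `a,b,c`, one of
the 5 species-tree nodes, hence 20%) explains both families: the first tree
is rooted on its internal edge (bipartition `a,b|a,c`) so that its
duplication can be raised to the root, where it joins the second tree's
root duplication. Per-edge diagnostics come from the `plateau` subcommand:

```sh
$ epiclust plateau --species species.nwk --genes genes.nwk
tree	bipartition	class	cost	in_plateau
0	a|a,b,c	single	2	0
0	a,a,c|b	single	2	0
0	a,b|a,c	single	1	1
0	a|a,b,c	single	1	1
0	a,a,b|c	empty	1	1
...
```

Tree 0's D-plateau holds three edges of cost 1, including the single empty
edge `a,a,b|c`. The other subcommands are `reconcile` (rooted D/L/DL
costs), `ec` (rooted episode clustering) and `simulate` (duplication-loss
fixture generation); all accept `--format tsv|json`, `--out` and
`--label-rule identity|prefix:<sep>` for gene-to-species label mapping.

## Documentation

`docs/methods.md` describes the model, the solvers, the simulator and the
package's design choices in detail.
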