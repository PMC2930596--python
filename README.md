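# metaconsensus

Semi-automatic integration of two metabolic-reaction databases into a tiered
consensus reconstruction, with stoichiometric-consistency validation and
network-topology analysis.

## The problem

Genome-scale metabolic reconstructions are usually built from a single
database, yet the major resources (KEGG-style and BioCyc-style databases)
disagree substantially: the same metabolite appears under different names,
protonation states, stereo annotations, or as a generic compound class, and
the same conversion is written with different cofactors or as a different
number of steps. Merging two such databases therefore cannot rely on
identifiers alone. `metaconsensus` implements an iterative, evidence-based
merge that separates what the two sources *agree* on from what only one of
them contributes, and validates the result physically.

## Method

Let the two databases be A and B, each a set of compounds (names, formula,
optional SMILES, cross-references) and reactions (stoichiometry, EC numbers).

**Compound identity.** An injective partial matching M ⊂ A×B is grown
iteratively:

1. *Seeding.* Pairs related by a cross-reference, or sharing a normalized
   synonym, are matched when unambiguous in both directions; ambiguous
   claims go to a review queue.
2. *Reaction-driven propagation.* For every unmatched reaction pair whose
   sides map one-to-one through M with equal coefficients except for at most
   one compound pair (free protons are dropped first), the unknown pair
   (a, b) becomes a candidate. It is accepted iff all three criteria hold:
   - the two reactions share a full four-field EC number;
   - the name-similarity score s(a, b) ≥ 0.9, where s is a logistic
     regression over seven symmetric string features (boundary-padded bigram
     Dice, prefix/suffix agreement, numeric-token agreement, acronym
     compatibility, shared and differing token counts), trained on the
     within-database synonym lists of the inputs (positives) and
     formula-discordant pairs (negatives);
   - the structures match exactly as canonical SMILES, or — when structures
     are missing — the formulas agree on every element except hydrogen.

   Candidates passing some but not all criteria are queued for review;
   resolved review decisions can be injected and the loop re-run. Iteration
   stops at a fixpoint.
3. *Tiers.* Reactions matched across both databases form the **core**
   network. A one-database reaction whose full substrate side or full
   product side consists of core compounds joins the **intermediate**
   network. Everything else joins the **complete** network. The three
   networks are nested: core ⊆ intermediate ⊆ complete.

**Consistency.** A network with stoichiometry matrix N (metabolites ×
reactions, net coefficients) is consistent iff some v ≥ 1 solves vᵀN = 0 —
i.e. every metabolite can carry a positive mass that all reactions conserve.
The validator decides this with an exact rational simplex (floating-point LP
for large instances), reports the *non-conserved* metabolites (those forced
to zero mass by every non-negative conservation vector), and enumerates the
support-minimal *elementary leakage modes* y with N·y ≥ 0, N·y ≠ 0, whose
one-sided nets are the minimal inconsistent net stoichiometries.

**Topology.** Compounds are nodes; each reaction connects every substrate to
every product by an undirected edge. The metric panel covers density,
heterogeneity (coefficient of variation of degree), mean clustering,
components, diameter, average connectivity 2(E−L)/N (L self-loops),
centralisation, per-component normalized betweenness
C_b(n) = 2/((N−1)(N−2)) · Σ_{s<t} σ_st(n)/σ_st and closeness
C_c(n) = (N−1)/Σ_m L(m, n), plus degree / shared-neighbour / path-length
distributions.

## Worked example: leakage in a two-reaction network

The classic inconsistency: R1: A ↔ B next to R2: A ↔ B + C lets C appear
from nothing (run R1 backwards, then R2 forwards).

```python
from fractions import Fraction
from metaconsensus.model_io import MatchedCompound, MatchedReaction, Reconstruction
from metaconsensus import stoich_check

compounds = {c: MatchedCompound(local_id=c, id_in_A=c) for c in "ABC"}
reactions = {
    "R1": MatchedReaction(local_id="R1", id_in_A="R1",
                          substrates=(("A", Fraction(1)),),
                          products=(("B", Fraction(1)),)),
    "R2": MatchedReaction(local_id="R2", id_in_A="R2",
                          substrates=(("A", Fraction(1)),),
                          products=(("B", Fraction(1)), ("C", Fraction(1)))),
}
net = Reconstruction(tier="core", compounds=compounds, reactions=reactions)
print(stoich_check.validate(net).to_text())
```

prints

```
stoichiometric consistency: FAIL
non-conserved metabolites: C
leakage mode: -1*R1 +1*R2
minimal inconsistent net stoichiometry (C): Ø ↔ 1 C
```

## Command-line workflow

```
$ metaconsensus fixtures synthetic demo/fix --seed 42
wrote demo/fix: A has 36 compounds / 37 reactions, B has 43 compounds / 37 reactions

$ metaconsensus integrate demo/fix/A demo/fix/B -o demo/out
matched 30 compounds and 30 reactions in 3 iterations
core: 30 compounds, 30 reactions
intermediate: 34 compounds, 37 reactions
complete: 48 compounds, 44 reactions
2 pairs queued for review

$ metaconsensus validate demo/out
stoichiometric consistency: PASS

$ metaconsensus topology demo/out
number_of_nodes: 28
number_of_edges: 95
network_density: 0.251
network_heterogeneity: 0.357
number_of_self_loops: 0
clustering_coefficient: 0.390
connected_components: 1
network_diameter: 5
network_centralisation: 0.168
average_path_length: 2.003
average_connectivity: 6.786
hubs:
  glutamate (Ath_C0022): 11
  malate (Ath_C0005): 10
  ...

$ metaconsensus export demo/out --format sbml -o demo/core.xml
wrote demo/core.xml
```

`integrate` writes the three nested reconstructions as TSV directories plus
`review_queue.tsv`; fill its `decision` column with `accept` and re-run with
`--review-decisions` to fold human judgments into the merge. `export` also
emits GraphML/SIF with tier colors for network viewers.

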