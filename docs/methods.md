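# Methods

This document specifies the algorithms and conventions implemented by
`metaconsensus`, in enough detail to re-derive every reported number.

## 1. Data model

A **source database** is a pair (C, R). Each compound c ∈ C carries a source
identifier, a non-empty list of names, an optional elemental formula (a map
element → count), an optional SMILES string, and a set of cross-reference
identifiers. Each reaction r ∈ R carries a source identifier, substrate and
product multisets of (compound id, coefficient ∈ ℚ₊) pairs, a reversibility
flag, and a set of EC numbers (strings of up to four dot-separated fields).

On disk a database is a directory with `compounds.tsv` and `reactions.tsv`;
stoichiometries use the `1 A + 2 B = 1 C` dialect with `=` separating sides.
Merged reconstructions round-trip losslessly through the same dialect and can
be exported to SBML Level 3 (species/reactions with `identifiers.org`
annotations for the source identifiers), GraphML, or SIF.

## 2. Name normalization and the similarity model

Normalization lowercases, maps Greek letters to their spelled-out names,
collapses punctuation to single spaces, and strips leading/trailing
stereo-irrelevant whitespace. Two names are *normalized-equal* iff their
normalizations coincide.

The similarity score s(a, b) ∈ (0, 1) is a logistic regression
σ(w·f(a, b) + w₀) over seven symmetric features of the normalized names:

1. **Bigram Dice** on boundary-padded character bigrams: each name is padded
   with a start and an end sentinel before bigram extraction, and
   Dice(X, Y) = 2|X∩Y| / (|X|+|Y|) on the bigram multisets. Padding makes
   the feature provably non-increasing under appending a common suffix to
   one name only, and gives identity exactly 1.
2. Longest-common-prefix fraction.
3. Longest-common-suffix fraction.
4. Numeric-token agreement: 1 if the multisets of digit-leading tokens
   coincide, 0 otherwise (locant transpositions keep this at 1).
5. Acronym compatibility: 1 if one name is a plausible initialism of the
   other's tokens.
6. Count of shared word tokens (capped).
7. Count of differing word tokens (capped).

Training pairs are mined from the inputs themselves: positives are all
within-record synonym pairs (every compound's name list, both databases);
negatives are seeded-random cross-record pairs whose formulas disagree on a
heavy atom. The model is sklearn `LogisticRegression` with L2 penalty,
`C = 1 / l2_strength`, default `l2_strength = 1.0`, deterministic solver. A
deterministic heuristic model (hand-set weights) is available for curated
fixtures too small to train on. The acceptance threshold on s is 0.9; pairs
scoring in [0.5, 0.9) with partial supporting evidence are routed to review.

## 3. Structure comparison

When both compounds carry SMILES, comparison proceeds through a tiered
RDKit canonicalization ladder; the first level at which the canonical forms
coincide is the match class:

1. **exact** — canonical isomeric SMILES equal;
2. **stereo** — equal after stripping stereochemistry;
3. **tautomer** — equal after RDKit tautomer canonicalization;
4. **charge** — equal after neutralizing protonation states;
5. **similar** — Morgan-fingerprint Tanimoto ≥ `sim_threshold` (default 0.4);
6. **none** — otherwise.

`exact` counts as structural confirmation for automatic acceptance;
`stereo`/`tautomer`/`charge`/`similar` contribute review-queue evidence.
When either SMILES is missing, the fallback predicate is *formula equality
ignoring hydrogen*: the formula maps agree on every element except H
(protonation-state differences between databases are expected and ignored).

## 4. Iterative integration

Let M be the (initially empty) injective partial matching between compound
sets. Free protons (compounds named `H+`/`proton`, configurable id list) are
excluded from matching and dropped from reaction sides before comparison.
Generic class compounds (names matching configurable generic markers such as
"an alcohol", "a quinone") are never auto-matched; their candidacies go to
review.

**Seeding.** Match every pair related by a shared cross-reference, and every
pair sharing a normalized name, provided the relation is unambiguous in both
directions (one candidate each way). Ambiguous claims emit review entries.

**Propagation loop.** Repeat until no change:

For every pair (rᴬ, rᴮ) of unmatched reactions, compare sides under M in
both orientations (B's reaction possibly reversed). A comparison outcome is
*full* when both sides map one-to-one with equal coefficients, *one-unknown*
when exactly one unmatched compound pair (a, b) is left over with equal
coefficients, and *blocked* otherwise. Reactions with a full match and
compatible ECs (non-empty intersection, or either side lacking ECs) are
matched. For a one-unknown outcome, the candidate (a, b) is **accepted**
automatically iff all three hold:

- the reactions share at least one full four-field EC number;
- s(a, b) ≥ 0.9;
- structure class is `exact`, or (structures missing) formulas agree
  ignoring hydrogen.

Accepted candidates extend M (an attempt to re-map an already-matched
compound raises an injectivity error rather than silently overwriting);
candidates with partial evidence are queued for review with the evidence
string; candidates with no supporting signal are rejected. Matched reactions
drop out, so acceptances cascade in later sweeps; termination is a fixpoint
of (M, matched reactions).

**Review workflow.** The queue is written as TSV; a curator fills the
`decision` column (`accept`/`reject`). Decisions are injected as a resolver
on a re-run, with manual evidence recorded in the match history.

## 5. Tier assignment

Given the fixpoint:

- **core** — matched reaction pairs, with compounds translated to merged
  identifiers; this is the both-databases consensus.
- **intermediate** — core plus every one-database reaction whose entire
  substrate side or entire product side (after proton drop) consists of core
  compounds; these reactions are anchored to the consensus at one end.
- **complete** — everything: intermediate plus all remaining one-database
  reactions and their compounds.

Unmatched same-role duplicates across the databases remain distinct entries
in the complete tier (double entries are a deliberate signal of unresolved
identity, not an error). The nesting core ⊆ intermediate ⊆ complete holds by
construction and is asserted in the tests.

## 6. Stoichiometric consistency

Let N ∈ ℚ^{m×n} be the net stoichiometry matrix of a reconstruction
(metabolites × reactions; substrates negative, products positive; catalytic
compounds appearing with equal coefficients on both sides contribute zero
and are dropped with a warning).

- **Consistency**: ∃ v ∈ ℚ^m, v ≥ 1, vᵀN = 0. Decided by linear
  programming: an exact two-phase simplex over `fractions.Fraction` with
  Bland's anti-cycling rule for small instances, `scipy.optimize.linprog`
  for large ones; both paths are cross-checked in the tests.
- **Non-conserved metabolites**: metabolite i is non-conserved iff
  max { vᵢ : vᵀN = 0, 0 ≤ v ≤ u } = 0 for a box bound u — i.e. every
  non-negative conservation vector assigns it zero mass.
- **Leakage modes**: support-minimal y ∈ ℚⁿ with N·y ≥ 0 and N·y ≠ 0, found
  by enumerating candidate supports in increasing size and solving the
  normalized feasibility LP on each; enumeration is capped (`mode_cap`,
  default 16) for large networks. Modes are canonicalized by positive
  scaling to coprime integers (sign is fixed by the cone orientation).
- Each mode's one-sided net N·y is reported as a **minimal inconsistent net
  stoichiometry**, rendered as `Ø ↔ k X` style production-from-nothing
  statements.

Elements flagged as exchange/boundary can be excluded from N before the
check.

## 7. Network topology

The compound graph G of a reconstruction is undirected: for each reaction,
every (substrate, product) pair gains an edge; parallel edges collapse;
self-loops (a compound on both sides) are kept as loops but excluded from
degree-based statistics. With N nodes, E edges, L self-loops:

- density = 2(E−L) / (N(N−1));
- heterogeneity = coefficient of variation of the loop-free degree sequence;
- clustering coefficient = mean over nodes of 2T(n)/(k(n)(k(n)−1)) (0 for
  degree < 2), T(n) the triangles at n;
- average connectivity = 2(E−L)/N;
- diameter and average path length over the largest scope of finite
  distances; connected-component count alongside;
- centralisation = [N/(N−2)] · [k_max/(N−1) − density];
- betweenness C_b(n) = 2/((N_c−1)(N_c−2)) Σ_{s<t} σ_st(n)/σ_st and
  closeness C_c(n) = (N_c−1)/Σ_m d(m, n), both normalized per connected
  component of size N_c;
- distributions: degree, shortest-path length, shared neighbours per pair.

Hub tables rank compounds by loop-free degree with deterministic
tie-breaking by identifier.

## 8. Synthetic fixtures with planted ground truth

`synthfix.generate(FixtureSpec)` builds two database views of one latent
metabolism so that every pipeline outcome is exactly scoreable. The spec's
defaults are the study conditions. The generator:

- samples a reaction template set (shared backbone plus per-view-only
  reactions) over template compounds with RDKit-valid SMILES and consistent
  formulas;
- gives each compound a synonym family in one of four styles — plain
  suffix family (`Xate` / `Xic acid` / `alpha-` variants), locant-phosphate
  (`Xate 6-phosphate` / `6-phospho-Xate`), O-ester, acronym
  (`ACR` / spelled-out) — and splits names across the views;
- perturbs a seeded fraction of shared compounds with one of three rewrite
  classes (suffix exchange, Greek-letter spelling, locant reordering) such
  that the two views share **no** normalized name for that compound;
- plants proton discrepancies (one view writes explicit `H+`), cofactor
  swaps, generic-class variants, and structure errors at seeded rates;
- emits a `GroundTruth` with the compound-pair bijection and the expected
  tier of every reaction, writable as TSV.

Identity recovery, false-merge purity (heavy-atom formula discordance), tier
accuracy, and core consistency are measured against this truth. Two curated
fixtures complement the generator: a TCA/glyoxylate-cycle pair encoding the
characteristic cross-database disagreements (two-step oxalosuccinate route,
direct vs three-step 2-oxoglutarate oxidation, generic vs specific
ubiquinone), and a tier-attribution showcase with at least two reactions per
tier-assignment case.

`synonym_corpus(n_compounds=300, seed=0)` emits a realistic-scale compound
list (same family machinery, synthetic formulas) used as the training
fixture when calibrating the name model outside a full integration run.

## 9. Verification strategy

Every analytical routine is checked against an independently implemented
oracle on instance families that do not depend on the implementation:

- consistency / non-conserved / leakage supports vs `scipy.optimize.linprog`
  formulations, exhaustively over all 2×2 integer matrices with entries in
  {−2..2} and on seeded 3×3/4×4 samples from the same space;
- the exact simplex vs scipy on seeded random LPs, with exact certificate
  verification (A·x = b over ℚ);
- betweenness / closeness / clustering vs pure-Python BFS path-counting
  oracles on 50 seeded random graphs of ≤12 nodes;
- TSV ↔ memory ↔ SBML round trips, byte-identical regenerated fixtures, and
  determinism of every seeded entry point.

`scripts/acceptance.py --seed S --out F` re-runs the headline studies with
all randomness derived from S and writes each quantity with its sample size.
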