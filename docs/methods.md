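# Methods

## The model

`pbcnet` treats disease-gene discovery as a guilt-by-association problem
on the protein–protein interaction (PPI) network. The working
assumptions are:

1. **Disease modules are local.** Genes involved in the same disease
   stage cluster topologically: they interact with each other more than
   with random genes, so network proximity to known disease genes is
   evidence of involvement.
2. **Known labels are positive-only.** Curated disease-gene lists
   contain true positives but say nothing about the rest of the genome;
   an unlabelled gene may be an undiscovered disease gene. This is the
   positive-unlabelled (PU) setting, not binary classification.
3. **Stages are separable.** Early-stage, late-stage and
   stage-unspecified gene sets are analysed independently; one gene may
   carry several stage labels.

The chain per stage is: curated seeds → relevance-weighted diffusion →
PU ranking of unlabelled genes → top-K "likely positive" (LP) selection →
over-representation analysis (ORA) of seed and LP sets against drug and
pathway collections.

## Seed curation

Raw rows `(symbol, stage, source, C, M, I, L)` are uppercased, resolved
through an optional alias table (tokens absent from the table are kept
uppercased and flagged, not dropped — silent shrinkage of a seed list is
worse than an unmapped symbol), and merged per canonical symbol with
stage-label union.

Relevance scores drive the diffusion initialization:

* database-sourced genes: GDA score `min(1, C + M + I + L)`, the sum of
  curated-source, model-organism, GWAS and text-mining components. The
  score's defined range is [0, 1]; the clamp realizes that range for
  component sums exceeding it.
* manually curated genes: the maximum database score of the gene's
  stage(s); 1.0 when a stage has no database genes. Curated genes thus
  always weigh at least as much as any database gene of the same stage,
  reflecting the higher confidence of manual curation.
* a gene with both database and curated rows resolves to the database
  score — the better-defined quantity.

## Diffusion

Propagation is a random walk with restart (RWR): the unique fixed point
of `p = r·p₀ + (1 − r)·W·p`, solved by power iteration. `p₀` puts mass
`relevance(g) / Σ relevance` on each in-network seed; seeds missing from
the interactome are dropped from diffusion (logged) but kept for ORA.

Parameters:

| parameter | default | meaning |
|---|---|---|
| `restart` | 0.3 | fraction of mass re-injected at seeds per step; larger values keep heat more local. 0.3 is the conventional middle ground for PPI prioritization. |
| `tol` | 1e-8 | max-norm convergence threshold on successive iterates |
| `max_iter` | 10000 | iteration cap; exceeded → explicit convergence error carrying the last residual |
| `normalization` | column-stochastic | `W = A D⁻¹` conserves the unit mass of `p₀`; `symmetric-degree` (`D^{-1/2} A D^{-1/2}`) is available by config |

A finite-time heat kernel would be the other natural reading of
"diffusion"; RWR was chosen because its restart parameter plays the same
locality-controlling role with a well-defined stationary limit, and
because the fixed point admits an independent linear-solve oracle
(`propagate_direct`, also used by the tests). The interactome is
restricted to its largest connected component before any diffusion —
heat trapped in small components would distort rankings — and edges are
unweighted, as curated PPI evidence lines carry no natural weights.

## PU ranking and LP selection

Features per gene: converged heat, log(1 + degree), fraction of
neighbours that are seeds, mean neighbour heat, and shortest-path
distance to the seed set capped at 5. All are standardized over nodes;
constant columns stay at zero.

Bagged PU in the Mordelet–Vert style: each of `n_bags = 100` rounds draws
`negatives_per_bag × |P|` unlabelled genes as provisional negatives
(default multiplier 1.0), fits an L2-regularized logistic classifier
(`C = 1.0`) on seeds vs the sample, and scores the out-of-bag unlabelled
genes. A gene's PU score is its mean out-of-bag positive-class
probability; genes never out-of-bag (possible only when the unlabelled
pool is barely larger than a bag) fall back to their in-bag mean. The
scheme is deterministic given its RNG seed; each pipeline stage derives
an independent sub-seed from the run seed.

The LP set is the top `K = 150` non-seed genes by PU score, ties broken
lexicographically; the combined set is the disjoint union of seeds and
LP genes with provenance labels. Whether a published 150-gene cut is a
fixed count or a score threshold is ambiguous; a fixed count is
implemented because it makes downstream set sizes comparable across
stages. The LP "relevance" reported is the PU score itself. By default a
stage run uses only its own stage's seeds; `pool_unspecified` adds the
unspecified-stage seeds to the early and late runs for sensitivity
analyses. ORA is emitted for seed sets and for LP sets; combined-set ORA
is behind `emit_combined_ora`.

## Enrichment

Standard ORA: query mapped to the background (protein-coding gene list),
sets intersected with the background and filtered to 5–2000 mapped
members, one-sided Fisher exact test — `P(X ≥ k)` under
Hypergeometric(N, K_set, n_query) — and Benjamini–Hochberg step-up
adjustment across all tested sets of one collection/category family,
with significance at FDR < 0.05. The test is enrichment-only (upper
tail), the ORA convention. Removing a set from a collection never
changes another set's raw p, only its FDR.

## The synthetic generator

`pbcnet.synthetic` emulates the statistical structure the method
assumes, not any particular organism's interactome:

* **Interactome**: Barabási–Albert preferential attachment (default
  n = 1000 genes, m = 3 edges per new node → m(n − m) = 2991 edges),
  giving the heavy-tailed degree distribution that dominates diffusion
  behaviour on real PPI networks. Duplication-divergence growth would be
  more mechanistic but adds parameters without changing the hub/locality
  structure the method depends on.
* **Disease module**: a connected set of 60 genes grown by random
  frontier expansion from a random root, then tightened: with
  probability `module_cohesion` (default 0.9) each module gene gains an
  edge to a non-adjacent module gene and, where possible, loses one edge
  to a non-module gene in exchange (removals that would disconnect the
  graph roll back to plain additions). Cohesion therefore raises
  within-module density while lowering leakage at roughly constant
  degree — the defining property of a disease module. Module membership
  is drawn from an RNG stream separate from the rewiring stream, so it
  is invariant to the cohesion setting at a fixed seed.
* **Seeds**: 30 stage draws from the module, split 6 / 5 / 19 across
  early / late / unspecified — the 238 : 183 : 728 stage proportions of
  stage-annotated PBC gene corpora, scaled down. Database-like scores
  are Beta(2, 5) (right-skewed, mass near 0.2–0.4, as real GDA scores
  are) split into C, M, I, L components by a Dirichlet draw; a
  configurable fraction (default 0.3) of rows is marked curated and
  scored by the stage-maximum rule.
* **Annotations**: 50 sets of 5–50 members, alternating drug/pathway
  tags; the first 5 are "planted" with 75 % of members from the module,
  decoys draw uniformly. Ground truth (module, seed assignments, planted
  ids) is written as a JSON sidecar.

Everything is deterministic per `rng_seed` (each generator stage uses
its own derived stream) and the fixture writer emits byte-identical
files for equal configs.

**What passing on synthetic data does and does not show.** The generator
produces clean symbols (no real alias noise), a single connected module,
independent Beta scores, and annotation sets with uniform decoys. Real
disease-gene data has correlated literature biases, multiple or
overlapping modules, database-version churn and annotation sets that are
themselves degree-biased. Tests on this generator validate the
machinery — mass conservation, recovery of a planted local module,
type-I control under a true null, determinism — not performance on PBC
itself. One consequence worth knowing: because the module is grown as a
connected neighbourhood, it stays topologically recoverable (AUROC well
above chance) even at `module_cohesion = 0`; a genuinely signal-free
control requires positives placed uniformly at random, which is what the
chance-level test does.

## Numerical and degenerate-input choices

* Ranking ties (equal heat or PU score) break lexicographically by
  symbol, making every output ordering reproducible.
* `restart = 1` short-circuits to the initial vector; zero total seed
  relevance is an error rather than a silent uniform fallback.
* Fisher at k = 0 returns exactly 1.0; inconsistent contingency counts
  are validation errors, not clamped.
* BH output is capped at 1 and aligned to input order; permuting the
  inputs permutes the outputs.
* Empty ORA tables and empty report sections propagate as empty
  DataFrames, not errors; a stage with no in-network seeds is skipped
  with a logged reason, and a run succeeds if at least one stage ran.
* Run manifests carry a config hash that excludes the output directory,
  so runs into different directories compare equal.

## Problem sizes used in validation

The test suite and the acceptance script work at the generator's default
scale (1000-gene network, 60-gene module, 30 seeds) with 10 replicate
universes for recovery metrics, 20 for monotonicity checks, and 200
smaller universes (400 genes, 40 sets) for the null false-positive rate
— sizes at which the planted signal is clearly detectable yet every
property is cheap to recompute from scratch.

## Known limitations

* Corpus-level figures from published PBC screens — e.g. a 1498 → 1121
  seed-list reduction or a 238/183/728 stage split — and absolute
  enrichment statistics (p-values, FDRs for specific drugs such as
  TUDCA, geldanamycin or erlotinib) depend on the curated literature
  corpus and on the DisGeNET, BioGRID and DrugBank versions and
  protein-coding background size used at query time. None of those
  inputs are deposited; such numbers are version-dependent and are not
  recomputation targets of this package. The reproducible counterparts
  here are structural: curation counts on printed gene lists, per-stage
  LP cardinality, and recovery/type-I behaviour on planted ground truth.
* Edge weights, evidence codes and physical-vs-genetic interaction
  classes are out of scope; pre-filter the edge list if that matters.
* The PU classifier is linear on five topological features; kernel or
  graph-embedding classifiers and hyperparameter search are out of
  scope.
* GSEA-style ranked enrichment is absent by design; ORA on discrete
  sets is the implemented contract.
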