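# Methods

## Diffusion-based target prediction

The predictor operates on a tripartite graph with three node layers —
substructure bits, compounds ("drugs") and protein targets — and two
edge types: drug–substructure edges wherever a fingerprint bit is 1,
and drug–target edges for known DTIs. There are no within-layer or
substructure–target edges. Compounds whose fingerprint row is all zero
cannot participate and are excluded with a warning.

One prediction run for drug *d*:

1. **Initial allocation.** A unit of resource is split α to *d*'s
   substructure neighbours (evenly within the side) and 1 − α to its
   known-target neighbours (evenly). A drug with no known targets puts
   everything on the substructure side (new-chemical-entity mode).
2. **Diffusion round**, repeated *k* times:
   (i) every substructure and target node returns its mass evenly to
   its neighbouring drugs; (ii) every drug splits its mass β to the
   substructure side versus 1 − β to the target side (all of it to the
   side that exists when the other is empty) and distributes it within
   a side proportionally to deg(neighbour)^γ, where deg is the node's
   total tripartite degree computed once before diffusion (static hub
   weights).
3. **Ranking.** Targets are sorted by final mass, descending; already
   known targets are removed ("putative" = not already known; a flag
   keeps them for the evaluation harness); the list is truncated to
   `top_n`; ties break lexicographically by gene symbol, so top-N lists
   are reproducible.

The exact update equations of the original bSDTNBI tool are defined in
its own publication chain; the formulation above is this package's
fixed contract, chosen so that every parameter plays the role its name
implies (α initial-side balance, β edge-type weight, γ hub penalty, k
round count) and should be treated as a possible divergence from the
original implementation. Defaults α = β = 0.1, γ = −0.5, k = 2,
top_n = 20.

Numerical notes. With γ = 0 each round is doubly conservative and the
total mass stays 1 to ≤ 1e−9 (tested). With γ ≠ 0 the within-side
renormalisation by Σ deg^γ does not conserve mass globally; only ranks
within a drug are contractually meaningful, so scores are reported as
raw final masses without renormalisation. All rounds are two sparse
matrix products; scoring every drug at once is a batched version of the
same operator, so the vectorised path and the per-drug path agree
exactly (tested against an independent dense oracle).

**Hold-out evaluation.** `evaluate_auc` hides a seeded uniform fraction
of known DTIs, rebuilds the graph from the rest, scores every
(drug, target) pair not retained in training, and computes ROC AUC with
the held-out edges as positives and never-known pairs as negatives.
Held-out pairs whose target dropped out of the training graph entirely
cannot be scored and are reported as `n_unscoreable` rather than
silently ignored.

## Network statistics

Known and predicted DTIs merge into one bipartite network with per-edge
provenance; a pair present in both resolves to `known`. Degree
summaries report exact means (edges/compounds and edges/targets) plus
half-up one-decimal roundings for display, because the published
figures of this literature are printed at one decimal. Degree-based
top lists count known and predicted edges together by default (the
published top lists mix them); a provenance filter is available. For
the nine-ingredient subnetwork the ambiguous published "average degree"
is interpreted as the mean target-side degree (edges/targets); both
sides are always computed.

Herb-level statistics treat a herb as its compound set; a herb's target
set is the union of its members' network neighbours. Overlap matrices
are symmetric with set sizes on the diagonal; the common-target core is
the intersection over all herbs.

## Enrichment statistics

Per compound, the 2×2 table counts its targets inside/outside the
disease gene set against the rest of the universe; the one-sided
(enrichment-direction) Fisher's exact p is the hypergeometric tail
P(X ≥ a) with margins fixed. The universe defaults to the target set of
the assembled network — the natural analogue of testing against the
screened target space — with an optional "union" policy (network
targets ∪ disease genes); the published analysis does not state its
background, so exact reproduction of its printed q values is not
promised, only the qualitative ordering. Compounds with zero targets in
the universe are excluded from testing rather than assigned p = 1: they
cannot be enriched, and including them would dilute the BH family.
Benjamini–Hochberg adjustment runs across all tested compounds of the
run; significance is q < 0.05 by default.

Fisher tails are computed with `scipy.stats.hypergeom` and BH with
`statsmodels`; both are verified in the test suite against independent
exact-rational brute-force oracles (pmf summation over all 2×2 tables
with total ≤ 30; hand step-up recursion).

The ORA module applies the same upper-tail hypergeometric per GMT
annotation set, dropping query genes outside the supplied universe with
a warning. No GO-DAG propagation or pathway topology is attempted.

## Four-step screen

Gates: (1) membership in the supplied main-component list; (2) Lipinski
Rule of Five, all four inequalities strict (MW < 500 Da, AlogP < 5,
HBD < 5, HBA < 10); (3) HIA and BBB positive-class probabilities both ≥
a threshold; (4) disease-enrichment q < q*. The ADMET probabilities are
inputs from an external classifier — the package implements the gate,
not the model. The positive-call cutoff is not stated in the source
analysis; 0.5 is adopted (all nine published ingredient probabilities
are ≥ 0.53, so the choice is not binding there) and configurable.

A gate with missing inputs returns *ineligible* (`None`), distinct from
*fail*: under-curated compounds are never silently passed or failed,
and retention requires an explicit pass on all four gates. Every gate
is evaluated for every compound so the report explains each exclusion;
the retained set is a pure conjunction, hence order-independent and
monotone in every threshold (both properties tested).

## Synthetic data generator

The generator emulates the input structure of a formula-scale analysis:

| parameter | default | meaning |
|---|---|---|
| n_herbs / compounds_per_herb | 6 / 100 | herbs sampled from a shared pool with reuse probability 0.5, giving the heavy inter-herb compound sharing seen in real formulas |
| n_compounds | 400 | compound pool |
| n_targets | 200 | target universe |
| n_bits | 300 | fingerprint width |
| n_scaffold_classes / signature_bits_per_class / signature_prob | 16 / 12 / 0.8 | scaffold-class model of the fingerprints |
| bit_density | 0.02 | background (noise) bit probability |
| dti_density | 0.06 | expected fraction of targets a compound binds (~12 known targets each) |
| coupling | 20 | extra DTI sampling weight per shared driver bit |
| n_disease_genes | 30 | disease subset of the target universe |
| n_planted / planting_strength | 20 / 0.6 | planted actives and their minimum disease-target fraction |

Coupling model: compounds belong to scaffold classes; each class owns a
dedicated block of signature bits which its members display with
probability 0.8 on top of background noise bits; targets fall
round-robin into one module per class, and a target's *driver bits* are
its class's signature bits. A compound's known targets are drawn
without replacement with weight 1 + coupling × (number of driver bits
it carries), so classes preferentially bind their module — the
scaffold-cluster structure real compound libraries show, and the reason
held-out DTIs are recoverable both through shared substructures and
through co-targeting. Planted actives additionally have
⌈s·n⌉ of their n targets forced into the disease subset, so their
realised disease fraction is ≥ s by construction (checked in tests).
`null_dataset` sets coupling = 0 and plants nothing: targets are wired
uniformly at random, the appropriate control for type-I error and
chance-level AUC.

Randomness: one master seed spawns independent per-component
`SeedSequence` children (fingerprints, wiring, herbs, disease,
planting, annotations), so adding a component never perturbs the
others, and a dataset is byte-identical across runs of the same seed.

What the generator does **not** emulate: real chemistry (SMILES are
absent, physicochemical values are drawn from plausible ranges
independent of the fingerprints), literature-curation noise, assay
bias, or gene-symbol aliasing. Passing the synthetic studies therefore
demonstrates statistical correctness of the pipeline — calibration
under the null and power under planted signal — not predictive validity
on any real formula.

## Problem sizes used in validation

The automated studies use the defaults above (400 compounds × 200
targets × 300 bits), one planted dataset and 20 null replicates, which
keeps the complete suite and the acceptance script in the range of
seconds to a few minutes on a single CPU. Diffusion correctness is
established separately against a dense dict-based oracle on hundreds of
random ≤ 12-node graphs, where exhaustive comparison is exact.

## Known limitations

- The diffusion update is a faithful-to-description reconstruction, not
  a port of the original bSDTNBI code; scores are not comparable across
  tools, only rankings within this one.
- The published full-network constants that depend on the source
  article's supplementary tables (e.g. the six-herb 79-gene common
  core, the exact printed q values) cannot be recomputed without those
  inputs; the corresponding operations are instead verified against
  independent oracles on synthetic data.
- Gene identity is the uppercased symbol string; no alias resolution.
- The BH family is the set of compounds tested in one run, so q values
  change when the compound panel changes — by design, as in any FDR
  screen.
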