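# Methods

This note records the modelling assumptions, default parameters and design
choices behind the package, and what the synthetic benchmark does and does
not establish about real screening data.

## Threshold labels from confirmatory measurements

A confirmatory measurement is (molecule, receptor, endpoint ∈ {IC50, Ki,
Kd}, value in nM, qualifier ∈ {eq, lt, gt}). Aggregation to one consensus
potency per molecule × receptor:

- **Endpoint precedence Ki > Kd > IC50.** Binding constants are
  assay-concentration-independent; IC50 is used only when no binding
  constant exists. Configurable in `ENDPOINT_PRECEDENCE`.
- **Geometric mean of exact replicates.** Potencies are conventionally
  log-normal; the geometric mean is the natural average.
- **Censored-only sets** return the least informative consistent bound
  (largest `lt`, else smallest `gt`). When `lt` and `gt` bounds bracket an
  interval, the `lt` bound alone is kept rather than fabricating a point
  estimate; the price is `unknown` instead of `inactive` labels below the
  `gt` bound. A `lt` bound at or below a `gt` bound is contradictory and
  yields all-unknown labels.

Labels at thresholds {1, 10, 100, 1000, 10000} nM: "active at t" means
potency ≤ t, boundary inclusive (a 10 nM molecule is active at 10 nM).
Censoring produces `unknown` wherever the bound does not decide the
comparison. Unknowns are masked out of the training loss, never imputed.

## Featurization

Binary Morgan fingerprints, radius 2, 2048 bits: deterministic,
canonicalization-invariant, standard for ligand-based screening at this
scale. No physicochemical descriptor block by default (the configuration
object is the hook point for one). A configuration hash accompanies every
feature matrix and model; mismatched hashes are a hard error rather than a
silent wrong answer.

Standardization keeps the largest covalent fragment and neutralizes simple
protonation states; tautomer canonicalization is deliberately omitted
(toolkit-unstable, and the benchmark never generates tautomer duplicates).

## Multitask threshold classifier

One model per receptor: a single shared ReLU hidden layer (64 units) with
five sigmoid heads, one per threshold, trained with masked, class-weighted
binary cross-entropy (Adam, lr 1e-3, 60 epochs, batch 128, L2 1e-6),
implemented directly in numpy. The shared trunk reflects that the five
tasks are nested views of one latent potency; inverse-class-frequency
weighting matters because the 1 nM task is rare-positive. A task missing an
entire class is masked and predicts its empirical prior. All randomness
passes through a single recorded seed; training and prediction are
reproducible to the bit, and model archives reload to identical
predictions.

Defaults were sized for ~2000 training molecules with 2048-bit inputs; at
that scale training one receptor takes a few seconds on one CPU. Validation
AUROC per task is computed on a held-out split (random by default; a
Bemis–Murcko scaffold split is available and is the more honest protocol
when scaffold novelty matters) and stored in the manifest.

**Monotonicity** of the five probabilities is enforced post hoc by
least-squares isotonic projection (pool-adjacent-violators, equal weights),
computed from the minimax characterization. The projection is idempotent
and leaves already-monotone profiles exactly unchanged, which makes it
testable against an independent oracle; an architectural monotonicity
constraint would be neither.

## Scores and funnel

Activity score: P(D4 ≤ 10 nM). Selectivity score (product mode, the
default everywhere):

S = P(D4 ≤ 10 nM) · (1 − P(D2 ≤ 1000 nM)) · (1 − P(D3 ≤ 1000 nM)) · (1 − P(D5 ≤ 1000 nM))

This is the probability of 100-fold selectivity under independence of the
four predictions. A `min` mode (worst single anti-target) is available
behind a flag. Product mode implies S ≤ activity score, annihilation by any
certain off-target activity, and monotone response to each component.

Because S composes four predictions, per-prediction error accumulates: for
a funnel-passing profile (activity 0.9, anti-target probabilities 0.1),
independent Normal(0, 0.1) noise on each component roughly doubles the
variance of S relative to the activity score alone (measured ratio ≈ 2.07).
The inequality is profile-dependent — at large anti-target probabilities
the product's small mean deflates its variance — so the package's check
fixes the profile in the regime the funnel actually advances.

Funnel semantics follow the campaign they model verbatim: activity cutoff
0.8 inclusive ("at or above"), selectivity cutoff 0.4 strict ("exceeding"),
selection quota 89. "Preference" for dual passers is operationalized as
strict two-tier ranking: all dual passers (by selectivity, then activity,
then id), then activity-only passers; molecules failing the activity filter
are never selected, so the selection can be smaller than the quota. The
ranking is independent of the screening batch size.

## Synthetic benchmark

The generator defines the study conditions; it is not a tuning dial.

**Library.** Molecules are assembled from a fragment grammar — six diamine
cores (2,7-diazaspiro[3.5]nonane, piperidine, piperazine, homopiperazine,
2,6-diazaspiro[3.3]heptane, 4-aminopiperidine) × 18 north (acyl/aryl) caps
× 16 south (benzyl/heteroaryl) caps — enumerated exhaustively, then
extended with random aromatic decorations (F, Cl, Me, OMe) until the
requested count of unique canonical structures is reached. This emulates a
make-on-demand deck's combinatorial structure: dense scaffold families,
near-neighbours differing by one substituent.

**Ground truth.** True pIC50 per receptor is linear in fingerprint bits,
pIC50_r(x) = bias_r + w_r·x, so that a classifier of the implemented family
can in principle learn it (recovery tests are meaningful) while remaining
nontrivial. Weights are constructed against the library's bit-frequency
spectrum:

- 2 *activity bits* (frequency band 5–9%, effect ≈ +2.5 log units on all
  four receptors): the correlated "binder" pharmacophore. Cross-receptor
  correlation is the central realism requirement — most binders hit all
  subtypes.
- 2 *D4-private bits* (band 3.5–6.5%, ≈ +2.3 on D4 only, scaled by
  `d4_private_scale`): the rare selectivity-carrying chemotypes. Setting
  the scale to 0 removes the selective class entirely.
- 2 *decoy bits* (band 6–10%, ≈ +2.0 on D2/D3/D5 only).
- A dense random background, shared across receptors (SD 0.5 log units)
  plus per-receptor variation (SD 0.25), normalized by mean bits-on.
  Decorations perturb bits and hence potency — mild activity cliffs.

Bits are drawn with a pairwise co-occurrence (Jaccard < 0.3) constraint so
the carriers are distinct fragment families. Baseline potency is 3.4
(≈ 400 µM): the deck is mostly inactive. At these defaults, across
generator seeds the deck's 10 µM hit base rate is ≈ 0.13–0.23 and the true
≥100-fold-selective fraction ≈ 0.6–8% (3.5% at the default seed 17). The
selective class was kept "rare but populous enough" deliberately: pushing
it below ~1% made some landscapes degenerate (no selective molecules in a
20,000-deck, or no funnel passers), which turns rate estimates from an
89-compound selection into noise.

**Assays.** One simulated IC50 per training molecule × receptor: true
log-potency plus Normal(0, 0.3 log units), censored outside [1, 10000] nM
as `lt`/`gt` bounds — matching the span of the label thresholds.

**Training-set composition.** Real confirmatory tables are heavily
potency-enriched (dose–response follow-up happens only for primary-screen
actives). The benchmark therefore samples its 2000 training molecules from
a held-out pool of 6000 with inclusion probability
sigmoid((best-receptor pIC50 − 5.5)/0.6) + 0.02, while the 20,000-molecule
deck is an unbiased draw, structurally disjoint from training (asserted at
build time). Without this bias the 10 nM task would have almost no training
positives, which no real campaign's training set resembles.

**What the benchmark does not show.** Real decks are ~10^4–10^5× larger
and chemically broader; real potency is not linear in fingerprint bits;
real assay heterogeneity (protocols, labs, genotypes such as D4.2/D4.4/
D4.7) is not modelled; descriptor and architecture choices are a surrogate,
not a reconstruction, of any particular production model. Passing here
demonstrates that the pipeline's logic — labelling, masking, monotone
composition, ranking, selection, evaluation — is correct and that the
learner recovers a learnable landscape; it does not predict real-world hit
rates.

## Pharmacology calculators

Percent inhibition at single-point concentration c: 100·c/(c + IC50)
(one-site occupancy; exactly 50% at IC50 = c). The 50%/85% thresholds at
10 µM are the two hit tiers used in evaluation. Cheng–Prusoff:
Ki = IC50/(1 + [L]/Kd), always below the IC50 for positive [L]. The ratio
[L]/Kd ≈ 2.65 inferred from one reported IC50/Ki pair (84 → 23 nM)
reproduces the other reported pairs within 10%, consistent with a single
assay condition across measurements.

## Evaluation

Hit rates of a selection (50% and 85% tiers), the ≥100-fold-selective rate,
and enrichment factors versus the screened deck's base rates. Empty
selections report NaN sentinels, never 0. The resampling null (1000 random
same-size selections) centres at enrichment 1 and calibrates the funnel's
gain. The per-anti-target breakdown reports the fraction of the selection
with a 100-fold margin over each anti-target alone versus all three
jointly; the gap reproduces the qualitative failure mode of compounds
selective against only a single off-target subtype.

## Problem sizes

Defaults everywhere: 2000 training molecules, 20,000-molecule deck,
26,000 generated structures, five threshold tasks × four receptors. The
full campaign (generation, featurization, four trainings, screening,
evaluation, nulls) runs in a few minutes on one CPU.
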