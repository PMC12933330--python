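# Methods

## Overview

`linkergen` designs PROTAC linkers by coupling a recurrent SMILES language
model with Monte Carlo tree search (MCTS), steering generation toward
candidates whose assembled PROTACs are predicted to be membrane-permeable
while remaining PROTAC-like under a structural filter cascade. A PROTAC here
is POI ligand — linker — E3 ligand; the linker is the generated object, a
molecular fragment carrying exactly two dummy-atom attachment markers (`*` in
SMILES), and each ligand carries one.

## Molecular representation and assembly

Linkers are parsed leniently with respect to valence at the markers: a marker
stands in for a future single bond, so a string like `*F*` is accepted at
parse time and rejected only when assembly produces an impossible molecule.
Syntax errors are rejected immediately. Assembly bonds the first marker (in
the linker's SMILES reading order) to the POI ligand's marker neighbour and
the second to the E3 ligand's, removes the four dummy atoms, and
re-sanitizes; a valence violation or a disconnected result raises an
assembly error. An optional flag retries the reversed orientation. One
canonical form — RDKit canonical SMILES with stereochemistry stripped — is
used for all identity comparisons and deduplication.

**Linker length convention.** `path_length` counts heavy atoms on the
shortest path between the two markers, excluding the markers themselves
(`*CCOCC*` has path length 5). The length filter's threshold of 15 is
interpreted in this convention; both the threshold and the convention are
configurable.

## Fingerprints

Morgan fingerprints, radius 2. Two flavours are used: count-based folded to
500 dimensions (regression features) and bit-based at 2048 dimensions
(similarity and applicability-domain checks). Widths below the 2048 hashing
base are produced by index-modulo folding — counts are summed across aliased
indices, so the total count is conserved; bits are OR-ed. Tanimoto
similarity is computed as sum(min)/sum(max), which reduces to the standard
bit Tanimoto on 0/1 vectors.

## Permeability model

The target is log10 of the Caco-2 apical-to-basolateral apparent
permeability in μcm/s. Data curation resolves left-censored entries "<x"
to the midpoint surrogate x/2 (so "<2" becomes 1 μcm/s) before the log
transform; censored records enter training at that surrogate with no
censored-likelihood treatment. The transwell utility formula
P_app = C·V/(T·A·C0) (receiver concentration × receiver volume / time ×
area × donor concentration) is provided for converting raw assay readouts.

The default regressor is a gradient-boosted tree quantile ensemble on the
count-500 fingerprints: one squared-error model for the predictive mean plus
one pinball-loss model per requested percentile (default 10/30/50/70/90).
Quantile crossing is resolved by sorting the per-level predictions;
percentile queries at other levels interpolate linearly and clamp at the
outermost trained levels. Of the two installed gradient-boosting stacks,
scikit-learn's `GradientBoostingRegressor` recovers the synthetic fixture
rule substantially better than LightGBM at the n ≤ 80 sample sizes this
package targets (LOOCV R² 0.91 vs 0.83 noise-free), so it is the default;
LightGBM remains available behind the same registry, and external
regressors (e.g. a prior-data fitted network) can be plugged in via
`register_regressor`.

Evaluation is leave-one-out cross-validation (LOOCV), the standard choice at
these sample sizes; metrics are R², Pearson r, and RMSE in log10 units,
computed on the pooled held-out predictions. The identity
R² = 1 − n·RMSE²/SST holds by construction and is asserted in tests.

## Filter cascade

Three presets of increasing stringency, evaluated in a fixed order with
short-circuiting at the first failure; every evaluated filter is recorded in
an auditable report.

| preset | filters |
|---|---|
| relaxed | attachment-point (exactly 2 markers), linker-validation (assembly succeeds), radical-atom |
| intermediate | relaxed + ring-structure (only 5–6-membered rings), branched-structure, alert-substructure, specific-substructure |
| strict | intermediate + linker-length (≤ 15), linker-similarity (≥ 0.3 to the generator corpus), applicability domain (≥ 0.1 to the model's training PROTACs) |

**Boundary semantics.** Exclusions are phrased as "below 0.3" and
"exceeded 15", so boundaries are inclusive-pass: similarity exactly 0.3,
path length exactly 15, and AD similarity exactly 0.1 all pass. This is
configurable.

**Branched-structure rule.** A linker fails when any branch off the
marker-to-marker shortest path contains a run of two or more consecutive
atoms (a methyl passes, an ethyl fails). Atoms of a ring are exempt when the
ring itself is traversed by the shortest path (shares at least two atoms
with it). The run length of a branch is the longest simple chain inside the
off-path component; the implementation is validated against a brute-force
networkx enumerator on the fixture corpus.

**SMARTS lists.** The alert filter ships a curated, conservative list of
~50 canonical structural alerts (reactive, unstable, or redox-active
motifs), and the specific-substructure filter a short list of synthetically
challenging motifs (acetals/aminals, O–O, N–N–N, enol ethers, hemiaminals,
α-halo ethers, anhydrides). Both are plain-text files, one pattern per
line, and are user-replaceable through the run configuration; a preset
override can drop the alert filter entirely. These default lists are the
package's own; they stand in for externally maintained alert collections
and make no claim of equivalence to any of them.

## Generator

**Tokenizer.** Regex-based: bracket atoms, `Cl`/`Br`, and two-digit ring
closures are single tokens; unknown symbols raise. Round-trip lossless over
any corpus the vocabulary was built from.

**Policy.** A token-level language model: embedding (32) → single tanh
recurrent layer (64) → softmax, trained by full-sequence backpropagation
with Adam (lr 5e-3, gradient-norm clip 5), implemented in NumPy. This keeps
training bit-deterministic for a fixed seed and is fast at the corpus sizes
targeted here (thousands of strings × tens of tokens). Training corpora are
augmented with up to 4 randomized SMILES rewritings per linker
(exact-string duplicates removed), which regularizes the model and
multiplies the effective corpus.

**Reward.** A left-sided Gaussian of the predicted mean log10 P_app of the
assembled PROTAC: reward 1 at or above μ = 0.25 (≈ 1.8 μcm/s), decaying as
exp(−(x−μ)²/2σ²) with σ = 1 below. Candidates failing the filter cascade
receive reward 0 — they still consume budget and update the tree, which
penalizes dead regions of token space. Duplicate strings are re-logged but
scored from a cache.

**Search.** MCTS over token prefixes: UCB1 selection (c = 1.0; unvisited
children first, ties to the lowest index), expansion with the policy's
top-10 next tokens, temperature-1 policy rollout to the end token (length
cap 80), and reward backup along the selection path. One generated string
per iteration; the budget counts generated strings, with an optional
valid-only counting mode.

Expansion additionally drops tokens whose policy probability is below
`min_expand_prob` (default 0.02). Without this pruning, UCB1's
visit-every-unvisited-child-first rule spends most of the budget visiting
token continuations the language model considers ungrammatical, and the
mean reward *decreases* over a run; with it, the fixture-scale reward
moving average climbs from ≈0.72 to ≈0.95 over a 2,000-candidate run. The
value was chosen from a small grid on the fixture setup and is
configurable.

## Analysis

Trailing moving averages (prefix windows averaged over available history)
for reward trends; top-k selection deduplicates by canonical SMILES before
ranking, ties broken by earlier generation index. Diversity clustering is
k-medoids on 1 − Tanimoto distance (bit-2048 fingerprints): k-medoids++
greedy seeding under the run seed, PAM-style assign/update alternation,
then steepest-descent single-medoid swap refinement until no exchange
lowers the total cost — so the result is a swap-local optimum and the cost
history is non-increasing. A Euclidean-on-counts metric is available.

## Synthetic fixtures

The fixture corpus composes linkers from a weighted grammar over chain
units — `CC` (alkane), `CCO` (PEG), `C(=O)N` (amide), and a
1,4-cyclohexylene insert — flanked by two markers, with 2–7 units by
default (marker-to-marker lengths ≈ 4–21, so a realistic minority exceeds
the 15-atom cap). This emulates the PEG/alkane/amide motifs that dominate
real PROTAC linkers, but not their full chemistry: no heteroaromatic
spacers, no triazoles, no stereochemistry, and far less scaffold diversity
than a curated database. Tests passing on fixtures therefore demonstrate
mechanism correctness and recovery capacity, not performance on real
PROTAC data.

The fixture permeability rule is linear in two descriptors of the
assembled PROTAC: log10 P_app = 1.2 − 0.35·(#H-bond donors) −
0.08·max(0, #rotatable bonds − 8) + N(0, σ). It mirrors the qualitative
beyond-rule-of-five observation that H-bond donors and flexibility depress
membrane permeability, and places typical fixture PROTACs on both sides of
the reward shoulder at 0.25 so that the reward discriminates. A
configurable fraction of records is emitted left-censored (the
lowest-permeability ones, emulating quantification limits), with the "<x"
string chosen so that the x/2 surrogate equals the intended target. The
generator returns both the noisy targets and the noise-free truth for
parameter-recovery tests.

Default fixture ligands are small alert-free fragments: an
acetanilide-like POI warhead and a morpholine-bearing E3 surrogate. They
are synthetic stand-ins, not actual degrader ligands.

## Problem sizes and numerical choices

Desk-scale runs use a 300-linker corpus (augmented ×4 ≈ 1,400 strings, 20
epochs), 60–80-compound permeability fixtures, search budgets of 500–2,000,
and 10-seed repetitions — sizes chosen so the full suite and the acceptance
script each complete in minutes on one CPU while still exercising every
code path at meaningful scale. Degenerate inputs are defined errors:
datasets below 3 records, empty corpora, empty reference sets, k greater
than n. All randomness flows from integer seeds (NumPy `default_rng`,
tree-ensemble seeds, RDKit randomization seeds); repeated runs at a fixed
seed are byte-identical.

## Known limitations

- The permeability model is trained on tens of compounds; its predictive
  distribution is a quantile-ensemble approximation, not a calibrated
  posterior.
- The policy is a small single-layer recurrent network; it produces some
  syntactically invalid strings, which the cascade absorbs by design.
- The alert/specific SMARTS lists are curated defaults, not a maintained
  medicinal-chemistry knowledge base.
- Generation is stereochemistry-blind, and no 3D/ternary-complex
  information enters the reward.
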