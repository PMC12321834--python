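# Methods

## Model

The classifier is a communicative message passing network over directed
molecular graphs. Hydrogens are implicit (encoded as attached-H counts);
every chemical bond yields two directed edges carrying identical bond
features; each directed edge stores the index of its reverse (an
involution). Atom features are the de-facto standard of directed
message-passing models: element one-hot over {C, N, O, S, F, Cl, Br, I, P,
B, Si, Se} plus an "other" slot, total degree, formal charge, chiral tag,
attached-H count, hybridization, aromaticity flag, and atomic mass scaled by
1/100. Bond features are bond-order class (single/double/triple/aromatic),
conjugation, ring membership, and stereo class. Feature widths are fixed per
run and recorded in checkpoints.

Message passing (K rounds, default K = 3):

- m_v^t = Σ_{u→v} h_{u→v}^{t−1}; isolated atoms (single-atom species, ions)
  receive the zero vector, so monoatomic molecules remain legal inputs.
- b_v^t = element-wise max over incoming edge states, zero when there are
  none. The boosted message is m′ = m ⊙ b.
- Node update h_v^t = ReLU(W_node [h_v^{t−1} ‖ m′ ‖ b]) — a single
  bias-free rectified linear layer. The three-way concatenation (including
  b explicitly) is the default; a two-way variant [h ‖ m⊙b] is available via
  `ModelConfig(booster_in_concat=False)` and exercised in tests.
- Edge update h_{u→v}^t = h_{u→v}^{t−1} + ReLU(W_e [h_v^t ‖ h_{u→v}^{t−1}]),
  using the *target* node state; the reverse-edge subtraction of the older
  directed-MPNN lineage is deliberately not applied. Because the residual
  is rectified, edge states are component-wise non-decreasing across
  rounds — a tested invariant. The edge update is skipped after the final
  node update, where its output could not be consumed.

Readout runs a GRU over a molecule's node states in canonical atom order
(atoms and bonds are renumbered through the molecule's canonical ranking at
graph construction, so spelling variants of the same SMILES give identical
graphs and embeddings) and sums the per-step outputs into h_mol. The head is
a two-layer perceptron with dropout before each linear layer and a sigmoid
output. Message-passing linear maps carry no offsets (mirroring the
bias-free configuration of the reference setup); the GRU's internal gate
offsets and the head offsets b₁, b₂ are retained, as they are part of the
standard GRU cell and the printed head equation respectively.

## Numerical core

The network is implemented on a small reverse-mode autodiff engine over
NumPy float64 arrays (`cmpnntox/nn/autodiff.py`) providing dense ops, row
gather, and segment sum/max reductions. The segment-max backward splits the
gradient equally among tied maxima — a symmetric subgradient; with
continuously distributed activations ties have probability zero. Gradients
of every op and of the composed forward pass are verified against central
finite differences in the test suite. Two forward implementations share one
parameter set: the vectorized batched path (training) and a nested-loop
reference exposing each step; their agreement to 1e-5 (observed ~1e-15) on
all fixture molecules is a standing test, as is batching invariance (the
GRU recurrence is masked per molecule, so no state crosses molecules).

## Training

Binary cross-entropy (numerically stable log-sum-exp form) is minimized
with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 50, at most 60
epochs. The learning rate rises linearly from 1e-4 to 1e-3 over 2 warm-up
epochs (per-step scheduling) and then decays exponentially, with the decay
rate solved so the last scheduled step lands exactly on 1e-4. Early stopping
monitors validation AUC with patience 10; the best-validation parameters are
returned. All randomness — Glorot initialization, batch shuffling, dropout —
flows from the single run seed, making training logs bit-reproducible.
Default hyperparameters follow the reference configuration record
(hidden 300, depth 3, bias-free, two FFN layers); 256 is a documented grid
candidate for the hidden width.

## Evaluation protocol

Nested cross-validation: a seeded shuffle partitions the indices into five
disjoint outer folds; each serves once as the test set. Within each outer
loop, five inner draws of 12.5% of the outer-training indices (10% of the
total) provide validation sets for tuning/early stopping. Partition
invariants (outer folds disjoint and covering; inner validation disjoint
from outer test) are asserted on every evaluation run. An alternative
single 0.7:0.1:0.2 split is provided for quick experiments. Fold statistics
are aggregated as the arithmetic mean and the *sample* (n−1) standard
deviation — the convention that reproduces 0.946 ± 0.013 from the five
reference fold AUCs (the population form would give 0.012) — and rounded to
three decimals for display.

Metrics are computed from first principles: confusion counts at threshold
0.5 (exposed as a flag; score ≥ threshold predicts toxic), ACC, balanced
accuracy, sensitivity/specificity, F1, Cohen's κ via observed/chance
agreement, MCC (0 with a warning when its denominator vanishes), and AUC by
the trapezoidal rule over a ROC built from a descending sweep of distinct
scores with ties grouped. Trapezoidal AUC is tested to agree exactly with
brute-force Mann–Whitney pair counting (ties counted ½) and with the
scikit-learn implementation, which serves only as an oracle.

## Baselines

The eleven classical comparators (decision tree, k-NN, linear SVM,
Bernoulli naive Bayes, logistic regression, random forest, AdaBoost,
gradient boosting, extra trees, LightGBM, XGBoost) run on 2,048-bit ECFP4
fingerprints over the identical fold plan as the network. They use the
library defaults of their standard implementations; the resolved values are
recorded in run manifests. The linear SVM exposes probabilities through
`SVC(kernel="linear", probability=True)`.

## Synthetic data

The generator assembles molecules by concatenating valence-safe SMILES
fragments (a chain of neutral extenders closed by a terminator), which
guarantees parseable output without a sanitization loop. A molecule whose
structure matches any planted toxicophore — aromatic nitro or phthalate
diester SMARTS by default — has true label 1; labels then flip independently
with probability ε (default 0.05). Class balance is steered by Bernoulli
draws of the intended class (default 0.5, emulating a 51/49 reference
composition); generation is fully deterministic under the seed, and a
ground-truth sidecar records the rule. A substructure-lookup classifier
attains AUC 1.0 at ε = 0 — the learnability ceiling against which trained
models are judged.

What the generator does *not* emulate: real structural diversity (scaffold
families, stereochemistry, charged/organometallic species), activity
cliffs, and any toxicological mechanism. Passing the recovery tests shows
the pipeline can learn a planted substructure rule under label noise; it
does not certify predictive accuracy on real reproductive-toxicity data.

## Problem sizes and desk-scale choices

The package targets single-CPU desk scale. The planted-rule recovery runs
(tests and acceptance script) use n = 500 molecules, ε = 0.05, hidden width
64, at most 30 epochs, with a 350/50/100 train/validation/test split —
chosen as the smallest configuration at which the rule is comfortably
learnable. The reference-composition stand-in (2,154 compounds) exercises
bookkeeping and descriptor medians at the composition of the reference
compound list, whose actual structures are not distributed with the
package; all quantities derived from it are labelled as stand-in values.

## Descriptors and fingerprints

Fingerprints are binary Morgan/ECFP4, radius 2, 2,048 bits. Descriptors:
molecular weight (Da, standard atomic masses), TPSA (Å², topological
contribution scheme), Crippen atom-contribution logP, Lipinski H-bond
donor/acceptor counts, rotatable bonds — the toolkit defaults matching the
reference environment. SMILES are parsed as-is (no desalting or
standardization); an opt-in largest-fragment reduction exists. Unparseable
SMILES are dropped with a logged warning and counted rather than aborting a
screen. Medians use the midpoint-of-central-order-statistics convention for
even n.

## Known limitations

- 2-D graphs only: stereochemistry enters solely through chiral-tag and
  stereo-class features; no conformers or spatial relationships.
- The edge update follows the literal printed recurrence (target-node
  state, no reverse-edge exclusion); other readings of that recurrence
  exist in the directed-MPNN literature.
- Baseline hyperparameters are library defaults, not tuned replicas.
- Checkpoints are platform-reproducible, not cross-platform-bitwise.
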