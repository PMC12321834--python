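# cmpnntox

Reproductive toxicity — a chemical's capacity to impair fertility or
development — is increasingly assessed *in silico* before any animal study.
`cmpnntox` is a toolkit for building such predictors from SMILES strings. It
implements a **communicative message passing neural network (CMPNN)** for
binary toxicity classification of small organic molecules, together with the
full protocol around it: molecular-graph featurization, Morgan/ECFP4
fingerprints and physicochemical descriptors, eleven classical fingerprint
baselines, repeated nested cross-validation, and the complete
binary-classification metric suite (AUC, ACC, balanced accuracy,
sensitivity/specificity, Cohen's κ, MCC, F1). It is aimed at computational
toxicologists and cheminformaticians who want a transparent, fully tested,
CPU-only reference implementation at desk scale.

## The model

A molecule is a directed graph G = (V, E): atoms are nodes, each chemical
bond contributes the two directed edges u→v and v→u. Starting from projected
atom/bond descriptors h_v⁰ and h_{u→v}⁰, each of K rounds performs:

1. **Message aggregation** m_v = Σ_{u→v∈E} h_{u→v}
2. **Message booster** b_v = max_{u→v∈E} h_{u→v} (element-wise), and
   m′_v = m_v ⊙ b_v — the most informative bond contributions are amplified
3. **Node update** h_v = ReLU(W_node · [h_v ‖ m′_v ‖ b_v]) (bias-free)
4. **Node–edge communication** h_{u→v} ← h_{u→v} + ReLU(W_e · [h_v ‖ h_{u→v}]),
   a rectified residual that lets atom and bond representations co-evolve

After K = 3 rounds a GRU is run over the node states in canonical atom order
and its outputs are summed into a fixed-length molecular embedding h_mol;
the head ŷ = σ(W₂ ReLU(W₁ h_mol + b₁) + b₂) yields the toxicity probability.
Training minimizes binary cross-entropy with Adam under a linear-warm-up /
exponential-decay learning-rate schedule (1e-4 → 1e-3 → 1e-4) with early
stopping on validation AUC. The network and its training loop are implemented
on a small NumPy reverse-mode autodiff core (`cmpnntox.nn.autodiff`); a
plain nested-loop reference implementation of every message-passing step is
shipped alongside and used to verify the vectorized path.

## Worked example

Generate a synthetic 300-compound dataset with a planted, noisy
structure–toxicity rule (nitroaromatic / phthalate-diester toxicophores,
5% label noise), then run the nested cross-validation:

```bash
cmpnntox simulate --n 300 --seed 7 --outdir demo
cmpnntox crossval --data demo/dataset.csv --outdir demo/cv \
    --seed 7 --epochs 15 --hidden-size 64
```

which prints (abridged):

```
                    mean    std
auc                0.941  0.041
acc                0.850  0.115
balanced_accuracy  0.843  0.126
sensitivity        0.931  0.033
specificity        0.755  0.223
kappa              0.688  0.244
mcc                0.700  0.231
f1                 0.872  0.085
```

Mean held-out AUC 0.941 across the five outer folds means the network
recovers the planted substructure rule almost up to the 5%-label-noise
ceiling; κ and MCC around 0.7 indicate strong chance-corrected agreement.
Other subcommands: `descriptors` (six physicochemical descriptors with
per-class medians/quartiles), `baselines` (the eleven classical classifiers
on 2048-bit ECFP4 fingerprints over the identical fold plan), `train` /
`predict` (single-split training and checkpoint scoring), `report`
(per-fold AUC aggregation).

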