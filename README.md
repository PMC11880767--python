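# kcatnet

Prediction of enzyme turnover numbers (k<sub>cat</sub>, s⁻¹) from protein
sequence, protein 3D-structure and substrate chemistry.

The turnover number is the maximum number of substrate molecules an enzyme
converts per unit time at saturation. Measured values cover only a small
fraction of known enzymes, so regression models that predict k<sub>cat</sub>
from sequence and structure are widely used in protein engineering and in
parameterising genome-scale metabolic models. `kcatnet` is a tested,
desk-scale implementation of a three-stream deep learning predictor for
log₁₀(k<sub>cat</sub>), together with the dataset preprocessing,
similarity-stratified evaluation and residue-level interpretation that such
models need. It is aimed at computational biologists who want a transparent,
fully reproducible reference pipeline they can run, test and extend without
GPUs or external downloads.

## The model

Each enzyme–substrate pair contributes three inputs:

* **Sequence stream.** The amino-acid sequence is split into overlapping
  n-grams (default n = 3), embedded, combined with sinusoidal positional
  encodings `PE(pos, 2i) = sin(pos / 10000^{2i/d})`,
  `PE(pos, 2i+1) = cos(pos / 10000^{2i/d})`, and passed through a
  transformer encoder built from multi-head scaled dot-product attention,
  `Attention(Q, K, V) = softmax(QKᵀ/√d_k) V`. This yields the hidden-vector
  set C = {c₁ … c_n}.
* **Structure stream.** The Cα trace of the protein structure becomes a
  contact map: residues i ≠ j are adjacent iff their Cα–Cα distance is
  strictly below 10 Å. Learned residue-type embeddings are propagated by a
  graph convolutional network, `H^(l+1) = σ(D̃^{-1/2} Ã D̃^{-1/2} H^(l)
  W^(l))` with Ã = A + I, and mean-pooled to a structure vector.
* **Substrate stream.** The SMILES string becomes a heavy-atom graph with
  per-atom environment tokens (radius-2 neighbourhood keys) and binary bond
  adjacency, processed by a dedicated GCN and mean-pooled to a substrate
  vector y.

The streams are fused by a neural attention mechanism: with
h = ReLU(W_inter·x + b) applied to both y and each c_i, the per-position
weights are a_i = σ(h_substrateᵀ h_i), the sequence stream is aggregated as
the a-weighted mean, and the concatenated embedding feeds a small dense head
that outputs log₁₀(k<sub>cat</sub>). Ablation modes (`sequence_only`,
`structure_only`, `substrate_only`) drop the other streams.

Evaluation uses R², RMSE (in log₁₀ units) and the Pearson correlation
coefficient; test sets can be stratified by maximum sequence identity to the
training set (0–50%, 50–90%, 90–100%), and dataset preprocessing removes
near-duplicate enzymes (identity > 90% on the same substrate, keeping the
longest sequence). Per-residue importance scores — min-max-normalised norms
of the structure-stream outputs — rank residues for comparison against
annotated binding/active sites.

## Worked example

The built-in generator creates a synthetic task in which log₁₀(k<sub>cat</sub>)
follows a linear rule over mean contact degree, substrate size and sequence
composition (plus Gaussian noise), so the pipeline can be exercised end to
end in about a minute:

```python
from kcatnet import KcatModel, ModelConfig, TrainConfig, make_synthetic_dataset

records, structures = make_synthetic_dataset(300, seed=7)
model = KcatModel(records, structures=structures, config=ModelConfig(seed=7))
results = model.fit(TrainConfig(epochs=15, seed=7))
print(results.summary())
```

```
kcat regression results
========================================================
mode:            full
d_model/heads:   32/4
layers (tf/gcn): 1/2+2
n-gram / radius: 3 / 2
contact cutoff:  10 Å
records:         train=240 val=30 test=30
epochs run:      15 (of 15)
final train MSE: 0.0027
--------------------------------------------------------
test R²:         0.8794
test RMSE:       0.4397  (log10 s⁻¹)
test PCC:        0.9385
========================================================
```

The model recovers most of the generating rule: held-out R² ≈ 0.88 means
~88% of the variance in log₁₀(k<sub>cat</sub>) is explained, and RMSE 0.44
says predictions are typically within a factor of ~2.8 of the true rate.
Per-record predictions come in both scales:

```python
print(results.test_predictions.head(3).to_string(index=False))
```

```
record_id  log_kcat  log_kcat_pred   kcat_pred
  syn0131  2.389103       1.615126   41.221718
  syn0264  4.604381       3.464298 2912.716834
  syn0243  2.685620       2.350991  224.383519
```

and `results.residue_weights("syn0131")` returns the per-residue weight
scores in [0, 1] used for functional-site interpretation.

The same pipeline is available from the shell:

```bash
kcatnet simulate --n 300 --seed 7 --out run/
kcatnet train    --data run/dataset.tsv --seed 7 --out run/model.ckpt.npz
kcatnet evaluate --model run/model.ckpt.npz --data run/dataset.tsv
kcatnet interpret --model run/model.ckpt.npz --data run/dataset.tsv \
                  --record-id syn0000 --out run/weights.tsv
```

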