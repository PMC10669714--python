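# confrna

Noncoding-RNA family classification from sequence alone, in the ConF
style: k-mer embeddings feed a parallel BiLSTM/CNN front-end, and the
resulting features pass through residual blocks whose skip connections
are *cross multi-head attention* fusions — the shallow features query
the deep ones and the attended disparity is added back to the shallow
path — with multi-scale dilated convolutions inside each block.

For: bioinformaticians who want a trainable, fully tested, dependency-
light (numpy + biopython) implementation of this architecture family,
plus the evaluation machinery around it — stratified ten-fold
cross-validation, per-family metrics, k-mer sweeps, robustness
protocols — and a synthetic ncRNA-family generator so everything runs
end to end without downloads.

## The model

A sequence over {A,C,G,U} becomes overlapping 2-mers, index-coded
lexicographically and padded/truncated to a 224-token window with a
learned 16-dim embedding.  Then:

```
tokens (224,) ── embed ──────────────────────────► 224×16
  ├─ BiLSTM, 16 hidden/direction ────► 224×32 ┐
  └─ CNN, two conv(5) layers, 96 filt ► 224×96 ┴─ concat ► 224×128
  ── MLP + attention residual ───────────────────► 224×128
  ── Block1: conv(16) ∥ conv(10,d=2) ∥ conv(18,d=2) ► 224×128
  ── downsample (lossless reshape) ──────────────► 112×256
  ── Block2: same kernels, 2× filters ────────────► 112×256
  ── global average pool ── FC ── softmax ───────► 13 families
```

Every residual is `x + MultiHead(Q=x, K=F(x), V=F(x))` with scaled
dot-product attention, softmax(QKᵀ/√d)·V per head.  The LSTM cell uses
the standard gates (f_t = σ(W_f·[h_{t−1},x_t]+b_f), …,
h_t = o_t ∗ tanh(C_t)); convolutions are same-padded and dilated where
noted.  Metrics are one-vs-rest per family — accuracy, sensitivity
TP/(TP+FN), precision TP/(TP+FP), F1 = 2TP/(2TP+FP+FN) — macro-averaged
by default.

Training and gradients run on a small reverse-mode autodiff engine over
numpy included in the package (`confrna.autograd`); there is no
framework dependency.  See `docs/methods.md` for the full model
description, design decisions, and limitations.

## Worked example

Generate a synthetic 4-family dataset, train one cross-validation fold
of a narrow configuration, and evaluate the held-out fold:

```python
from confrna import TrainConfig, make_folds, small_config, train_fold
from confrna.synthetic_data import easy_four_family_config, generate

dataset = generate(easy_four_family_config(seed=7))      # 800 sequences
plan = make_folds(dataset, n_folds=10, seed=7)           # stratified folds
result = train_fold(dataset, plan, fold_index=0,
                    model_cfg=small_config(),
                    train_cfg=TrainConfig(epochs=30, batch_size=64, seed=7))
print(f"epoch 1 loss {result.train_loss[0]:.3f} -> "
      f"epoch 30 loss {result.train_loss[-1]:.3f}")
print(f"held-out macro F1 {result.report.f1:.4f}, "
      f"accuracy {result.report.overall_accuracy:.4f}")
```

Output (a few minutes on one CPU):

```
epoch 1 loss 1.379 -> epoch 30 loss 0.029
held-out macro F1 0.9875, accuracy 0.9875
```

The loss falls from chance level (ln 4 ≈ 1.386) to near zero, and the
80-sequence held-out fold is classified almost perfectly — the planted
motif and composition signal in the synthetic families is strong by
construction.  The same objects drive the larger protocols:
`cross_validate` (full ten-fold rotation), `kmer_sweep` (k = 1/2/3 on
shared folds), and `robustness_protocol` (five disjoint-subset CVs).

The same workflows are available from the shell:

```sh
conf generate --config families.yaml --out data.fasta --labels labels.tsv
conf train --fasta data.fasta --small --epochs 30 --batch-size 64 --seed 7
conf cv --fasta data.fasta --small --n-folds 10
conf sweep-k --fasta data.fasta --small --ks 1,2,3
conf robustness --fasta data.fasta --small
conf predict --fasta new.fasta --checkpoint conf_out/checkpoint.npz \
             --families families.txt
```

FASTA headers carry labels as `>id|family`, or pass a two-column TSV
(id, family) via `--labels` / `label_source`.

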