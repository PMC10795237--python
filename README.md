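# mscan

A multi-scale self- and cross-attention classifier for RNA modification
site prediction from fixed 41-nt sequence windows, with a k-mer CBOW
embedding front-end, ablation variants, a full evaluation harness
(threshold metrics, AUROC/AUPRC, replicated t-tests, cross-modification
validation) and a synthetic motif-data generator so everything is
testable offline.

The network views each window at three centered scales (default order
21, 41, 31 nt). The first scale is the query stream; per encoder layer a
multi-head sublayer sums a self-attention branch with two cross-attention
branches toward the other scales, followed by a position-wise
feed-forward sublayer, both with residual connections and post-layer
normalization. A mean-pool + linear + sigmoid head emits the
site probability. Ablation variants (`SCAN`, `SAN`, `MCAN`, `CAN`) mask
subsets of the attention branches; `SAN` is the single-scale transformer
baseline.

Everything runs on numpy: the package ships a small reverse-mode
autograd engine (`mscan.nn`) and a self-contained CBOW word2vec trainer,
so no deep-learning framework is required and runs are bit-reproducible
from their seeds on one device.

## Layout

- `mscan.sequence_io` — labeled-window FASTA/TSV I/O, validation,
  padding/cropping, stratified k-fold splitting
- `mscan.kmer_embedding` — overlapping 3-mer tokenization, CBOW training
  (negative sampling), embedding lookup, word2vec-text persistence
- `mscan.multiscale_encoder` — subsequence extraction, positional
  encoding, attention/FFN building blocks, the model, variants,
  checkpoints, and the sequence-level `Predictor`
- `mscan.training` — BCE/Adam training loop with the tuned defaults
  (epochs 100, lr 5e-4, batch 10, dropout 0.2) and exhaustive grid search
- `mscan.evaluation` — confusion metrics, AUROC/AUPRC, Student t-test
  comparison, cross-modification matrix + heatmap
- `mscan.synthetic_data` — PWM-motif window generator (1:1 or 1:10
  ratios, shared/independent motif pairs)

## CLI

```sh
mscan synth --spec spec.yaml --out data/        # generate synthetic data
mscan data validate data/synthetic.fa
mscan data split data/synthetic.fa --k 5 --seed 1 --out-dir folds/
mscan embed train data/train.fa --dim 100 --seed 1 --out emb
mscan train --config cfg.yaml --data train.fa --out model.npz
mscan predict --model model.npz --in test.fa --out preds.tsv
mscan evaluate --model model.npz --data test.fa
mscan gridsearch --space space.yaml --data train.fa --k 5
mscan crossmod --models models/ --tests tests/ --out-dir cross/
```

FASTA headers carry the label and modification tag
(`>id|label=1|mod=m1A`); TSV is `sequence<TAB>label`. `T` is normalized
to `U` on ingestion; windows shorter than 41 nt are padded with a
contiguous `-` run at the head or tail.

A train config (`cfg.yaml`) mirrors the two config dataclasses:

```yaml
model: {d_model: 64, h: 8, d_k: 8, d_v: 8, d_ff: 256, layers: 3,
        scale_order: [21, 41, 31], d_embed: 100, variant: MSCAN}
train: {epochs: 100, learning_rate: 5.0e-4, batch_size: 10,
        dropout: 0.2, seed: 1}
```

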