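# seqembed

Interpretable embedding of encoder–decoder recurrent network hidden states,
with unsupervised clustering of sequence types, training-quality monitoring,
and temporal segmentation of long multi-activity sequences.

A GRU (or LSTM) sequence-to-sequence predictor is trained to continue
multidimensional time series. Its per-step encoder and decoder hidden states
are stacked into a global states matrix, embedded by column-centered SVD
(proper orthogonal decomposition) with singular-value-energy mode selection,
and the decoder-state trajectories — which self-organize into separable
attractors, one per sequence type — are clustered without labels. The same
embedding, rebuilt at training checkpoints, tracks how separability co-evolves
with the loss and flags over-fitting; slid along a long sequence it yields
unsupervised activity segmentation.

The recurrent model is implemented directly in numpy (hand-written
backpropagation through time, verified against finite differences in the test
suite) so everything runs on one CPU with no deep-learning framework.

## Layout

- `seqembed.synthetic` — deterministic generators: circles, ellipses, shifted
  and variable-rate circles, one-hot augmentation, composite multi-activity
  sequences with frame labels.
- `seqembed.cells` / `seqembed.seq2seq` — GRU/LSTM cells with BPTT; the
  encoder–decoder model (teacher-forcing-free decoding, full state capture),
  MSE loss, Adam training, checkpoints.
- `seqembed.embedding` — column centering, SVD with a deterministic sign
  convention, singular-value-energy mode counts, global states matrix,
  projection into the shared mode space.
- `seqembed.clustering` — K-means++ (restarts), agglomerative single-link
  cosine clustering, adjusted Rand index, Hungarian-matched accuracy.
- `seqembed.monitor` — embedding snapshots during training (losses, decoder
  ARIs, mode counts), optimal-iteration / over-fit detection.
- `seqembed.segmentation` — sliding-window scan, decoder-state collection,
  unsupervised frame labeling and frame-level accuracy.

## CLI

Every stage is a `seqembed` subcommand; data are plain CSV/JSON.

```sh
seqembed synth --kind circle-ellipse --te 50 --out data/
seqembed train --data data/ --units 16 --iterations 3000 --lr 5e-3 \
    --seed 0 --out run/
seqembed embed --model run/model.npz --data data/ --pcs 3 --out emb/
seqembed cluster --embedding emb/ --k 2 --method agglo --out labels.txt
seqembed monitor --data data/ --iterations 2000 --interval 100 --out mon/
seqembed synth --kind composite --te 50 --out comp/
seqembed segment --model run/model.npz --sequence comp/composite.csv \
    --k 3 --te 50 --td 50 --truth comp/composite_labels.txt --out seg/
```

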