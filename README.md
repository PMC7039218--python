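# emgnet

Gesture recognition from 8-channel surface EMG (Myo-armband-like, 200 Hz)
with a compact convolutional network over continuous-wavelet-transform
scalograms, plus classical feature-set baselines.

The pipeline:

1. **Recordings** — delimited-text recordings (one row per time step, 8
   numeric columns) or two-armband NinaPro-style MAT files; a synthetic
   generator produces labelled recordings with controllable class
   separation so everything runs without any dataset download.
2. **Segmentation** — optional transition trimming, then sliding windows
   of 52 samples (260 ms at 200 Hz).
3. **Frontend** — per-channel Mexican-hat CWT at 32 scales (a 32×52
   matrix), magnitudes mean-pooled (3×3 kernel, stride 2) to 15×25;
   stacking channels gives the (8, 15, 25) model input. An STFT
   spectrogram path is provided for parity.
4. **Model** — four 3×3 convolutions (stride 2 exactly where the channel
   width increases), channel-wise parametric rectifiers, adaptive mean
   pooling and a 1×1 convolution head; no fully connected layer. The
   default 7-class configuration has **exactly 34 311 learnable
   parameters** (see `scripts/width_search.py` for how the widths were
   frozen).
5. **Training** — Adam, lr 0.01 shrunk ×0.1 at epochs 20 and 40, 50
   epochs, batch 128, classic L2 penalty; per-class shuffled 60/10/30
   train/val/test split.
6. **Baselines** — TD (MAV/ZC/SSC/WL), enhanced TD (+RMS+AR4),
   NinaPro-style (RMS+TD+wavelet marginals) and SampEn feature sets
   feeding LDA / RBF-SVM classifiers.

The network is implemented on a small, fully tested NumPy engine
(`emgnet.nn`) — forward, backprop and Adam — so the package has no deep
learning framework dependency and is bit-reproducible from a seed.

## CLI

All commands read one YAML config and compose through artifacts in
`out_dir` (each writes a manifest with the config fingerprint and seed):

```sh
emgnet synth          -c run.yaml   # synthetic recordings + labels.tsv
emgnet preprocess     -c run.yaml   # windows -> scalogram tensors (.npz)
emgnet features       -c run.yaml   # classical feature CSVs
emgnet train-cnn      -c run.yaml   # checkpoint + per-epoch history
emgnet train-baseline -c run.yaml   # LDA/SVM on a chosen feature set
emgnet evaluate       -c run.yaml   # metrics.json + confusion.csv
emgnet report         -c run.yaml   # gather everything into report.json
```

Minimal config:

```yaml
seed: 1
out_dir: out
synthetic: {n_gestures: 7, repetitions_per_gesture: 5}
train: {epochs: 50}
```

## Layout

| module | role |
| --- | --- |
| `emgnet.synthetic_data` | seeded synthetic sEMG generator |
| `emgnet.signal_io` | readers, transition trimming, windowing |
| `emgnet.tf_frontend` | Mexican-hat CWT, STFT, downsampling, tensors |
| `emgnet.classic_features` | TD / enhanced TD / NinaPro / SampEn + LDA/SVM |
| `emgnet.network` | the compact CNN and its parameter budget |
| `emgnet.nn` | NumPy layers, backprop, Adam |
| `emgnet.training` | splits, lr schedule, training loop, metrics |
| `emgnet.benchmarks` | standard synthetic benchmarks |
| `emgnet.cli` | YAML-config command-line pipeline |
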