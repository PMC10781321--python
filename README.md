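# fogbci

Motor-imagery EEG command decoding for fog-deployed brain-computer
interfaces: a convolutional-LSTM latent encoder, random-forest command
classification, latent-space interpretability maps, and a discrete-event
comparison of fog-node versus cloud-only control latency.

## Who this is for

Researchers and engineers prototyping BCI control loops for cyber-physical
systems who need the full decoding chain — signal conditioning, feature
learning, classification, and deployment-latency analysis — runnable end to
end on synthetic data, with every stage reproducible from a seed.

## The method

A 4-channel EEG trial `x` (electrodes TP9, AF7, AF8, TP10 of the 10-20
system) is decoded into one of four command classes — left-foot imagery
(LF), left-hand imagery (LH), relaxation (RX), mental arithmetic (MA) — in
two stages:

1. **Latent encoding.** An encoder `f_enc` maps the band-passed trial to a
   16 x 21 real matrix (the *latent image*). The encoder is the surviving
   half of an autoencoder trained to minimize the mean squared
   reconstruction error

       f_enc, f_dec = argmin || X - (f_dec ∘ f_enc) X ||²

   over the training set `X`. Architecturally `f_enc` is a convolutional
   LSTM with 20 filters and kernel 2 along the electrode axis (hidden state
   3 x 20), whose final state passes through a single-filter 14 x 2
   transposed convolution: (3-1)+14 = 16 rows by (20-1)+2 = 21 columns.
   The decoder `f_dec` (training scaffolding only) reads the flattened
   latent sequence through a 2-unit LSTM and a stack of 1-D convolutions.

2. **Classification.** A random forest with 250 trees classifies the 336
   flattened latent pixels: `C = RF(f_enc(x))`. The forest is benchmarked
   against an RBF-kernel SVM (C = 1.0), a Gini decision tree, and gradient
   boosting (159 estimators, depth 4) on a shared stratified 80/20 split,
   with per-class precision/recall/F1 and accuracy.

Interpretability comes from per-class average latent images, their
log-positive transforms, and the forest's per-pixel Mean Decrease in
Impurity (Gini importance) map. A minimal discrete-event simulator compares
mean command latency when the encode-classify pipeline runs on a nearby fog
node versus a distant cloud node.

Because the consumer-headset dataset this method targets is not publicly
retrievable, the package ships a first-class synthetic generator that
emulates its structure: 4 channels, 4 balanced classes, pink-noise
background plus class-dependent band-power modulation (ERD/ERS style) in
the theta/alpha/beta bands, amplitudes within the physiological 0.5-100 µV
range. See `docs/methods.md` for what the generator does and does not
emulate.

## Worked example

```python
from fogbci import (
    SyntheticSpec, generate_dataset, preprocess_dataset,
    TrainConfig, train_autoencoder, evaluate_suite,
    compare_architectures,
)
from fogbci.classification import default_specs

spec = SyntheticSpec(n_records=200, separation=2.0, seed=7)
dataset = preprocess_dataset(generate_dataset(spec))

encoder, decoder, history = train_autoencoder(
    dataset, TrainConfig(epochs=30, batch_size=16, seed=0)
)
print(f"reconstruction loss: {history.first:.4f} -> {history.final:.4f}")

reports = evaluate_suite(dataset, encoder, default_specs(), split_seed=0)
for algo, rep in reports.items():
    print(f"{algo}: accuracy {rep.accuracy:.3f}")

latency = compare_architectures()
print(f"fog {latency['fog_mean_ms']:.1f} ms vs cloud {latency['cloud_mean_ms']:.1f} ms")
```

Output of this exact script:

```
reconstruction loss: 1.8723 -> 1.7255
RF: accuracy 1.000
SVM: accuracy 1.000
DT: accuracy 0.800
GB: accuracy 0.925
fog 11.7 ms vs cloud 107.7 ms
```

Reading the numbers: training reduces the mean squared reconstruction error
(the latent images become a usable compression of the trials); on held-out
synthetic trials the random forest decodes essentially every command, with
the decision tree weakest — and the 40 test trials are balanced, so chance
would be 0.25. The fog routing cuts mean command latency roughly ninefold
because the fog node sits 2 ms from the sensor while the cloud sits 50 ms
away with equal compute.

The same pipeline is scriptable from the shell:

```bash
fogbci generate --n-records 200 --separation 2.0 --seed 7 --out-dir data/
fogbci train-autoencoder --data-dir data/ --epochs 30 --out model.npz
fogbci benchmark --model model.npz --data-dir data/ --out report/
fogbci analyze-latent --model model.npz --data-dir data/ --out-dir maps/
fogbci simulate-fog --routing both
fogbci run-all --out-dir full_run/ --seed 7
```

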