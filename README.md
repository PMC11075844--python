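# emgbicoh

Bicoherence-based analysis of surface EMG for knee-pathology screening:
preprocess multichannel gait EMG, quantify quadratic phase coupling with
higher-order spectra, render the resulting bicoherence maps as images, and
classify Normal vs. knee-osteoarthritis (KOA) signals with a compact CNN
under a repeated random-subsampling protocol. A synthetic phase-coupled
EMG generator makes the whole pipeline testable end to end without
clinical data.

Intended users: biomedical-signal researchers who want a reproducible,
inspectable implementation of the bicoherence-image classification
pipeline — each stage is a scikit-learn-style estimator usable on its own.

## The statistic at the core

For a zero-mean signal segmented into K windows with spectra X_k, the
direct bispectrum estimate and its bounded normalization are

    b(f1,f2)   = (1/K) Σ_k X_k(f1) X_k(f2) X_k*(f1+f2)
    bic(f1,f2) = |b(f1,f2)| / sqrt( (1/K)Σ|X_k(f1)X_k(f2)|² · (1/K)Σ|X_k(f1+f2)|² )

`bic` lies in [0, 1] by Cauchy–Schwarz: it is 1 when the phase relation
φ(f1) + φ(f2) − φ(f1+f2) is constant across segments (quadratic phase
coupling, the signature of a quadratic nonlinearity) and decays as
1/sqrt(K) for independent phases — crucially, independent of the power at
the component frequencies. Gaussian signals have zero bispectrum, so the
map highlights exactly the nonlinear structure that ordinary power
spectra cannot see.

Pipeline: band-pass 30–300 Hz (6th-order Butterworth) → 60 Hz notch →
full-wave rectification → per-trial bicoherence map → 224×224×3 heatmap →
compact CNN (Adam, minibatch 32, ≤60 epochs) → seven metrics over five
random 70/15/15 train/validation/test splits → per-muscle ANOVA + Tukey
HSD. See `docs/methods.md` for every default and the reasoning behind it.

## Worked example

Bicoherence recovers the coupled fraction λ of a synthetic
phase-coupled signal (components at 60 and 90 Hz, sum tone at 150 Hz,
fs = 1500 Hz, 64 independent segments):

```python
from emgbicoh import QpcSpec, generate_qpc_signal, bicoherence, HosaParams

params = HosaParams(nfft=512, seg_len=512, overlap_frac=0.0)
for lam in (0.0, 0.5, 1.0):
    rec = generate_qpc_signal(
        QpcSpec(f1=60, f2=90, coupling=lam), 64 * 512, 1500.0,
        seed=1, block_len=512,
    )
    bic = bicoherence(rec, params)
    print(f"coupling={lam:.1f}: bicoherence(60, 90) = {bic.at(60, 90):.3f}  "
          f"(K = {bic.n_segments} segments)")
```

```
coupling=0.0: bicoherence(60, 90) = 0.121  (K = 64 segments)
coupling=0.5: bicoherence(60, 90) = 0.547  (K = 64 segments)
coupling=1.0: bicoherence(60, 90) = 1.000  (K = 64 segments)
```

The value at the coupled bin tracks λ: ~0.12 residual estimator noise at
λ=0 (the 1/sqrt(64) floor), ~1 at full coupling. The full pipeline runs
the same measurement on a 20-subject synthetic cohort whose two classes
differ only in λ (0.2 vs 0.9) and classifies the rendered maps.

## Command line

Each stage also runs from the shell on the previous stage's outputs:

```sh
emgbicoh synth --out work/sig --seed 0              # cohort + manifest
emgbicoh preprocess --manifest work/sig/manifest.csv --out work/pre
emgbicoh bicoh --manifest work/pre/manifest.csv --out work/maps
emgbicoh render --manifest work/maps/manifest.csv --out work/img
emgbicoh train --manifest work/img/manifest.csv --out work/metrics
emgbicoh report --scores work/metrics/scores.csv --out work/metrics
emgbicoh run --out work/full                        # everything at once
```

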