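# eegaad

EEG auditory spatial attention decoding: spectro-spatial feature maps plus
an auxiliary-classifier GAN for data augmentation and left/right
classification.

The package converts windowed multichannel EEG into 28×28 alpha-band
(8–13 Hz) topographic images — per-channel FFT band power, azimuthal
equidistant electrode projection, Clough-Tocher interpolation — and trains
a class-conditional GAN whose discriminator carries both a real/fake head
and an auxiliary left/right head. A synthetic-data module generates EEG
with a known hemispheric alpha-power asymmetry so the whole pipeline is
testable without any external dataset.

## Layout

| module | purpose |
|---|---|
| `eegaad.recording` | `EEGRecording` container; CSV/NPY + JSON sidecar and minimal EDF/BDF readers |
| `eegaad.montage` | unit-sphere montages (packaged 64/32-channel BioSemi layouts) and the azimuthal equidistant projection |
| `eegaad.ssf` | preprocessing (0.5 Hz high-pass, resample to 70 Hz, per-trial z-score), sliding decision windows, band power, interpolation, map normalization, HDF5 I/O |
| `eegaad.nn` | small numpy layer library (conv / transposed conv / batch norm / Adam) with full backprop |
| `eegaad.gan` | generator + discriminator builders, losses, adversarial training, sampling, classification, checkpoints |
| `eegaad.evaluate` | precision/recall/F/accuracy, ED/PCC/KLD similarity, noise robustness, rotation/scaling augmentation, McNemar's test, per-subject cross-validation |
| `eegaad.simulate` | synthetic EEG with configurable lateralization, SNR and 1/f background |
| `eegaad.pipeline` / `eegaad.cli` | end-to-end orchestration and the `eegaad` command |

## CLI

```sh
# simulate EEG and extract feature maps
eegaad simulate --n-per-class 20 --duration 2 --window 2 --out maps.h5

# train the (scaled-down) GAN and inspect it
eegaad train maps.h5 --epochs 20 --width-scale 8 --out ckpt/
eegaad generate ckpt/ --count 32 --out generated.h5
eegaad evaluate ckpt/ maps.h5
eegaad robustness ckpt/ maps.h5 --levels 1,3,5,7,9,11

# full pipeline (simulate -> split by trial -> features -> GAN -> reports)
eegaad run --config config.yaml --out artifacts/

# augmentation sweep and per-subject cross-validation
eegaad sweep --counts 0,16,32 --fractions 0.25,0.5,1.0
eegaad crossval --subjects 3 --maps-per-class 15
```

`width_scale` divides every channel width for desk-scale runs; at
`width_scale=1` the models match the reference architecture exactly
(generator FC 1,266,944 parameters, discriminator source head 8,193, …).

Real EEG can be supplied as EDF/BDF or as a channels×samples CSV/NPY
matrix with a JSON sidecar (`{"fs": ..., "channel_names": [...],
"label": "left"}`) via `eegaad ssf`.

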