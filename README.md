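# fricshape

Classification of fricative consonants into three place-of-articulation
groups — non-sibilant (/f, v, θ, ð/), alveolar (/s, z/) and palatal
(/∫, ʒ/) — from single 8-ms analysis frames, in quiet and in noise.

The pipeline: labeled audio (TIMIT-style WAV + `.phn` files, or the
built-in synthetic corpus generator) → RMS equalization → optional noise
mixing (speech-shaped noise for training, 12-talker babble for testing, at
exact SNRs) → per-frame features (spectral moments/peak/slope, MFCC,
gammatone filterbank outputs, FFT magnitudes) → optional linear or kernel
PCA → a grid-searched RBF SVM (one-against-one) → per-consonant majority
vote over frames → accuracy and confusion-matrix reports.

## Layout

| module | role |
| --- | --- |
| `fricshape.corpus_io` | WAV / `.phn` I/O, RMS equalization, token extraction |
| `fricshape.noise_mixing` | speech-shaped noise, synthetic babble, SNR mixing |
| `fricshape.frame_features` | 8-ms framing and the seven feature sets |
| `fricshape.dimred` | linear PCA and kernel PCA with threshold dimension selection |
| `fricshape.classification` | SVM training, grid-search CV, majority-vote decoding |
| `fricshape.evaluation` | accuracy, confusion matrices, Kruskal–Wallis screening, CI widths |
| `fricshape.synthetic_fricatives` | calibrated synthetic fricative corpora |
| `fricshape.pipeline` / `fricshape.cli` | end-to-end runs and the `fricshape` CLI |

## CLI

```sh
fricshape synth --n 100 --talkers 10 --seed 7 --out corpus/
fricshape mix --wav in.wav --snr 10 --masker ssn --seed 1 --out noisy.wav
fricshape train --corpus corpus/train --features gt14 --seed 3 --out model.pkl
fricshape classify --model model.pkl --wav corpus/test/xxx.wav --phn corpus/test/xxx.phn
fricshape run --out runs/demo --seed 42          # full experiment
fricshape evaluate --run-dir runs/demo
```

`fricshape run` accepts a YAML config (`--config`) mirroring
`fricshape.pipeline.RunConfig`; every random draw (corpus, masker
segments, training frames, cross-validation folds) is derived from the
single config seed, so reruns are bit-identical.

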