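# signfuse

Sign-language word recognition from multimodal single-arm recordings:
4-channel surface EMG plus a wrist inertial unit (3-axis acceleration,
3-axis angular velocity) at 1 kHz.

Words are modeled as short sequences of composite *(gesture, movement)*
states. The pipeline:

1. **Segmentation** (`signfuse.segmentation`) — sliding-window mean
   absolute value (MAV) envelopes with per-modality thresholds; a word
   segment is a maximal active run of the OR of the sEMG and ACC masks,
   so a brief mid-word muscle relaxation (dynamic words) does not split
   the word while it does split its gesture *stages*.
2. **Features** (`signfuse.features`) — two aligned observation streams
   per stage: per-window sEMG MAV (gesture stream) and per-window motion
   means + first differences (trajectory stream).
3. **Coupled HMM** (`signfuse.chmm`) — two-chain coupled hidden Markov
   model: each chain's next state conditions on both chains' previous
   states; emissions are per-chain diagonal Gaussians. Exact log-domain
   inference on the composite lattice, Baum–Welch EM with factorized
   M-steps, per-composite-state dwell scoring, and word classification
   by summing stage scores over lexicon candidates.
4. **Lexicon** (`signfuse.lexicon`) — the decomposition of words into
   stage states; a packaged 120-word fixture (45 SHGV / 52 DHGV /
   23 DGV over 9 gestures and 9 movement states incl. rest).
5. **Synthetic data** (`signfuse.synthgen`) — seeded generator of
   realistic recordings with ground truth (amplitude-modulated sEMG
   noise, smooth trajectory templates, per-subject channel gains,
   mid-word relaxation for dynamic words), so the whole pipeline is
   testable without the original study's data.
6. **Pipeline + CLI** (`signfuse.pipeline`, `signfuse.cli`) —
   orchestration, recording/model/report file I/O, per-category accuracy
   reporting (micro-averaged total).

## CLI

```sh
signfuse config --show-defaults
signfuse simulate --subjects 8 --out data/ --seed 1          # packaged lexicon
signfuse segment data/s00_w001.csv --out segments.json
signfuse features data/s00_w001.csv --start 0 --end 2000 --out feats.txt
signfuse train --manifest data/manifest.csv --lexicon data/lexicon.json \
               --seed 1 --out model.json
signfuse classify --model model.json --lexicon data/lexicon.json \
                  --recording data/s01_w001.csv
signfuse evaluate --manifest data/manifest.csv --lexicon data/lexicon.json \
                  --model model.json --out report
signfuse report --counts counts.json --out report
```

Recordings are CSV with a `# fs=1000` header line and columns
`t,semg1..semg4,accx..accz,avx..avz`; lexica and models are JSON;
reports are CSV + JSON (with confusion matrix).

## Python API

```python
from signfuse import load_default_lexicon, run_experiment

lex = load_default_lexicon()
report, trained, dataset = run_experiment(lex, n_subjects=8, seed=0)
print(report.to_frame())
```
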