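# chirplearn

Transfer-learning toolkit for bird sound classification from weakly labelled
recordings. It implements, end to end and at desk scale:

- **Spectrogram front-ends** — 3-second chunking and two log-mel
  configurations (16 kHz / win 400 / hop 160 / FFT 512 and 32 kHz / win 800 /
  hop 320 / FFT 1024, both yielding 298 frames for a 3 s input under
  no-center framing), plus a raw-waveform 48 kHz pass-through preset and a
  small `tiny` preset for fast experiments.
- **Waveform augmentation** — MixUp (probability 0.6, Beta-sampled mixing
  ratio) and background-noise addition (probability 0.5, SNR drawn from
  [3, 30] dB), applied on-the-fly to raw waveforms before spectrogram
  conversion.
- **Transfer strategies** — deep finetuning, shallow (head-only) finetuning,
  and teacher→student knowledge distillation with *consistent teaching*
  (teacher and student consume the identical augmented spectrogram batch).
  The distillation objective is `lam * L_g + (1 - lam) * L_kd` with the
  temperature dividing teacher logits only (defaults lam = 0.5, tau = 1.0;
  CE + softmax + KL for single-label, BCE + sigmoid for multi-label).
- **Weak labels** — class vocabularies with a dedicated noise class,
  multi-hot targets with or without secondary (background) species,
  species curation (≥ 10 recordings) and low/medium/high data-regime
  stratification (< 50 / 50–200 / > 200 recordings).
- **Segment selection** — a band-energy heuristic (500–10,000 Hz energy vs.
  the recording's median chunk) and a pluggable detector-score filter
  (keep when the score crosses 0.3).
- **Evaluation** — per-recording max pooling of chunk scores, single-label
  F1, per-class AP / mAP, macro AUROC, thresholded precision/recall
  (threshold 0.2), regime-stratified AP, and the foreground/background
  recall contrast on two-species recordings.
- **Synthetic data** — a download-free generator of focal recordings (loud
  target species, fainter and incompletely labelled background species),
  polyphonic soundscapes, noise-only clips, and a long-tailed Zipf-like
  recordings-per-species distribution, so every pipeline stage is testable
  offline.

The reference classifiers (a small strided CNN and a small patch
transformer, plus a matched-filter band-template model) run on a minimal
numpy autodiff core (`chirplearn.nn`) — no GPU or deep-learning framework
required. They are stand-ins that share one backbone/head contract; the
toolkit's subject is the transfer methodology, not any specific
architecture.

## CLI

```bash
# generate a synthetic corpus (WAV + annotations.csv + vocabulary + manifest)
chirplearn synth --seed 7 --out data/demo

# shallow-finetune a model, then evaluate with recording-level max pooling
chirplearn train --data data/demo --arch tiny_cnn --strategy shallow_finetune \
    --epochs 20 --seed 1 --out runs/shallow
chirplearn evaluate --checkpoint runs/shallow/model.json --data data/demo \
    --out runs/shallow/metrics.json

# distillation from a frozen teacher checkpoint
chirplearn train --data data/demo --arch band_template --out runs/teacher
chirplearn distill --data data/demo --arch tiny_cnn \
    --teacher runs/teacher/model.json --out runs/student

# energy-based segment selection
chirplearn select-segments --data data/demo --out segments.csv
```

Annotation CSV dialect: columns `recording_id, primary_species,
secondary_species, split`, with secondary species semicolon-joined and one
primary species per recording (no timing — weak labels). Checkpoints are
single-file JSON with a mandatory version field, the architecture config,
the class vocabulary (logit index i ↔ `classes[i]`), and the weights.

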