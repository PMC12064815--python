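"""Download-free synthetic corpus generator.

Emulates the statistical structure of community birdsong archives: focal
recordings with one loud target species and fainter background species,
incompletely annotated secondary labels, polyphonic soundscape clips,
noise-only clips for the dedicated noise class, and a long-tailed Zipf-like
recordings-per-species distribution. Calls are amplitude-enveloped
frequency-modulated tones — the point is pipeline behaviour, not
bioacoustic realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioClip, write_wav
from .augment import NoisePool
from .frontend import MelConfig, compute_mel
from .labels import (NOISE_CLASS, ClassVocabulary, RecordingAnnotation,
                     build_target, write_annotations)
from .models import BandTemplateModel

__all__ = [
    "SpeciesProfile", "SceneConfig", "Corpus", "make_profiles",
    "synthesize_call", "generate_noise_clip", "generate_focal_recording",
    "generate_soundscape", "generate_corpus", "write_corpus",
    "make_template_teacher", "to_training_examples",
]

FREQ_BAND_HZ = (500.0, 10_000.0)


@dataclass(frozen=True)
class SpeciesProfile:
    """Acoustic fingerprint of one synthetic species."""

    species_id: str
    base_frequency: float          # Hz, inside FREQ_BAND_HZ
    chirp_rate: float = 25.0       # vibrato/trill rate, Hz
    bandwidth: float = 40.0        # peak-to-peak frequency deviation, Hz
    call_duration: float = 0.4     # seconds

    def __post_init__(self):
        lo, hi = FREQ_BAND_HZ
        if not lo <= self.base_frequency <= hi:
            raise ValueError(
                f"base_frequency {self.base_frequency} outside [{lo}, {hi}] Hz")


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the synthetic corpus generator."""

    n_species: int = 12
    top_count: int = 250           # recordings for the most-recorded species
    zipf_s: float = 1.2            # long-tail exponent
    clip_seconds: float = 3.0
    sample_rate: int = 8_000
    call_amplitude: float = 0.3
    foreground_to_background_gain_db: float = 15.0
    secondary_label_completeness: float = 0.5
    polyphony_probs: tuple[float, ...] = (0.50, 0.25, 0.12, 0.07, 0.04, 0.02)
    noise_rms: float = 0.02
    noise_clip_fraction: float = 0.05
    test_fraction: float = 0.2
    freq_range_hz: tuple[float, float] = (600.0, 3_600.0)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.polyphony_probs) - 1.0) > 1e-9:
            raise ValueError("polyphony_probs must sum to 1")
        if not 0.0 <= self.secondary_label_completeness <= 1.0:
            raise ValueError("secondary_label_completeness must lie in [0, 1]")

    def species_counts(self) -> dict[str, int]:
        """Deterministic Zipf-like recordings-per-species table."""
        return {f"sp{i:03d}": max(1, round(self.top_count * (i + 1) ** -self.zipf_s))
                for i in range(self.n_species)}


def make_profiles(config: SceneConfig) -> list[SpeciesProfile]:
    """Evenly spaced base frequencies; pairwise distinct by construction."""
    lo, hi = config.freq_range_hz
    if hi > config.sample_rate / 2:
        raise ValueError("freq_range_hz exceeds Nyquist for the scene sample rate")
    bases = np.linspace(lo, hi, config.n_species)
    if config.n_species > 1 and bases[1] - bases[0] < 100.0:
        raise ValueError(
            f"{config.n_species} species do not fit {lo}-{hi} Hz with a "
            "100 Hz separation margin; widen freq_range_hz or reduce n_species")
    rng = np.random.default_rng(config.seed)
    profiles = []
    for i in range(config.n_species):
        chirp_rate = float(rng.uniform(15.0, 35.0))
        # modulation index = bandwidth / (2 * chirp_rate) kept below 0.7 so
        # the spectral peak stays at the carrier (base) frequency
        profiles.append(SpeciesProfile(
            species_id=f"sp{i:03d}",
            base_frequency=float(bases[i]),
            chirp_rate=chirp_rate,
            bandwidth=float(chirp_rate * rng.uniform(0.8, 1.4)),
            call_duration=float(rng.uniform(0.3, 0.6)),
        ))
    return profiles


def synthesize_call(profile: SpeciesProfile, sample_rate: int,
                    amplitude: float) -> AudioClip:
    """One call: Hann-enveloped tone with mild sinusoidal vibrato.

    The modulation index is kept below 1 so the spectral peak stays at
    ``base_frequency``. Deterministic: same profile, same waveform.
    """
    n = int(round(profile.call_duration * sample_rate))
    t = np.arange(n) / sample_rate
    deviation = profile.bandwidth / 2.0
    phase = (2 * np.pi * profile.base_frequency * t
             - (deviation / profile.chirp_rate)
             * np.cos(2 * np.pi * profile.chirp_rate * t))
    envelope = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    return AudioClip(amplitude * envelope * np.sin(phase), sample_rate)


def generate_noise_clip(config: SceneConfig, rng: np.random.Generator,
                        seconds: float | None = None) -> AudioClip:
    """Noise-only clip: white noise plus a low-frequency rumble component."""
    seconds = config.clip_seconds if seconds is None else seconds
    n = int(round(seconds * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    white = rng.normal(0.0, config.noise_rms, n)
    rumble_freq = rng.uniform(40.0, 120.0)
    rumble = (config.noise_rms * rng.uniform(0.5, 1.5)
              * np.sin(2 * np.pi * rumble_freq * t + rng.uniform(0, 2 * np.pi)))
    return AudioClip(white + rumble, config.sample_rate)


def _place_calls(canvas: np.ndarray, call: np.ndarray, n_calls: int,
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    spans = []
    for _ in range(n_calls):
        start = int(rng.integers(0, max(len(canvas) - len(call), 1)))
        canvas[start:start + len(call)] += call[: len(canvas) - start]
        spans.append((start, min(start + len(call), len(canvas))))
    return spans


def generate_focal_recording(
    config: SceneConfig,
    profiles: dict[str, SpeciesProfile],
    primary: str,
    secondaries: list[str],
    rng: np.random.Generator,
    recording_id: str = "",
    return_events: bool = False,
):
    """Focal recording: loud primary calls, attenuated background species.

    Each secondary species enters the annotation independently with
    probability ``secondary_label_completeness`` — present-but-unlabelled
    species model the incomplete background labels of community archives.
    """
    n = int(round(config.clip_seconds * config.sample_rate))
    canvas = generate_noise_clip(config, rng).samples.copy()
    events: dict[str, list[tuple[int, int]]] = {}
    fg_call = synthesize_call(profiles[primary], config.sample_rate,
                              config.call_amplitude)
    n_calls = int(rng.integers(1, 4))
    events[primary] = _place_calls(canvas, fg_call.samples, n_calls, rng)
    bg_gain = 10.0 ** (-config.foreground_to_background_gain_db / 20.0)
    labelled = []
    for code in secondaries:
        bg_call = synthesize_call(profiles[code], config.sample_rate,
                                  config.call_amplitude * bg_gain)
        events[code] = _place_calls(canvas, bg_call.samples,
                                    int(rng.integers(1, 3)), rng)
        if rng.random() < config.secondary_label_completeness:
            labelled.append(code)
    clip = AudioClip(canvas[:n], config.sample_rate)
    annotation = RecordingAnnotation(recording_id, primary, tuple(labelled),
                                     source="synthetic-focal")
    if return_events:
        return clip, annotation, events
    return clip, annotation


def generate_soundscape(
    config: SceneConfig,
    profiles: dict[str, SpeciesProfile],
    rng: np.random.Generator,
    recording_id: str = "",
) -> tuple[AudioClip, RecordingAnnotation]:
    """Polyphonic clip: k species (polyphony-distributed) at equal gain,
    fully annotated — the soundscape/dawn-chorus analog."""
    k = int(rng.choice(np.arange(1, len(config.polyphony_probs) + 1),
                       p=config.polyphony_probs))
    k = min(k, len(profiles))
    codes = list(rng.choice(sorted(profiles), size=k, replace=False))
    canvas = generate_noise_clip(config, rng).samples.copy()
    for code in codes:
        call = synthesize_call(profiles[code], config.sample_rate,
                               config.call_amplitude * 0.5)
        _place_calls(canvas, call.samples, int(rng.integers(1, 3)), rng)
    annotation = RecordingAnnotation(recording_id, codes[0],
                                     tuple(codes[1:]), source="synthetic-soundscape")
    return AudioClip(canvas, config.sample_rate), annotation


@dataclass
class Corpus:
    """In-memory synthetic corpus; write_corpus persists it as text + WAV."""

    config: SceneConfig
    vocab: ClassVocabulary
    profiles: dict[str, SpeciesProfile]
    items: list[tuple[str, AudioClip, RecordingAnnotation, str]]  # id, clip, ann, split
    counts: dict[str, int]
    manifest: dict = field(default_factory=dict)

    def split_items(self, split: str):
        return [(rid, clip, ann) for rid, clip, ann, s in self.items if s == split]

    def noise_pool(self, split: str = "train") -> NoisePool:
        clips = [clip for _, clip, ann, s in self.items
                 if s == split and ann.primary_species == NOISE_CLASS]
        return NoisePool(tuple(clips))


def generate_corpus(config: SceneConfig) -> Corpus:
    """Build the full corpus: focal recordings per the long-tailed count
    table, noise-only clips, and a per-species stratified train/test split.

    Reproducible: a fixed seed yields a byte-identical annotation table.
    """
    profiles = {p.species_id: p for p in make_profiles(config)}
    counts = config.species_counts()
    vocab = ClassVocabulary.from_species(sorted(counts))
    rng = np.random.default_rng(config.seed)
    items = []
    poly = np.asarray(config.polyphony_probs)
    others = {c: [o for o in sorted(counts) if o != c] for c in counts}
    idx = 0
    for code in sorted(counts):
        for _ in range(counts[code]):
            n_present = int(rng.choice(np.arange(1, len(poly) + 1), p=poly))
            n_secondary = min(n_present - 1, len(others[code]))
            secondaries = (list(rng.choice(others[code], size=n_secondary,
                                           replace=False))
                           if n_secondary else [])
            rid = f"rec{idx:05d}"
            clip, ann = generate_focal_recording(config, profiles, code,
                                                 secondaries, rng, rid)
            items.append((rid, clip, ann))
            idx += 1
    n_noise = max(4, int(round(config.noise_clip_fraction * idx)))
    for _ in range(n_noise):
        rid = f"rec{idx:05d}"
        clip = generate_noise_clip(config, rng)
        items.append((rid, clip,
                      RecordingAnnotation(rid, NOISE_CLASS, (),
                                          source="synthetic-noise")))
        idx += 1

    # stratified split: per class, every ceil(1/test_fraction)-th item is test
    by_class: dict[str, list[int]] = {}
    for i, (_, _, ann) in enumerate(items):
        by_class.setdefault(ann.primary_species, []).append(i)
    split_of = {}
    for code, indices in by_class.items():
        n_test = max(1, int(round(config.test_fraction * len(indices))))
        test_idx = set(rng.choice(indices, size=n_test, replace=False).tolist())
        for i in indices:
            split_of[i] = "test" if i in test_idx else "train"
    full_items = [(rid, clip, ann, split_of[i])
                  for i, (rid, clip, ann) in enumerate(items)]
    manifest = {"scene_config": asdict(config), "n_recordings": len(full_items),
                "n_noise_clips": n_noise, "counts": counts,
                "classes": list(vocab.classes), "seed": config.seed}
    return Corpus(config, vocab, profiles, full_items, counts, manifest)


def write_corpus(corpus: Corpus, outdir: str | Path) -> None:
    """Persist as WAV files + annotation CSV + count table + JSON manifest."""
    outdir = Path(outdir)
    audio_dir = outdir / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    annotations, splits = [], {}
    for rid, clip, ann, split in corpus.items:
        write_wav(audio_dir / f"{rid}.wav", clip)
        annotations.append(ann)
        splits[rid] = split
    write_annotations(outdir / "annotations.csv", annotations, splits)
    pd.DataFrame(sorted(corpus.counts.items()),
                 columns=["species", "n_recordings"]
                 ).to_csv(outdir / "species_counts.csv", index=False)
    corpus.vocab.to_json(outdir / "vocabulary.json")
    (outdir / "manifest.json").write_text(json.dumps(corpus.manifest, indent=1))


def to_training_examples(corpus: Corpus, split: str, mode: str = "single",
                         use_secondary: bool = False) -> list[tuple[AudioClip, np.ndarray]]:
    """(clip, target) pairs for the trainer."""
    return [(clip, build_target(ann, corpus.vocab, use_secondary, mode))
            for _, clip, ann in corpus.split_items(split)]


def make_template_teacher(corpus: Corpus, mel_config_preset: str = "tiny",
                          activation_kind: str = "softmax",
                          logit_scale: float = 20.0,
                          n_examples_per_class: int = 8) -> BandTemplateModel:
    """Construct a near-optimal matched-filter teacher from the generator.

    Per class, averages the time-mean standardized log-mel features of a few
    clean single-species recordings (no secondaries, full-gain calls); the
    noise-class template comes from noise-only clips. Templates are centered
    on their grand mean so the shared noise-floor component cancels.
    """
    model = BandTemplateModel(corpus.vocab, activation_kind=activation_kind,
                              frontend_preset=mel_config_preset,
                              logit_scale=logit_scale)
    cfg = corpus.config
    rng = np.random.default_rng(cfg.seed + 1)
    feats = np.zeros((len(corpus.vocab), model.mel_config.n_mels))
    for c, code in enumerate(corpus.vocab.classes):
        rows = []
        for _ in range(n_examples_per_class):
            if code == NOISE_CLASS:
                clip = generate_noise_clip(cfg, rng)
            else:
                clip, _ = generate_focal_recording(cfg, corpus.profiles, code,
                                                   [], rng)
            mel = compute_mel(clip, model.mel_config)
            rows.append(BandTemplateModel.features(mel.standardized()))
        feats[c] = np.mean(rows, axis=0)
    mean = feats.mean(axis=0)
    return model.set_templates(feats - mean, feature_mean=mean)
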