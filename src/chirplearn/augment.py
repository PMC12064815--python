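"""Waveform-domain augmentation: MixUp and SNR-controlled background noise.

Both operate on raw waveforms *before* spectrogram conversion and are applied
on-the-fly with configured probabilities (MixUp 0.6, noise 0.5 by default;
noise scaled to a random SNR drawn uniformly from [3, 30] dB). When both
fire, MixUp is applied first. No clipping is applied — training stays in
floating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .audio import AudioClip

__all__ = ["AugmentationConfig", "NoisePool", "mixup", "add_background_noise",
           "augment_for_training"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AugmentationConfig:
    mixup_prob: float = 0.6
    noise_prob: float = 0.5
    snr_range_db: tuple[float, float] = (3.0, 30.0)
    beta_alpha: float = 0.2
    clip_multilabel_targets: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.mixup_prob <= 1.0 and 0.0 <= self.noise_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.snr_range_db[0] > self.snr_range_db[1]:
            raise ValueError("snr_range_db lower bound exceeds upper bound")
        if self.beta_alpha <= 0:
            raise ValueError("beta_alpha must be positive")


@dataclass(frozen=True)
class NoisePool:
    """Collection of noise-only clips used for background-noise mixing."""

    clips: tuple[AudioClip, ...]

    def __post_init__(self):
        object.__setattr__(self, "clips", tuple(self.clips))

    def __len__(self) -> int:
        return len(self.clips)

    def sample_window(self, n_samples: int, sample_rate: int,
                      rng: np.random.Generator) -> AudioClip:
        """Random crop from a random pool clip, tiling clips that are short."""
        if not self.clips:
            raise ValueError("noise pool is empty")
        clip = self.clips[rng.integers(len(self.clips))]
        if clip.sample_rate != sample_rate:
            raise ValueError(
                f"noise clip rate {clip.sample_rate} != requested {sample_rate}")
        samples = clip.samples
        if len(samples) < n_samples:
            reps = -(-n_samples // len(samples))
            samples = np.tile(samples, reps)
        start = int(rng.integers(len(samples) - n_samples + 1))
        return AudioClip(samples[start:start + n_samples], sample_rate)


def mixup(clip_a: AudioClip, clip_b: AudioClip, target_a: np.ndarray,
          target_b: np.ndarray, lam: float) -> tuple[AudioClip, np.ndarray]:
    """Convex combination of two waveforms and their targets."""
    if len(clip_a) != len(clip_b) or clip_a.sample_rate != clip_b.sample_rate:
        raise ValueError(
            f"mixup requires matching clips: {len(clip_a)}@{clip_a.sample_rate}Hz "
            f"vs {len(clip_b)}@{clip_b.sample_rate}Hz")
    target_a, target_b = np.asarray(target_a), np.asarray(target_b)
    if target_a.shape != target_b.shape:
        raise ValueError("mixup targets must have the same dimension")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    mixed = AudioClip(lam * clip_a.samples + (1.0 - lam) * clip_b.samples,
                      clip_a.sample_rate)
    return mixed, lam * target_a + (1.0 - lam) * target_b


def add_background_noise(clip: AudioClip, noise: AudioClip,
                         snr_db: float) -> AudioClip:
    """Add noise scaled so the signal-to-noise power ratio equals ``snr_db``.

    Gain: ``g = (rms_signal / rms_noise) * 10**(-snr_db / 20)``. A silent
    input signal skips the augmentation (logged); silent noise is an error.
    """
    if clip.sample_rate != noise.sample_rate:
        raise ValueError("clip and noise sample rates differ")
    if len(noise) < len(clip):
        raise ValueError("noise shorter than clip; crop/tile via NoisePool first")
    noise_samples = noise.samples[: len(clip)]
    rms_signal = float(np.sqrt(np.mean(clip.samples ** 2)))
    rms_noise = float(np.sqrt(np.mean(noise_samples ** 2)))
    if rms_noise == 0.0:
        raise ValueError("noise clip is silent; cannot scale to a target SNR")
    if rms_signal == 0.0:
        logger.warning("silent input signal: skipping background-noise augmentation")
        return clip
    gain = (rms_signal / rms_noise) * 10.0 ** (-snr_db / 20.0)
    return AudioClip(clip.samples + gain * noise_samples, clip.sample_rate)


def augment_for_training(
    clip: AudioClip,
    target: np.ndarray,
    partner_source,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    noise_pool: NoisePool | None = None,
    multi_label: bool = False,
) -> tuple[AudioClip, np.ndarray]:
    """One stochastic augmentation pass for a training example.

    ``partner_source()`` must return a ``(AudioClip, target)`` pair (the
    MixUp partner, typically drawn uniformly from the same batch). With
    probability ``mixup_prob`` MixUp fires (lam ~ Beta(alpha, alpha));
    independently with probability ``noise_prob`` background noise fires.
    The returned waveform is the single input shown to both teacher and
    student under consistent teaching.
    """
    target = np.asarray(target, dtype=np.float64)
    if cfg.noise_prob > 0 and (noise_pool is None or len(noise_pool) == 0):
        raise ValueError("noise augmentation enabled but noise pool is empty")
    if rng.random() < cfg.mixup_prob:
        partner_clip, partner_target = partner_source()
        lam = float(rng.beta(cfg.beta_alpha, cfg.beta_alpha))
        clip, target = mixup(clip, partner_clip, target, partner_target, lam)
        if multi_label and cfg.clip_multilabel_targets:
            target = np.minimum(target, 1.0)
    if rng.random() < cfg.noise_prob:
        snr_db = float(rng.uniform(*cfg.snr_range_db))
        noise = noise_pool.sample_window(len(clip), clip.sample_rate, rng)
        clip = add_background_noise(clip, noise, snr_db)
    return clip, target
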