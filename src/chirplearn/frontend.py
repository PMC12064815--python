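"""Spectrogram front-end: chunking, framing arithmetic, and log-mel features.

Framing uses *no* center padding (left-aligned frames): a 3-second input at
16 kHz with a 400-sample window and 160-sample hop yields exactly 298 frames,
matching the preprocessing configurations this toolkit standardizes on.
Centered framing would give 301 and is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .audio import AudioClip

__all__ = [
    "MelConfig",
    "RawWaveformConfig",
    "MelSpectrogram",
    "PRESETS",
    "frame_count",
    "chunk_recording",
    "compute_mel",
    "mel_filterbank",
    "mel_center_frequencies",
]


@dataclass(frozen=True)
class MelConfig:
    """Parameters of a log-mel front-end."""

    n_mels: int
    sample_rate: int
    win_length: int
    hop_length: int
    n_fft: int
    log_floor: float = 1e-10

    def __post_init__(self):
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if self.win_length > self.n_fft:
            raise ValueError(
                f"win_length ({self.win_length}) must be <= n_fft ({self.n_fft})")
        if self.hop_length > self.win_length:
            raise ValueError(
                f"hop_length ({self.hop_length}) must be <= win_length "
                f"({self.win_length})")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be a small positive constant")


@dataclass(frozen=True)
class RawWaveformConfig:
    """Pass-through front-end: the model consumes the waveform directly."""

    sample_rate: int = 48_000


PRESETS: dict[str, MelConfig | RawWaveformConfig] = {
    "passt": MelConfig(n_mels=128, sample_rate=16_000, win_length=400,
                       hop_length=160, n_fft=512),
    "psla": MelConfig(n_mels=128, sample_rate=32_000, win_length=800,
                      hop_length=320, n_fft=1024),
    "birdnet_raw": RawWaveformConfig(sample_rate=48_000),
    # Desk-scale preset for synthetic-corpus experiments; not a published
    # configuration and never used for the 298-frame contract.
    "tiny": MelConfig(n_mels=32, sample_rate=8_000, win_length=256,
                      hop_length=128, n_fft=256),
}


@dataclass(frozen=True)
class MelSpectrogram:
    """Log-mel energies, shape ``(n_mels, n_frames)``."""

    values: np.ndarray = field(repr=False)
    config: MelConfig

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != self.config.n_mels:
            raise ValueError(
                f"expected ({self.config.n_mels}, n_frames), got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("mel spectrogram contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> np.ndarray:
        """Per-spectrogram zero-mean/unit-std values, guarded for silence."""
        std = self.values.std()
        if std < 1e-12:
            return self.values - self.values.mean()
        return (self.values - self.values.mean()) / std


def frame_count(config: MelConfig, duration: float) -> int:
    """Number of STFT frames for ``duration`` seconds under no-center framing.

    ``1 + floor((duration * sample_rate - win_length) / hop_length)``.
    """
    n_samples = int(round(duration * config.sample_rate))
    if n_samples < config.win_length:
        raise ValueError(
            f"signal of {n_samples} samples is shorter than one window "
            f"({config.win_length} samples)")
    return 1 + (n_samples - config.win_length) // config.hop_length


def chunk_recording(recording: AudioClip, chunk_seconds: float = 3.0) -> list[AudioClip]:
    """Split a recording into contiguous fixed-length chunks.

    The trailing remainder, if any, is zero-padded to full chunk length so
    late vocalizations are preserved. Chunk order follows time order.
    """
    if len(recording) == 0:
        raise ValueError("cannot chunk an empty recording")
    if chunk_seconds <= 0:
        raise ValueError("chunk_seconds must be positive")
    chunk_len = int(round(chunk_seconds * recording.sample_rate))
    n_chunks = -(-len(recording) // chunk_len)  # ceil division
    padded = np.zeros(n_chunks * chunk_len)
    padded[: len(recording)] = recording.samples
    return [AudioClip(padded[i * chunk_len:(i + 1) * chunk_len], recording.sample_rate)
            for i in range(n_chunks)]


def _hz_to_mel(hz):
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    hz = np.asarray(hz, dtype=np.float64)
    mel = hz / (200.0 / 3.0)
    log_region = hz >= 1000.0
    mel = np.where(
        log_region,
        15.0 + np.log(np.maximum(hz, 1e-12) / 1000.0) / (np.log(6.4) / 27.0),
        mel,
    )
    return mel


def _mel_to_hz(mel):
    mel = np.asarray(mel, dtype=np.float64)
    hz = mel * (200.0 / 3.0)
    log_region = mel >= 15.0
    hz = np.where(log_region, 1000.0 * np.exp((np.log(6.4) / 27.0) * (mel - 15.0)), hz)
    return hz


def mel_center_frequencies(config: MelConfig) -> np.ndarray:
    """Center frequency (Hz) of each mel band over [0, sample_rate/2]."""
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(config.sample_rate / 2),
                                   config.n_mels + 2))
    return edges[1:-1]


def mel_filterbank(config: MelConfig) -> np.ndarray:
    """Slaney-style triangular filterbank with area normalization.

    Shape ``(n_mels, n_fft // 2 + 1)``.
    """
    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, config.sample_rate / 2.0, n_bins)
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(config.sample_rate / 2),
                                   config.n_mels + 2))
    fb = np.zeros((config.n_mels, n_bins))
    for m in range(config.n_mels):
        lower, center, upper = edges[m], edges[m + 1], edges[m + 2]
        rise = (fft_freqs - lower) / max(center - lower, 1e-12)
        fall = (upper - fft_freqs) / max(upper - center, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(rise, fall))
        fb[m] *= 2.0 / (upper - lower)  # Slaney area normalization
    return fb


def compute_mel(clip: AudioClip, config: MelConfig) -> MelSpectrogram:
    """Log-mel spectrogram: Hann STFT (no centering), power, mel, log.

    The clip must already be at ``config.sample_rate``; resample upstream —
    this op never resamples silently.
    """
    if clip.sample_rate != config.sample_rate:
        raise ValueError(
            f"clip sample rate {clip.sample_rate} != config sample rate "
            f"{config.sample_rate}; resample explicitly first")
    n_frames = frame_count(config, clip.duration)
    window = get_window("hann", config.win_length, fftbins=True)
    idx = (np.arange(n_frames)[:, None] * config.hop_length
           + np.arange(config.win_length)[None, :])
    frames = clip.samples[idx] * window
    spectrum = np.fft.rfft(frames, n=config.n_fft, axis=1)
    power = np.abs(spectrum) ** 2                    # (n_frames, n_bins)
    mel_power = power @ mel_filterbank(config).T     # (n_frames, n_mels)
    values = np.log(mel_power + config.log_floor).T
    return MelSpectrogram(values, config)
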