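"""Audio container and basic waveform I/O.

WAV is the supported on-disk format (read/written via :mod:`scipy.io.wavfile`);
multi-channel files are converted to mono by channel averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioClip", "read_wav", "write_wav", "resample"]


@dataclass(frozen=True)
class AudioClip:
    """A fixed-duration mono waveform.

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of amplitudes, nominal range [-1, 1].
    sample_rate : int
        Sampling rate in Hz, positive.
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"AudioClip is mono-only; got shape {samples.shape}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path: str | Path) -> AudioClip:
    """Read a WAV file as a mono :class:`AudioClip` scaled to [-1, 1]."""
    path = Path(path)
    if path.suffix.lower() == ".flac":
        raise ValueError(
            "FLAC decoding is not available in this build; convert to WAV first"
        )
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned WAV
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioClip(data, int(rate))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (clipped to [-1, 1])."""
    data = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(Path(path), clip.sample_rate, (data * 32767).astype(np.int16))


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Band-limited resampling; duration preserved within one sample."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == clip.sample_rate:
        return clip
    g = np.gcd(clip.sample_rate, target_rate)
    out = resample_poly(clip.samples, target_rate // g, clip.sample_rate // g)
    return AudioClip(out, target_rate)
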