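"""Segment selection for weakly labelled recordings.

Discards 3-second chunks likely devoid of bird sound, either by a
band-energy heuristic (energy in 500-10,000 Hz relative to the recording's
median chunk) or by thresholding scores from an injected pretrained
detector (keep when the score crosses the threshold, default 0.3).
Retained chunks inherit the recording's weak labels unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioClip

__all__ = ["SegmentDecision", "band_energy", "energy_detector",
           "score_threshold_filter"]

DEFAULT_BAND_HZ = (500.0, 10_000.0)


@dataclass(frozen=True)
class SegmentDecision:
    chunk_index: int
    score: float
    keep: bool


def band_energy(chunk: AudioClip, band_hz: tuple[float, float] = DEFAULT_BAND_HZ) -> float:
    """Spectral energy of a chunk inside a frequency band (rfft bins summed)."""
    lo, hi = band_hz
    spectrum = np.fft.rfft(chunk.samples)
    freqs = np.fft.rfftfreq(len(chunk), d=1.0 / chunk.sample_rate)
    mask = (freqs >= lo) & (freqs <= hi)
    return float(np.sum(np.abs(spectrum[mask]) ** 2))


def energy_detector(chunks: list[AudioClip],
                    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                    ratio_threshold: float = 1.0) -> list[SegmentDecision]:
    """Keep chunks whose band energy >= ratio_threshold x the median chunk.

    Always keeps at least the top-scoring chunk, so no recording is left
    empty. Scores are energy ratios, invariant to global gain.
    """
    if not chunks:
        raise ValueError("energy_detector requires at least one chunk")
    energies = np.array([band_energy(c, band_hz) for c in chunks])
    median = float(np.median(energies))
    if median <= 0.0:
        # degenerate: all-zero chunks tie at 1, otherwise zeros rank last
        fill = 1.0 if not energies.any() else 0.0
        ratios = np.where(energies > 0, np.inf, fill)
    else:
        ratios = energies / median
    keep = ratios >= ratio_threshold
    if not keep.any():
        keep[int(np.argmax(ratios))] = True
    return [SegmentDecision(i, float(ratios[i]), bool(keep[i]))
            for i in range(len(chunks))]


def score_threshold_filter(scores, threshold: float = 0.3,
                           inclusive: bool = False) -> list[SegmentDecision]:
    """Keep chunks whose detector score crosses ``threshold`` (strict ``>``).

    Scores come from any injected detector mapping chunks to bird-presence
    confidences in [0, 1].
    """
    scores = np.asarray(scores, dtype=np.float64)
    if np.any(scores < 0) or np.any(scores > 1):
        bad = scores[(scores < 0) | (scores > 1)][0]
        raise ValueError(f"detector scores must lie in [0, 1]; got {bad}")
    keep = scores >= threshold if inclusive else scores > threshold
    return [SegmentDecision(i, float(s), bool(k))
            for i, (s, k) in enumerate(zip(scores, keep))]
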