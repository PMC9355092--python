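"""Core containers shared by every stage of the pipeline.

The common currency of all signal operations is :class:`WaveformSignal`, a
uniformly sampled mono vibration waveform.  Multi-part signals (male
courtship and male competition calls) additionally carry a
:class:`Segmentation` describing which stretch of samples belongs to which
part of the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveformSignal",
    "SegmentPart",
    "Segmentation",
    "NyquistError",
]


class NyquistError(ValueError):
    """A requested frequency violates the Nyquist limit of the sample rate."""


@dataclass
class WaveformSignal:
    """Uniformly sampled mono vibration waveform.

    Parameters
    ----------
    samples:
        Real amplitudes, dimensionless, nominal range [-1, 1].
    sample_rate:
        Sampling frequency in Hz.
    label:
        Optional signal-class tag (e.g. ``"female_courtship"``,
        ``"PT (225 Hz)"``).
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"expected mono (1-D) samples, got shape {self.samples.shape}")
        if self.samples.size == 0:
            raise ValueError("waveform must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sample_rate

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def slice(self, start: int, end: int, label: str | None = None) -> "WaveformSignal":
        """Return the half-open sample interval [start, end) as a new signal."""
        if not 0 <= start < end <= len(self):
            raise ValueError(f"invalid slice [{start}, {end}) for signal of length {len(self)}")
        return WaveformSignal(self.samples[start:end].copy(), self.sample_rate, label or self.label)


@dataclass
class SegmentPart:
    """One labelled part of a multi-part signal: half-open [start, end) sample interval."""

    label: str
    start: int
    end: int
    pulse_count: int = 0

    @property
    def empty(self) -> bool:
        return self.end <= self.start

    def duration(self, sample_rate: float) -> float:
        return max(self.end - self.start, 0) / sample_rate


@dataclass
class Segmentation:
    """Ordered, non-overlapping labelled parts of a signal.

    Intervals are 0-based half-open ``[start, end)`` sample index pairs.
    Empty parts (``start == end``) are allowed and mark parts that the
    signal class may contain but this particular signal does not (e.g. a
    male courtship call drawn with zero wide pulses).
    """

    parts: list[SegmentPart] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = 0
        for p in self.parts:
            if p.start < pos or p.end < p.start:
                raise ValueError("segmentation parts must be ordered and non-overlapping")
            pos = p.end

    def part(self, label: str) -> SegmentPart | None:
        for p in self.parts:
            if p.label == label:
                return p
        return None

    def __iter__(self):
        return iter(self.parts)

    def __len__(self) -> int:
        return len(self.parts)

    def boundary_string(self) -> str:
        """Serialize as semicolon-separated ``start:end`` pairs (part order)."""
        return ";".join(f"{p.start}:{p.end}" for p in self.parts)
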