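"""Artificial courtship-disruption signals and playback mixing.

Seven disruptive signals of three types are screened against the male's
recognition of female courtship calls:

* three pure tones (PT) at 150, 225 and 300 Hz — the frequency range of the
  female courtship signal;
* three continuous pulse signals (CPS) with a constant 22 Hz pulse rate and
  main vibration frequencies of 150, 225 and 300 Hz, built by filling a
  sine wave with a periodic triangular pulse;
* white Gaussian noise (WGN) at 0 dBW (unit variance in the dimensionless
  amplitude convention).

For playback, a disruptive signal is mixed with a courtship signal "at
uniform intensity", interpreted here as equal RMS of the two components
(peak-equal matching is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NyquistError, WaveformSignal
from .synth import DEFAULT_SAMPLE_RATE, PulseTrainSpec, gen_pulse_train

__all__ = [
    "DisruptiveSpec",
    "gen_pure_tone",
    "gen_cps",
    "gen_wgn",
    "make_all_seven",
    "mix_uniform_intensity",
    "SEVEN_LABELS",
]

#: Labels of the seven screened disruptive signals, in screening-table order.
SEVEN_LABELS = (
    "PT (150 Hz)",
    "PT (225 Hz)",
    "PT (300 Hz)",
    "CPS (22-150 Hz)",
    "CPS (22-225 Hz)",
    "CPS (22-300 Hz)",
    "WGN",
)


@dataclass
class DisruptiveSpec:
    """Parametric description of one artificial disruptive signal.

    ``kind`` is one of ``"PT"`` (pure tone: ``frequency`` set), ``"CPS"``
    (continuous pulse signal: ``frequency`` and ``pulse_rate`` set) or
    ``"WGN"`` (white Gaussian noise: ``power_dbw`` and ``seed`` set).
    """

    kind: str
    duration: float = 2.0
    frequency: float | None = None
    pulse_rate: float | None = None
    power_dbw: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "PT":
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("PT requires a positive frequency")
            if self.pulse_rate is not None:
                raise ValueError("PT does not take a pulse rate")
        elif self.kind == "CPS":
            if self.pulse_rate is None:
                self.pulse_rate = 22.0
            if self.frequency is None or self.frequency <= 2 * self.pulse_rate:
                raise ValueError("CPS requires frequency > 2 x pulse rate")
        elif self.kind == "WGN":
            if self.frequency is not None or self.pulse_rate is not None:
                raise ValueError("WGN takes no frequency parameters")
            if self.power_dbw is None:
                self.power_dbw = 0.0
        else:
            raise ValueError(f"unknown disruptive signal kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "PT":
            return f"PT ({self.frequency:g} Hz)"
        if self.kind == "CPS":
            return f"CPS ({self.pulse_rate:g}-{self.frequency:g} Hz)"
        return "WGN"

    def render(self, sample_rate: int = DEFAULT_SAMPLE_RATE) -> WaveformSignal:
        if self.kind == "PT":
            return gen_pure_tone(self.frequency, self.duration, sample_rate)
        if self.kind == "CPS":
            return gen_cps(self.frequency, self.pulse_rate, self.duration, sample_rate)
        return gen_wgn(self.power_dbw, self.duration, sample_rate, self.seed)


def gen_pure_tone(frequency: float, duration: float,
                  sample_rate: int = DEFAULT_SAMPLE_RATE,
                  amplitude: float = 1.0) -> WaveformSignal:
    """Unmodulated sinusoid: ``samples[k] = amplitude * sin(2 pi f k / fs)``."""
    if not 0 < frequency < sample_rate / 2:
        raise NyquistError(
            f"tone frequency {frequency} Hz must lie in (0, {sample_rate / 2}) Hz"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    return WaveformSignal(amplitude * np.sin(2.0 * np.pi * frequency * t),
                          sample_rate, f"PT ({frequency:g} Hz)")


def gen_cps(frequency: float, pulse_rate: float = 22.0, duration: float = 2.0,
            sample_rate: int = DEFAULT_SAMPLE_RATE, amplitude: float = 1.0,
            duty: float = 0.8, envelope_shape: str = "triangular") -> WaveformSignal:
    """Continuous pulse signal: sine carrier filled with a periodic triangular pulse.

    The envelope repeats at ``pulse_rate`` (22 Hz by convention) so the
    envelope spectrum peaks there while the carrier spectrum peaks at
    ``frequency``.  With ``duty=1`` and a flat envelope this degenerates to
    :func:`gen_pure_tone`.
    """
    spec = PulseTrainSpec(mvf=frequency, pulse_rate=pulse_rate, duration=duration,
                          amplitude=amplitude, envelope_shape=envelope_shape, duty=duty)
    return gen_pulse_train(spec, sample_rate, label=f"CPS ({pulse_rate:g}-{frequency:g} Hz)")


def gen_wgn(power_dbw: float = 0.0, duration: float = 2.0,
            sample_rate: int = DEFAULT_SAMPLE_RATE,
            seed: int | np.random.Generator | None = None) -> WaveformSignal:
    """White Gaussian noise with variance ``10**(power_dbw / 10)``.

    0 dBW maps to unit variance in dimensionless amplitude units (1 W into
    unit impedance).  Reproducible under a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = 10.0 ** (power_dbw / 20.0)
    n = int(round(duration * sample_rate))
    return WaveformSignal(rng.normal(0.0, sigma, n), sample_rate, "WGN")


def make_all_seven(duration: float = 2.0, sample_rate: int = DEFAULT_SAMPLE_RATE,
                   seed: int | None = 0, equal_rms: bool = False) -> list[WaveformSignal]:
    """The seven screened disruptive signals, labelled in screening-table order.

    With ``equal_rms=True`` every signal is rescaled to the RMS of a
    unit-amplitude pure tone (1/sqrt(2)) so all playbacks share one intensity.
    """
    signals = [
        gen_pure_tone(150.0, duration, sample_rate),
        gen_pure_tone(225.0, duration, sample_rate),
        gen_pure_tone(300.0, duration, sample_rate),
        gen_cps(150.0, 22.0, duration, sample_rate),
        gen_cps(225.0, 22.0, duration, sample_rate),
        gen_cps(300.0, 22.0, duration, sample_rate),
        gen_wgn(0.0, duration, sample_rate, seed),
    ]
    if equal_rms:
        target = 1.0 / np.sqrt(2.0)
        signals = [WaveformSignal(s.samples * (target / s.rms()), s.sample_rate, s.label)
                   for s in signals]
    return signals


def mix_uniform_intensity(courtship: WaveformSignal, disruptive: WaveformSignal,
                          match: str = "rms") -> WaveformSignal:
    """Mix a courtship signal with a disruptive signal at uniform intensity.

    The disruptive signal is tiled or truncated to the courtship duration,
    rescaled so both components have equal RMS (``match="rms"``, default) or
    equal peak (``match="peak"``), then summed.  The output is scaled down
    to peak 1 if the sum would clip.  An all-zero disruptor leaves the
    courtship signal unchanged (up to peak normalization).

    Raises
    ------
    ValueError
        On sample-rate mismatch (no implicit resampling).
    """
    if courtship.sample_rate != disruptive.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: {courtship.sample_rate} vs {disruptive.sample_rate} Hz"
        )
    if match not in ("rms", "peak"):
        raise ValueError(f"unknown intensity match {match!r}")
    c = courtship.samples
    d = np.resize(disruptive.samples, c.size)  # tile or truncate
    if match == "rms":
        c_level, d_level = np.sqrt(np.mean(c**2)), np.sqrt(np.mean(d**2))
    else:
        c_level, d_level = np.max(np.abs(c)), np.max(np.abs(d))
    mixed = c if d_level == 0 else c + d * (c_level / d_level)
    peak = np.max(np.abs(mixed))
    if peak > 1.0:
        mixed = mixed / peak
    label = f"{courtship.label or 'courtship'}+{disruptive.label or 'disruptor'}"
    return WaveformSignal(mixed.copy(), courtship.sample_rate, label)
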