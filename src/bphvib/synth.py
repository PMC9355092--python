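"""Synthetic brown planthopper (BPH) vibrational signals.

Generates the three natural signal classes — female courtship, male
courtship, male competition — as parametric pulse-train waveforms whose
population statistics match the reported field measurements:

* female courtship: continuous pulse train, per-individual main vibration
  frequency (MVF) ~ Normal(236, 43) Hz, pulse rate ~ Normal(23, 2) Hz;
* male courtship: 3-10 irregular pulses (part a), a continuous pulse train
  with MVF ~ Normal(255, 24) Hz (part b), then 0-5 wide pulses (part c);
* male competition: a continuous pulse train with main frequency
  ~ Normal(281, 46) Hz (part a) followed by 2-4 short pulses (part b).

Every generator is bit-reproducible under a fixed seed.  The generated
waveforms serve both as a stand-in for recorded signals and as ground truth
for the feature-extraction round-trip tests: the multi-part generators
return the true part boundaries alongside the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NyquistError, SegmentPart, Segmentation, WaveformSignal

__all__ = [
    "PulseTrainSpec",
    "MaleCourtshipSpec",
    "CompetitionSpec",
    "ClassMoments",
    "PopulationParams",
    "GroundTruth",
    "gen_pulse_train",
    "gen_female_courtship",
    "gen_male_courtship",
    "gen_male_competition",
    "gen_corpus",
    "sample_class_params",
    "DEFAULT_SAMPLE_RATE",
]

#: Default sample rate (Hz).  All frequencies of interest are below 500 Hz,
#: so 8 kHz leaves a wide anti-aliasing margin while keeping files small.
DEFAULT_SAMPLE_RATE = 8000


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# parametric specs
# ---------------------------------------------------------------------------


@dataclass
class PulseTrainSpec:
    """Sine carrier amplitude-modulated by a periodic pulse envelope.

    Parameters
    ----------
    mvf:
        Carrier (main vibration) frequency in Hz.
    pulse_rate:
        Pulse repetition frequency in Hz; must be below ``mvf`` so the
        carrier oscillates within each pulse.
    duration:
        Length in seconds.
    amplitude:
        Peak envelope amplitude (the carrier peaks reach ~this value).
    envelope_shape:
        ``"triangular"`` (symmetric rise/fall, the default) or ``"flat"``
        (rectangular gate; with ``duty=1`` this degenerates to a pure sine).
    duty:
        Fraction of each pulse period occupied by the pulse, in (0, 1].
    """

    mvf: float
    pulse_rate: float
    duration: float
    amplitude: float = 1.0
    envelope_shape: str = "triangular"
    duty: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.pulse_rate < self.mvf:
            raise ValueError(
                f"need 0 < pulse_rate < mvf, got pulse_rate={self.pulse_rate}, mvf={self.mvf}"
            )
        if not 0 < self.duty <= 1:
            raise ValueError(f"duty must be in (0, 1], got {self.duty}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.envelope_shape not in ("triangular", "flat"):
            raise ValueError(f"unknown envelope shape {self.envelope_shape!r}")


@dataclass
class MaleCourtshipSpec:
    """Three-part male courtship call: irregular pulses, train, wide pulses."""

    n_irregular: int
    part_b: PulseTrainSpec
    n_wide: int
    irregular_pulse_dur: float = 0.015
    wide_pulse_dur: float | None = None  # default: 3 x part-b pulse width
    gap_dur: float = 0.1

    def __post_init__(self) -> None:
        if self.n_irregular < 0 or self.n_wide < 0:
            raise ValueError("pulse counts must be non-negative")
        if self.wide_pulse_dur is None:
            self.wide_pulse_dur = 3.0 * self.part_b.duty / self.part_b.pulse_rate


@dataclass
class CompetitionSpec:
    """Two-part male competition call: pulse train then short pulses."""

    part_a: PulseTrainSpec
    n_short: int
    short_pulse_dur: float | None = None  # default: 0.5 x part-a pulse width

    def __post_init__(self) -> None:
        if self.n_short < 0:
            raise ValueError("n_short must be non-negative")
        if self.short_pulse_dur is None:
            self.short_pulse_dur = 0.5 * self.part_a.duty / self.part_a.pulse_rate


@dataclass(frozen=True)
class ClassMoments:
    """Population mean/SD of MVF and pulse rate for one signal class (Hz)."""

    mvf_mean: float
    mvf_sd: float
    pr_mean: float
    pr_sd: float

    def __post_init__(self) -> None:
        if self.mvf_sd < 0 or self.pr_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class PopulationParams:
    """Population-level generative parameters for the three signal classes.

    Defaults are the reported field statistics: female MVF 236 +/- 43 Hz and
    pulse rate 23 +/- 2 Hz; male courtship part-b MVF 255 +/- 24 Hz;
    competition part-a main frequency 281 +/- 46 Hz.  No male pulse-rate
    spread is reported; the male train pulse rate defaults to 82 Hz with a
    nominal 5 Hz SD (configurable).  Normal draws are truncated at
    ``trunc_sd`` standard deviations to avoid physically impossible values,
    and the drawn MVF is required to exceed twice the drawn pulse rate so
    the carrier oscillates within each pulse.
    """

    female: ClassMoments = field(default_factory=lambda: ClassMoments(236.0, 43.0, 23.0, 2.0))
    male_courtship: ClassMoments = field(default_factory=lambda: ClassMoments(255.0, 24.0, 82.0, 5.0))
    competition: ClassMoments = field(default_factory=lambda: ClassMoments(281.0, 46.0, 82.0, 5.0))
    noise_snr_db: float | None = 20.0
    trunc_sd: float = 3.0

    def moments(self, signal_class: str) -> ClassMoments:
        try:
            return getattr(self, signal_class)
        except AttributeError:
            raise ValueError(f"unknown signal class {signal_class!r}") from None


@dataclass
class GroundTruth:
    """True generative parameters of one synthesized signal."""

    signal_class: str
    mvf: float
    pulse_rate: float
    segmentation: Segmentation


# ---------------------------------------------------------------------------
# deterministic waveform builders
# ---------------------------------------------------------------------------


def _pulse_envelope(n: int, sample_rate: float, pulse_rate: float, duty: float, shape: str) -> np.ndarray:
    """Periodic pulse envelope sampled at ``n`` points.

    ``triangular``: symmetric rise/fall over the duty portion of each pulse
    period, zero floor between pulses.  ``flat``: rectangular gate.
    """
    phase = (np.arange(n) / sample_rate * pulse_rate) % 1.0
    env = np.zeros(n)
    inside = phase < duty
    if shape == "triangular":
        x = phase[inside] / duty
        env[inside] = 1.0 - np.abs(2.0 * x - 1.0)
    elif shape == "flat":
        env[inside] = 1.0
    else:
        raise ValueError(f"unknown envelope shape {shape!r}")
    return env


def gen_pulse_train(spec: PulseTrainSpec, sample_rate: int = DEFAULT_SAMPLE_RATE,
                    label: str | None = None) -> WaveformSignal:
    """Synthesize a continuous pulse train: sine carrier x periodic envelope.

    The returned waveform is ``amplitude * envelope(t) * sin(2 pi mvf t)``
    evaluated on the sample grid.  The envelope spectrum peaks at
    ``spec.pulse_rate`` and the carrier spectrum at ``spec.mvf``.

    Raises
    ------
    NyquistError
        If ``sample_rate <= 2 * spec.mvf``.
    """
    if sample_rate <= 2 * spec.mvf:
        raise NyquistError(
            f"carrier {spec.mvf} Hz requires sample_rate > {2 * spec.mvf} Hz, got {sample_rate}"
        )
    n = int(round(spec.duration * sample_rate))
    if n < 1:
        raise ValueError(f"duration {spec.duration} s too short for sample rate {sample_rate} Hz")
    t = np.arange(n) / sample_rate
    carrier = np.sin(2.0 * np.pi * spec.mvf * t)
    env = _pulse_envelope(n, sample_rate, spec.pulse_rate, spec.duty, spec.envelope_shape)
    return WaveformSignal(spec.amplitude * env * carrier, sample_rate, label)


def _burst(duration: float, sample_rate: float, freq: float, amplitude: float) -> np.ndarray:
    """One isolated pulse: a single triangular envelope over a sine carrier."""
    n = max(int(round(duration * sample_rate)), 2)
    t = np.arange(n) / sample_rate
    env = 1.0 - np.abs(2.0 * t / t[-1] - 1.0)
    return amplitude * env * np.sin(2.0 * np.pi * freq * t)


def _add_noise(samples: np.ndarray, snr_db: float | None, rng: np.random.Generator) -> np.ndarray:
    """Additive white Gaussian background noise at the given SNR (dB re signal RMS)."""
    if snr_db is None or np.isinf(snr_db):
        return samples
    rms = np.sqrt(np.mean(samples**2))
    sigma = rms / (10.0 ** (snr_db / 20.0))
    return samples + rng.normal(0.0, sigma, samples.size)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------


def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float, trunc_sd: float) -> float:
    """One Normal(mean, sd) draw, re-drawn until within +/- trunc_sd SDs."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= trunc_sd * sd:
            return x
    raise RuntimeError("truncated normal rejection sampling failed")  # pragma: no cover


def sample_class_params(pop: PopulationParams, signal_class: str,
                        rng: np.random.Generator) -> tuple[float, float]:
    """Draw one individual's (MVF, pulse rate) for the given signal class.

    Draws are truncated normals; the pair is re-drawn until MVF exceeds
    twice the pulse rate (the carrier must oscillate within each pulse).
    """
    m = pop.moments(signal_class)
    for _ in range(1000):
        mvf = _draw_truncated_normal(rng, m.mvf_mean, m.mvf_sd, pop.trunc_sd)
        pr = _draw_truncated_normal(rng, m.pr_mean, m.pr_sd, pop.trunc_sd)
        if mvf > 2.0 * pr and pr > 0:
            return mvf, pr
    raise ValueError(
        f"cannot draw MVF > 2 x pulse rate for class {signal_class!r} with moments {m}"
    )


# ---------------------------------------------------------------------------
# class generators
# ---------------------------------------------------------------------------

#: Lead-in / tail silence around multi-part calls (s).
_SILENCE = 0.05


def gen_female_courtship(pop: PopulationParams, duration: float = 2.0,
                         sample_rate: int = DEFAULT_SAMPLE_RATE,
                         seed: int | np.random.Generator | None = None) -> WaveformSignal:
    """Synthesize one female courtship signal: a continuous pulse train.

    Per-individual MVF and pulse rate are drawn from the population
    distributions, the pulse train is built, and Gaussian background noise
    is added at ``pop.noise_snr_db``.  Bit-reproducible under a fixed seed.
    """
    signal, _ = gen_female_courtship_with_truth(pop, duration, sample_rate, seed)
    return signal


def gen_female_courtship_with_truth(pop: PopulationParams, duration: float = 2.0,
                                    sample_rate: int = DEFAULT_SAMPLE_RATE,
                                    seed: int | np.random.Generator | None = None,
                                    ) -> tuple[WaveformSignal, GroundTruth]:
    """As :func:`gen_female_courtship` but also return the drawn parameters."""
    rng = _as_rng(seed)
    mvf, pr = sample_class_params(pop, "female", rng)
    train = gen_pulse_train(PulseTrainSpec(mvf=mvf, pulse_rate=pr, duration=duration), sample_rate)
    samples = _add_noise(train.samples, pop.noise_snr_db, rng)
    seg = Segmentation([SegmentPart("train", 0, samples.size,
                                    pulse_count=int(round(duration * pr)))])
    truth = GroundTruth("female_courtship", mvf, pr, seg)
    return WaveformSignal(samples, sample_rate, "female_courtship"), truth


def gen_male_courtship(pop: PopulationParams, sample_rate: int = DEFAULT_SAMPLE_RATE,
                       seed: int | np.random.Generator | None = None,
                       part_b_duration: float = 1.0,
                       ) -> tuple[WaveformSignal, Segmentation]:
    """Synthesize one male courtship signal and its true part boundaries.

    Structure: part a = 3-10 irregular pulses with randomized amplitudes and
    inter-pulse gaps; part b = continuous pulse train (MVF drawn from the
    male courtship distribution); part c = 0-5 wide pulses.  Boundaries are
    0-based half-open [start, end) sample intervals spanning each part's
    pulses; a part drawn with zero pulses gets an empty interval.
    """
    signal, truth = gen_male_courtship_with_truth(pop, sample_rate, seed, part_b_duration)
    return signal, truth.segmentation


def gen_male_courtship_with_truth(pop: PopulationParams, sample_rate: int = DEFAULT_SAMPLE_RATE,
                                  seed: int | np.random.Generator | None = None,
                                  part_b_duration: float = 1.0,
                                  ) -> tuple[WaveformSignal, GroundTruth]:
    rng = _as_rng(seed)
    mvf, pr = sample_class_params(pop, "male_courtship", rng)
    spec = MaleCourtshipSpec(
        n_irregular=int(rng.integers(3, 11)),
        part_b=PulseTrainSpec(mvf=mvf, pulse_rate=pr, duration=part_b_duration),
        n_wide=int(rng.integers(0, 6)),
    )
    chunks: list[np.ndarray] = [np.zeros(int(_SILENCE * sample_rate))]
    pos = chunks[0].size
    parts: list[SegmentPart] = []

    # part a: irregular pulses, amplitudes 0.3-1.0 of the train amplitude,
    # gaps 20-80 ms ("irregular" is a qualitative field label)
    a_start = pos
    for k in range(spec.n_irregular):
        if k > 0:
            gap = np.zeros(int(rng.uniform(0.02, 0.08) * sample_rate))
            chunks.append(gap)
            pos += gap.size
        burst = _burst(spec.irregular_pulse_dur, sample_rate, mvf, rng.uniform(0.3, 1.0))
        chunks.append(burst)
        pos += burst.size
    parts.append(SegmentPart("a", a_start, pos, pulse_count=spec.n_irregular))

    gap = np.zeros(int(spec.gap_dur * sample_rate))
    chunks.append(gap)
    pos += gap.size

    # part b: the continuous pulse train
    train = gen_pulse_train(spec.part_b, sample_rate)
    b_start = pos
    chunks.append(train.samples)
    pos += train.samples.size
    parts.append(SegmentPart("b", b_start, pos,
                             pulse_count=int(round(part_b_duration * pr))))

    chunks.append(np.zeros(int(spec.gap_dur * sample_rate)))
    pos += int(spec.gap_dur * sample_rate)

    # part c: wide pulses (3 x the train pulse width), possibly none
    c_start = pos
    for k in range(spec.n_wide):
        if k > 0:
            gap = np.zeros(int(rng.uniform(0.03, 0.08) * sample_rate))
            chunks.append(gap)
            pos += gap.size
        burst = _burst(spec.wide_pulse_dur, sample_rate, mvf, rng.uniform(0.5, 1.0))
        chunks.append(burst)
        pos += burst.size
    parts.append(SegmentPart("c", c_start, pos, pulse_count=spec.n_wide))

    chunks.append(np.zeros(int(_SILENCE * sample_rate)))
    samples = _add_noise(np.concatenate(chunks), pop.noise_snr_db, rng)
    truth = GroundTruth("male_courtship", mvf, pr, Segmentation(parts))
    return WaveformSignal(samples, sample_rate, "male_courtship"), truth


def gen_male_competition(pop: PopulationParams, sample_rate: int = DEFAULT_SAMPLE_RATE,
                         seed: int | np.random.Generator | None = None,
                         part_a_duration: float = 1.0,
                         ) -> tuple[WaveformSignal, Segmentation]:
    """Synthesize one male competition signal and its true part boundaries.

    Structure: part a = continuous pulse train (main frequency drawn from
    the competition distribution); part b = 2-4 short pulses (half the
    train pulse width).
    """
    signal, truth = gen_male_competition_with_truth(pop, sample_rate, seed, part_a_duration)
    return signal, truth.segmentation


def gen_male_competition_with_truth(pop: PopulationParams, sample_rate: int = DEFAULT_SAMPLE_RATE,
                                    seed: int | np.random.Generator | None = None,
                                    part_a_duration: float = 1.0,
                                    ) -> tuple[WaveformSignal, GroundTruth]:
    rng = _as_rng(seed)
    mvf, pr = sample_class_params(pop, "competition", rng)
    spec = CompetitionSpec(
        part_a=PulseTrainSpec(mvf=mvf, pulse_rate=pr, duration=part_a_duration),
        n_short=int(rng.integers(2, 5)),
    )
    chunks: list[np.ndarray] = [np.zeros(int(_SILENCE * sample_rate))]
    pos = chunks[0].size
    parts: list[SegmentPart] = []

    train = gen_pulse_train(spec.part_a, sample_rate)
    a_start = pos
    chunks.append(train.samples)
    pos += train.samples.size
    parts.append(SegmentPart("a", a_start, pos,
                             pulse_count=int(round(part_a_duration * pr))))

    gap = np.zeros(int(0.1 * sample_rate))
    chunks.append(gap)
    pos += gap.size

    b_start = pos
    for k in range(spec.n_short):
        if k > 0:
            g = np.zeros(int(rng.uniform(0.02, 0.06) * sample_rate))
            chunks.append(g)
            pos += g.size
        burst = _burst(spec.short_pulse_dur, sample_rate, mvf, rng.uniform(0.5, 1.0))
        chunks.append(burst)
        pos += burst.size
    parts.append(SegmentPart("b", b_start, pos, pulse_count=spec.n_short))

    chunks.append(np.zeros(int(_SILENCE * sample_rate)))
    samples = _add_noise(np.concatenate(chunks), pop.noise_snr_db, rng)
    truth = GroundTruth("male_competition", mvf, pr, Segmentation(parts))
    return WaveformSignal(samples, sample_rate, "male_competition"), truth


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def gen_corpus(pop: PopulationParams, n_female: int, n_male_court: int, n_male_comp: int,
               out_dir: str | Path | None = None,
               seed: int | None = 0,
               sample_rate: int = DEFAULT_SAMPLE_RATE,
               female_duration: float = 2.0,
               ) -> tuple[list[WaveformSignal], pd.DataFrame]:
    """Generate a labelled corpus of synthetic signals plus a ground-truth table.

    Emits ``n`` signals per class; when ``out_dir`` is given each signal is
    written as a mono float32 WAV and the table as ``ground_truth.csv``
    (columns: file, class, mvf_hz, pulse_rate_hz, part_boundaries, seed).
    Deterministic under a fixed seed.
    """
    if min(n_female, n_male_court, n_male_comp) < 0:
        raise ValueError("corpus counts must be non-negative")
    rng = np.random.default_rng(seed)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    signals: list[WaveformSignal] = []
    rows: list[dict] = []

    def emit(idx: int, signal: WaveformSignal, truth: GroundTruth) -> None:
        fname = f"{truth.signal_class}_{idx:04d}.wav"
        signals.append(signal)
        rows.append({
            "file": fname,
            "class": truth.signal_class,
            "mvf_hz": round(truth.mvf, 6),
            "pulse_rate_hz": round(truth.pulse_rate, 6),
            "part_boundaries": truth.segmentation.boundary_string(),
            "seed": seed if seed is not None else "",
        })
        if out_dir is not None:
            from .io import write_wav  # deferred: io imports core only
            write_wav(signal, Path(out_dir) / fname)

    for i in range(n_female):
        emit(i, *gen_female_courtship_with_truth(pop, female_duration, sample_rate, rng))
    for i in range(n_male_court):
        emit(i, *gen_male_courtship_with_truth(pop, sample_rate, rng))
    for i in range(n_male_comp):
        emit(i, *gen_male_competition_with_truth(pop, sample_rate, rng))

    table = pd.DataFrame(rows, columns=["file", "class", "mvf_hz", "pulse_rate_hz",
                                        "part_boundaries", "seed"])
    if out_dir is not None:
        from .io import atomic_write_text
        atomic_write_text(Path(out_dir) / "ground_truth.csv", table.to_csv(index=False))
    return signals, table
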