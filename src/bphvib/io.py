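"""Waveform and table I/O, configuration, and plotting.

WAV files are RIFF mono, 32-bit float by default (bit-exact round trips)
with 16-bit PCM behind a flag.  All writes are atomic: content goes to a
temporary file in the target directory which is then renamed, so an
interrupted run never leaves a partial output.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy.io import wavfile

from .core import WaveformSignal

__all__ = [
    "read_wav",
    "write_wav",
    "atomic_write_text",
    "atomic_write_json",
    "RunConfig",
    "load_config",
    "plot_oscillogram_spectrogram",
]


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------


def _atomic_replace(path: Path, write_fn) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def atomic_write_text(path, text: str) -> None:
    """Write text atomically (write to temp file, then rename)."""
    _atomic_replace(Path(path), lambda tmp: Path(tmp).write_text(text))


def atomic_write_json(path, obj) -> None:
    """Write a JSON document atomically."""
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------


def read_wav(path) -> WaveformSignal:
    """Read a mono RIFF WAV (16-bit PCM or 32-bit float) as a waveform.

    PCM16 samples are scaled to [-1, 1) by 1/32768.  Multichannel files and
    other encodings are rejected with an error naming the encoding.
    """
    sample_rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono WAV, got {data.shape[1]} channels"
        )
    if data.dtype == np.float32 or data.dtype == np.float64:
        samples = data.astype(np.float64)
    elif data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    else:
        raise ValueError(
            f"{path}: unsupported WAV encoding {data.dtype}; use float32 or 16-bit PCM"
        )
    return WaveformSignal(samples, int(sample_rate))


def write_wav(signal: WaveformSignal, path, encoding: str = "float32") -> None:
    """Write a waveform as mono RIFF WAV, atomically.

    ``encoding="float32"`` (default) round-trips bit-exactly through
    :func:`read_wav`; ``"pcm16"`` quantizes to 16 bits (values clipped to
    [-1, 1]).
    """
    if encoding == "float32":
        data = signal.samples.astype(np.float32)
    elif encoding == "pcm16":
        # symmetric 1/32768 step so the round trip error stays within 1 LSB
        q = np.round(np.clip(signal.samples, -1.0, 1.0) * 32768.0)
        data = np.clip(q, -32768, 32767).astype(np.int16)
    else:
        raise ValueError(f"unsupported WAV encoding {encoding!r}")
    _atomic_replace(Path(path), lambda tmp: wavfile.write(tmp, signal.sample_rate, data))


def write_sidecar(signal_path, params: dict) -> Path:
    """Write a JSON sidecar recording generation parameters for provenance."""
    sidecar = Path(signal_path).with_suffix(".json")
    atomic_write_json(sidecar, params)
    return sidecar


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class ClassMomentsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mvf_mean: float
    mvf_sd: float = Field(ge=0)
    pr_mean: float
    pr_sd: float = Field(ge=0)


class PopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    female: ClassMomentsConfig = ClassMomentsConfig(
        mvf_mean=236, mvf_sd=43, pr_mean=23, pr_sd=2)
    male_courtship: ClassMomentsConfig = ClassMomentsConfig(
        mvf_mean=255, mvf_sd=24, pr_mean=82, pr_sd=5)
    competition: ClassMomentsConfig = ClassMomentsConfig(
        mvf_mean=281, mvf_sd=46, pr_mean=82, pr_sd=5)
    noise_snr_db: float | None = 20.0


class ProtocolConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arp_window: float = Field(10.0, gt=0)
    arp_required_consecutive: int = Field(2, ge=1)
    observation_window: float = Field(45.0, gt=0)
    inter_trial_wait: float = Field(60.0, gt=0)
    retest_wait: float = Field(60.0, gt=0)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    sample_rate: int = Field(8000, gt=0)
    seed: int = 0
    female_duration: float = Field(2.0, gt=0)
    disruptor_duration: float = Field(2.0, gt=0)
    n_female: int = Field(60, ge=0)
    n_male_court: int = Field(66, ge=0)
    n_male_comp: int = Field(39, ge=0)
    n_trials_per_condition: int = Field(45, ge=0)
    population: PopulationConfig = PopulationConfig()
    protocol: ProtocolConfigModel = ProtocolConfigModel()
    out_dir: str = "bphvib_out"
    log_level: str = "INFO"

    def population_params(self):
        from .synth import ClassMoments, PopulationParams
        p = self.population
        return PopulationParams(
            female=ClassMoments(**p.female.model_dump()),
            male_courtship=ClassMoments(**p.male_courtship.model_dump()),
            competition=ClassMoments(**p.competition.model_dump()),
            noise_snr_db=p.noise_snr_db,
        )

    def protocol_config(self):
        from .behavior import ProtocolConfig
        return ProtocolConfig(**self.protocol.model_dump())


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(raw or {})


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_oscillogram_spectrogram(signal: WaveformSignal, path,
                                 max_freq: float = 500.0) -> None:
    """Two-panel figure: time-domain trace above a 0-``max_freq`` spectrogram."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy import signal as sps

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    ax1.plot(signal.times(), signal.samples, lw=0.4, color="k")
    ax1.set_ylabel("Amplitude")
    if signal.label:
        ax1.set_title(signal.label)
    nperseg = min(len(signal), max(int(0.1 * signal.sample_rate), 64))
    f, t, sxx = sps.spectrogram(signal.samples, fs=signal.sample_rate,
                                nperseg=nperseg, noverlap=nperseg // 2)
    keep = f <= max_freq
    power_db = 10 * np.log10(sxx[keep] + 1e-20)
    ax2.pcolormesh(t, f[keep], power_db, shading="gouraud", cmap="magma")
    ax2.set_ylabel("Frequency (Hz)")
    ax2.set_xlabel("Time (s)")
    ax2.set_ylim(0, max_freq)
    fig.tight_layout()
    _atomic_replace(Path(path), lambda tmp: fig.savefig(tmp, format=Path(path).suffix.lstrip(".") or "png",
                                                        dpi=100, metadata={"Software": None}))
    plt.close(fig)
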