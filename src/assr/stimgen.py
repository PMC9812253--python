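"""Synthesis and QC of the 40 Hz amplitude-modulated tone stimulus.

The stimulus is a pure-tone carrier multiplied by a raised cosine
envelope::

    A(t) = sin(2 pi f_c t) * (1 + m * cos(2 pi f_m t))

with carrier frequency ``f_c`` (default 1000 Hz), modulation depth
``m`` (default 1) and modulation frequency ``f_m`` (default 40 Hz).
Full-depth modulation at 40 Hz entrains the auditory steady-state
response at the modulation rate; the spectrum consists of the carrier
plus two sidebands at ``f_c +/- f_m`` whose magnitude is ``m/2`` of the
carrier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = [
    "StimulusSpec",
    "Waveform",
    "SidebandReport",
    "generate_am_tone",
    "validate_spectrum",
    "write_wav",
    "read_wav",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the amplitude-modulated tone.

    Parameters
    ----------
    carrier_freq_hz : float
        Carrier frequency ``f_c`` in Hz.
    mod_freq_hz : float
        Modulation frequency ``f_m`` in Hz.
    mod_depth : float
        Modulation depth ``m`` in [0, 1].
    duration_s : float
        Stimulus duration in seconds.
    sample_rate_hz : float
        Sampling rate of the synthesized waveform.
    ramp_s : float
        Optional cosine onset/offset ramp duration in seconds.  Off
        (0.0) by default: no ramp is part of the canonical stimulus.
    """

    carrier_freq_hz: float = 1000.0
    mod_freq_hz: float = 40.0
    mod_depth: float = 1.0
    duration_s: float = 1.0
    sample_rate_hz: float = 44100.0
    ramp_s: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_freq_hz <= 0 or self.mod_freq_hz <= 0:
            raise ValueError("carrier and modulation frequencies must be positive")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be positive")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError(f"mod_depth must lie in [0, 1], got {self.mod_depth}")
        if self.ramp_s < 0 or 2 * self.ramp_s > self.duration_s:
            raise ValueError("ramp_s must be nonnegative and fit twice into the duration")

    @property
    def n_samples(self) -> int:
        """Sample count: round(duration * rate); t starts at 0."""
        return int(round(self.duration_s * self.sample_rate_hz))


@dataclass(frozen=True)
class Waveform:
    """A sampled waveform with its sampling rate (amplitude dimensionless)."""

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass(frozen=True)
class SidebandReport:
    """Dominant spectral peaks of an AM tone (carrier and sidebands)."""

    peak_freqs_hz: np.ndarray
    peak_magnitudes: np.ndarray  # relative to the largest peak (=1)


def generate_am_tone(spec: StimulusSpec) -> Waveform:
    """Synthesize the amplitude-modulated tone defined by ``spec``.

    Sample ``i`` equals ``sin(2 pi f_c t_i) * (1 + m cos(2 pi f_m t_i))``
    with ``t_i = i / sample_rate_hz`` starting at 0.  If ``spec.ramp_s``
    is positive, a cosine-squared onset/offset ramp is applied.
    """
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    samples = np.sin(2 * np.pi * spec.carrier_freq_hz * t) * (
        1.0 + spec.mod_depth * np.cos(2 * np.pi * spec.mod_freq_hz * t)
    )
    if spec.ramp_s > 0:
        n_ramp = int(round(spec.ramp_s * spec.sample_rate_hz))
        if n_ramp > 0:
            ramp = np.sin(np.linspace(0, np.pi / 2, n_ramp)) ** 2
            samples[:n_ramp] *= ramp
            samples[-n_ramp:] *= ramp[::-1]
    return Waveform(samples=samples, sample_rate_hz=spec.sample_rate_hz)


def validate_spectrum(wave: Waveform, spec: StimulusSpec, n_peaks: int = 3) -> SidebandReport:
    """Locate the dominant spectral peaks of an AM tone.

    For the canonical stimulus the three dominant peaks are the carrier
    ``f_c`` and the sidebands ``f_c +/- f_m``; with ``m = 0`` only the
    carrier remains.  Peaks are local maxima of the magnitude spectrum,
    reported in ascending frequency with magnitudes relative to the
    largest peak.  Peaks below 1% of the maximum are discarded, so an
    unmodulated carrier yields a single peak.
    """
    if len(wave.samples) < wave.sample_rate_hz / spec.mod_freq_hz:
        raise ValueError("waveform shorter than one modulation period")
    mag = np.abs(np.fft.rfft(wave.samples))
    freqs = np.fft.rfftfreq(len(wave.samples), d=1.0 / wave.sample_rate_hz)
    # local maxima, strict on the left to absorb plateaus
    interior = (mag[1:-1] > mag[:-2]) & (mag[1:-1] >= mag[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[mag[idx] >= 0.01 * mag.max()]
    order = np.argsort(mag[idx])[::-1][:n_peaks]
    sel = np.sort(idx[order])
    return SidebandReport(peak_freqs_hz=freqs[sel], peak_magnitudes=mag[sel] / mag[sel].max())


def write_wav(
    wave: Waveform,
    path,
    *,
    dtype: str = "int16",
    peak_normalize: bool = True,
    target_level: float = 0.95,
) -> None:
    """Write a waveform to a WAV file.

    By default the output is peak-normalized to ``target_level`` of full
    scale (presentation level in the lab is a hardware calibration, not
    a property of the file); the in-memory :class:`Waveform` keeps its
    raw amplitudes.  ``dtype`` selects 16-bit PCM or float32.
    """
    samples = np.asarray(wave.samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot write an empty waveform")
    if not np.all(np.isfinite(samples)):
        raise ValueError("waveform contains non-finite samples")
    if peak_normalize:
        peak = np.max(np.abs(samples))
        if peak > 0:
            samples = samples * (target_level / peak)
    if dtype == "int16":
        data = np.clip(np.round(samples * 32767.0), -32768, 32767).astype(np.int16)
    elif dtype == "float32":
        data = samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}; use 'int16' or 'float32'")
    wavfile.write(path, int(round(wave.sample_rate_hz)), data)


def read_wav(path) -> Waveform:
    """Read a WAV file back into a :class:`Waveform` on the [-1, 1] scale."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        samples = data / 32767.0
    else:
        samples = data.astype(float)
    return Waveform(samples=samples, sample_rate_hz=float(rate))
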