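"""Amplitude-envelope and narrowband-phase extraction.

Audio is reduced to a slow amplitude envelope in one of two ways:

* ``cochlear_envelope`` — a gammatone filterbank with ERB-spaced channels
  spanning the speech-relevant band (180–7246 Hz by default); the envelope is
  the across-channel mean of per-channel Hilbert magnitudes.  This emulates
  the "cochlear envelope" commonly computed for syllable-train stimuli.
* ``hilbert_envelope`` — the magnitude of the analytic signal of the raw
  waveform, the standard broadband envelope for recorded speech.

Envelopes are then downsampled (100 Hz by default elsewhere in the pipeline)
and bandpass filtered in the theta/syllable band (3.5–5.5 Hz) before the
instantaneous phase is taken, again via the Hilbert transform.  All filtering
is zero-phase so that phase relations between two envelopes are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "EnvelopeSeries",
    "PhaseSeries",
    "erb_space",
    "cochlear_envelope",
    "hilbert_envelope",
    "resample_envelope",
    "bandpass_phase",
]


@dataclass
class AudioRecording:
    """A mono audio signal with its sampling rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 2:
            # stereo or multichannel: average to mono
            warnings.warn(
                "multichannel audio averaged to mono", stacklevel=3
            )
            self.samples = self.samples.mean(axis=1)
        if self.samples.ndim != 1:
            raise ValueError("audio must be a 1-D (mono) sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @classmethod
    def from_wav(cls, path) -> "AudioRecording":
        fs, data = wavfile.read(path)
        data = np.asarray(data)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        return cls(samples=data.astype(float), sample_rate=float(fs))

    def to_wav(self, path) -> None:
        wavfile.write(path, int(round(self.sample_rate)),
                      self.samples.astype(np.float32))


@dataclass
class EnvelopeSeries:
    """Uniformly sampled nonnegative amplitude envelope.

    ``kind`` records provenance: ``"cochlear"`` (gammatone filterbank) or
    ``"hilbert"`` (broadband analytic magnitude).
    """

    values: np.ndarray
    sample_rate: float
    kind: str = "hilbert"
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be 1-D")
        if np.any(self.values < -1e-12):
            raise ValueError("envelope values must be nonnegative")
        self.values = np.maximum(self.values, 0.0)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


@dataclass
class PhaseSeries:
    """Instantaneous narrowband phase in (-pi, pi].

    ``edge_trim_s`` marks how much of each end is contaminated by
    filter/Hilbert edge effects; PLV computations may drop it.
    """

    phase: np.ndarray
    sample_rate: float
    band: tuple[float, float] = (3.5, 5.5)
    edge_trim_s: float = 1.0
    source_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 1 or len(self.phase) < 2:
            raise ValueError("phase series must be 1-D with length >= 2")
        if self.band[0] >= self.band[1]:
            raise ValueError("band low edge must be below high edge")

    def __len__(self) -> int:
        return len(self.phase)

    def trimmed(self) -> np.ndarray:
        """Phase with ``edge_trim_s`` removed from both ends (if possible)."""
        k = int(round(self.edge_trim_s * self.sample_rate))
        if k > 0 and len(self.phase) > 2 * k + 2:
            return self.phase[k:-k]
        return self.phase


# ---------------------------------------------------------------------------
# gammatone filterbank


def _hz_to_erb_number(f: np.ndarray | float) -> np.ndarray | float:
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=float))


def _erb_number_to_hz(e: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_space(low_hz: float, high_hz: float, n: int) -> np.ndarray:
    """``n`` centre frequencies equally spaced on the ERB-number scale."""
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if n < 1:
        raise ValueError("need at least one channel")
    e = np.linspace(_hz_to_erb_number(low_hz), _hz_to_erb_number(high_hz), n)
    return np.asarray(_erb_number_to_hz(e), dtype=float)


def cochlear_envelope(
    audio: AudioRecording,
    n_channels: int = 30,
    band: tuple[float, float] = (180.0, 7246.0),
) -> EnvelopeSeries:
    """Across-channel mean of gammatone-channel Hilbert envelopes.

    Parameters
    ----------
    audio : AudioRecording
        Mono input signal.
    n_channels : int
        Number of ERB-spaced gammatone channels.
    band : (low_hz, high_hz)
        Centre-frequency range of the filterbank; must lie inside Nyquist.
    """
    nyq = audio.sample_rate / 2.0
    if band[1] >= nyq:
        raise ValueError(
            f"filterbank band {band} exceeds Nyquist frequency {nyq} Hz"
        )
    if len(audio.samples) < 8:
        raise ValueError("audio too short for filterbank analysis")
    cfs = erb_space(band[0], band[1], n_channels)
    acc = np.zeros_like(audio.samples)
    for cf in cfs:
        b, a = signal.gammatone(cf, "iir", fs=audio.sample_rate)
        channel = signal.lfilter(b, a, audio.samples)
        acc += np.abs(signal.hilbert(channel))
    return EnvelopeSeries(
        values=acc / n_channels,
        sample_rate=audio.sample_rate,
        kind="cochlear",
        source_id=getattr(audio, "source_id", None),
    )


def hilbert_envelope(audio: AudioRecording) -> EnvelopeSeries:
    """Broadband amplitude envelope: magnitude of the analytic signal."""
    if len(audio.samples) < 2:
        raise ValueError("audio must contain at least 2 samples")
    env = np.abs(signal.hilbert(audio.samples))
    return EnvelopeSeries(values=env, sample_rate=audio.sample_rate,
                          kind="hilbert")


def resample_envelope(env: EnvelopeSeries, target_hz: float) -> EnvelopeSeries:
    """Anti-alias filtered polyphase downsampling of an envelope.

    Only downsampling is supported; the analysis pipeline never upsamples.
    """
    if target_hz >= env.sample_rate:
        raise ValueError(
            f"target rate {target_hz} Hz must be below current rate "
            f"{env.sample_rate} Hz (only downsampling is supported)"
        )
    frac = Fraction(target_hz / env.sample_rate).limit_denominator(10000)
    out = signal.resample_poly(env.values, frac.numerator, frac.denominator)
    # polyphase ringing can produce tiny negative excursions
    out = np.maximum(out, 0.0)
    return EnvelopeSeries(values=out, sample_rate=target_hz, kind=env.kind,
                          source_id=env.source_id)


def bandpass_phase(
    env: EnvelopeSeries,
    band: tuple[float, float] = (3.5, 5.5),
    order: int = 4,
    edge_trim_s: float = 1.0,
) -> PhaseSeries:
    """Zero-phase bandpass then Hilbert instantaneous phase.

    A Butterworth filter of the given order is applied forward-backward
    (``sosfiltfilt``) so group delay is zero and the phase relation between
    two envelopes filtered the same way is preserved.
    """
    nyq = env.sample_rate / 2.0
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=env.sample_rate,
                        output="sos")
    narrow = signal.sosfiltfilt(sos, env.values - env.values.mean())
    phase = np.angle(signal.hilbert(narrow))
    return PhaseSeries(phase=phase, sample_rate=env.sample_rate, band=band,
                       edge_trim_s=edge_trim_s, source_id=env.source_id)
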