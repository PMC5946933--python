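"""Waveform container and 16-bit PCM WAV input/output.

Recordings of stored-product insect activity are mono WAV files sampled at
44.1 kHz. Amplitudes are kept dimensionless in [-1, 1]; full-scale
corresponds to the recorder's clipping point.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 44100.0

__all__ = ["Waveform", "WavReadError", "read_wav", "write_wav", "DEFAULT_SAMPLE_RATE"]


class WavReadError(RuntimeError):
    """Raised when a WAV file cannot be decoded as mono/first-channel PCM."""


@dataclass(frozen=True)
class Waveform:
    """A sampled audio signal.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitudes, nominally in [-1, 1].
    sample_rate : float
        Sampling rate in Hz (44100 for the recorders this package targets).
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)

    def segment(self, start: float, end: float) -> "Waveform":
        """Contiguous sub-waveform between two times (seconds)."""
        i0 = max(0, int(round(start * self.sample_rate)))
        i1 = min(len(self.samples), int(round(end * self.sample_rate)))
        if i1 <= i0:
            raise ValueError(f"empty segment [{start}, {end}] s")
        return Waveform(self.samples[i0:i1], self.sample_rate)


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file, scaling amplitudes to [-1, 1].

    Stereo files are reduced to their first channel (a warning is logged);
    8-, 16- and 32-bit integer PCM are supported. Truncated or compressed
    files raise :class:`WavReadError` naming the file and, for truncation,
    the byte offset at which data ran out.
    """
    path = Path(path)
    try:
        with wave.open(str(path), "rb") as handle:
            n_channels = handle.getnchannels()
            sampwidth = handle.getsampwidth()
            framerate = handle.getframerate()
            n_frames = handle.getnframes()
            raw = handle.readframes(n_frames)
    except (wave.Error, EOFError) as exc:
        raise WavReadError(f"{path}: not a readable PCM WAV file ({exc})") from exc

    expected = n_frames * n_channels * sampwidth
    if len(raw) < expected:
        # 44 bytes is the canonical RIFF/fmt/data header size for plain PCM.
        raise WavReadError(
            f"{path}: truncated at byte {44 + len(raw)} "
            f"(expected {44 + expected} bytes of audio data)"
        )

    dtypes = {1: np.uint8, 2: np.dtype("<i2"), 4: np.dtype("<i4")}
    if sampwidth not in dtypes:
        raise WavReadError(f"{path}: unsupported sample width {sampwidth} bytes")
    data = np.frombuffer(raw, dtype=dtypes[sampwidth])

    if n_channels > 1:
        logger.warning("%s: %d channels; using first channel only", path, n_channels)
        data = data[::n_channels]

    # Divide by the positive full-scale value so write_wav/read_wav round-trips
    # reproduce quantized amplitudes exactly.
    if sampwidth == 1:  # unsigned 8-bit convention
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64) / float(2 ** (8 * sampwidth - 1) - 1)
    return Waveform(samples, float(framerate))


def write_wav(path: str | Path, waveform: Waveform) -> None:
    """Write a mono 16-bit PCM WAV file. Samples are clipped to [-1, 1]."""
    clipped = np.clip(waveform.samples, -1.0, 1.0)
    data = (clipped * 32767.0).round().astype("<i2")
    with wave.open(str(path), "wb") as handle:
        handle.setnchannels(1)
        handle.setsampwidth(2)
        handle.setframerate(int(round(waveform.sample_rate)))
        handle.writeframes(data.tobytes())
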