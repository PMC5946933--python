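"""Detection of brief sound impulses in grain-mass recordings.

Feeding and movement sounds of stored-product insects occur as trains of
brief (1-10 ms) broadband impulses. This module finds candidate impulses
with an envelope detector over a robust (median/MAD) noise floor and
attaches a normalized power spectrum to each, ready for template matching.

The detector's constants are all exposed in :class:`DetectionConfig`;
defaults were tuned on the synthetic fixtures shipped with the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .audio import Waveform, read_wav

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumVector",
    "Impulse",
    "DetectionConfig",
    "read_wav",
    "select_analysis_window",
    "detect_impulses",
    "extract_spectrum",
]

#: Timestamps are reported at 0.1 ms resolution.
TIME_DECIMALS = 4


@dataclass(frozen=True)
class SpectrumVector:
    """One-sided power spectrum normalized to unit total power.

    ``values`` has ``n_fft // 2 + 1`` non-negative entries summing to 1,
    covering 0 Hz to the Nyquist frequency.
    """

    values: np.ndarray = field(repr=False)
    n_fft: int = 256
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or len(values) != self.n_fft // 2 + 1:
            raise ValueError(
                f"spectrum must have n_fft/2 + 1 = {self.n_fft // 2 + 1} bins, "
                f"got {values.shape}"
            )
        if np.any(values < 0):
            raise ValueError("spectral power must be non-negative")
        total = values.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum must sum to 1 (got {total!r}); "
                             "use SpectrumVector.from_power to normalize")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_power(cls, power: np.ndarray, n_fft: int = 256,
                   sample_rate: float = 44100.0) -> "SpectrumVector":
        """Build a unit-total-power spectrum from raw non-negative power."""
        power = np.asarray(power, dtype=np.float64)
        total = power.sum()
        if total <= 0:
            # a silent window carries no spectral information; use flat power
            power = np.ones_like(power)
            total = power.sum()
        return cls(power / total, n_fft=n_fft, sample_rate=sample_rate)

    @property
    def frequencies(self) -> np.ndarray:
        """Bin center frequencies in Hz."""
        return np.fft.rfftfreq(self.n_fft, d=1.0 / self.sample_rate)


@dataclass(frozen=True)
class Impulse:
    """A detected transient: onset/duration in seconds plus its spectrum."""

    onset: float
    duration: float
    peak_amplitude: float
    spectrum: SpectrumVector

    def __post_init__(self) -> None:
        if not 0.0005 <= self.duration <= 0.020:
            raise ValueError(
                f"impulse duration {self.duration * 1e3:.2f} ms outside the "
                "0.5-20 ms range retained by the detector"
            )
        if self.onset < 0:
            raise ValueError("impulse onset must be non-negative")


@dataclass(frozen=True)
class DetectionConfig:
    """Envelope-detector constants.

    Attributes
    ----------
    envelope_smoothing : float
        Moving-average width (s) applied to the rectified signal.
    threshold_k : float
        Event threshold in multiples of the envelope's MAD above its median.
    dead_time : float
        Events closer than this (s) are merged into one impulse.
    min_duration, max_duration : float
        Events outside this range (s) are discarded as noise; insect
        impulses are 1-10 ms so a 2x margin is allowed above.
    highpass_cutoff : float
        High-pass corner (Hz) suppressing room rumble below the insect band.
    """

    envelope_smoothing: float = 0.001
    threshold_k: float = 8.0
    dead_time: float = 0.020
    min_duration: float = 0.0005
    max_duration: float = 0.020
    highpass_cutoff: float = 200.0

    def __post_init__(self) -> None:
        if self.dead_time < self.max_duration:
            raise ValueError("dead_time must be >= max_duration")
        if not self.min_duration < self.max_duration:
            raise ValueError("min_duration must be < max_duration")
        if self.envelope_smoothing <= 0:
            raise ValueError("envelope_smoothing must be positive")


def select_analysis_window(
    waveform: Waveform,
    min_len: float = 77.0,
    max_len: float = 300.0,
    rng: np.random.Generator | int | None = None,
) -> Waveform:
    """Select a random contiguous analysis segment of 77-300 s.

    Long recordings are subsampled for analysis: the segment length is drawn
    uniformly from ``[min_len, min(max_len, record length)]`` and its start
    uniformly over feasible positions. A recording shorter than ``min_len``
    is returned whole with a warning, so short fixtures remain analyzable.
    """
    rng = np.random.default_rng(rng)
    total = waveform.duration
    if total < min_len:
        logger.warning(
            "recording is %.1f s, shorter than the %.0f s analysis minimum; "
            "analyzing it whole", total, min_len,
        )
        return waveform
    length = rng.uniform(min_len, min(max_len, total))
    start = rng.uniform(0.0, total - length)
    return waveform.segment(start, start + length)


def _merge_runs(starts: np.ndarray, ends: np.ndarray, gap_samples: int):
    """Merge [start, end) sample runs separated by fewer than gap_samples."""
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return merged


def detect_impulses(
    waveform: Waveform, config: DetectionConfig | None = None, n_fft: int = 256
) -> list[Impulse]:
    """Detect candidate insect sound impulses in a waveform.

    The signal is high-pass filtered, rectified and smoothed; samples where
    the envelope exceeds ``median + threshold_k * MAD`` seed events, nearby
    events are merged within ``dead_time``, and events outside the allowed
    duration range are discarded. Returned impulses are sorted by onset and
    carry spectra from :func:`extract_spectrum`.

    An all-zero (silent) input yields an empty list.
    """
    cfg = config or DetectionConfig()
    x = waveform.samples
    if len(x) == 0 or not np.any(x):
        return []
    fs = waveform.sample_rate

    sos = signal.butter(4, cfg.highpass_cutoff, btype="highpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x)

    smooth_n = max(1, int(round(cfg.envelope_smoothing * fs)))
    envelope = uniform_filter1d(np.abs(filtered), size=smooth_n, mode="nearest")

    med = np.median(envelope)
    mad = np.median(np.abs(envelope - med))
    # a degenerate noise floor (kernels in near-digital silence leaves only
    # ~1e-17 filter residue) would put the threshold at numerical dust; keep
    # it at least a small fraction of the peak so isolated events register
    mad = max(mad, envelope.max() * 1e-3, np.finfo(float).tiny)
    threshold = med + cfg.threshold_k * mad

    above = envelope > threshold
    if not above.any():
        return []
    # pad so every run has both a rising and a falling edge
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_starts = edges[0::2]
    run_ends = edges[1::2]

    gap_samples = int(round(cfg.dead_time * fs))
    runs = _merge_runs(run_starts, run_ends, gap_samples)

    # compensate the moving-average group delay: the envelope rises roughly
    # half a smoothing window before the rectified peak crosses threshold
    half_smooth = smooth_n // 2

    filtered_wave = Waveform(filtered, fs)
    impulses: list[Impulse] = []
    for s, e in runs:
        duration = (e - s) / fs
        if not cfg.min_duration <= duration <= cfg.max_duration:
            continue
        onset_idx = min(len(x) - 1, s + half_smooth)
        onset = round(onset_idx / fs, TIME_DECIMALS)
        peak = float(np.max(np.abs(filtered[s:e])))
        spectrum = extract_spectrum(filtered_wave, s / fs, duration, n_fft=n_fft)
        impulses.append(
            Impulse(onset=onset, duration=round(duration, TIME_DECIMALS),
                    peak_amplitude=peak, spectrum=spectrum)
        )
    return impulses


def extract_spectrum(
    waveform: Waveform, onset: float, duration: float, n_fft: int = 256
) -> SpectrumVector:
    """Averaged Hann-windowed power spectrum of one impulse.

    The impulse segment is padded symmetrically to at least ``n_fft``
    samples and analyzed with ``n_fft``-point frames at 50% overlap; frame
    periodograms are averaged and the result normalized to unit total power.
    """
    fs = waveform.sample_rate
    n = len(waveform.samples)
    if not 0 <= onset <= n / fs:
        raise ValueError(f"onset {onset} s outside recording of {n / fs:.3f} s")
    i0 = int(round(onset * fs))
    i1 = min(n, max(i0 + 1, int(round((onset + duration) * fs))))
    seg = waveform.samples[i0:i1]
    if len(seg) < n_fft:
        pad = n_fft - len(seg)
        seg = np.pad(seg, (pad // 2, pad - pad // 2))
    freqs, power = signal.welch(
        seg,
        fs=fs,
        window="hann",
        nperseg=n_fft,
        noverlap=n_fft // 2,
        detrend=False,
        scaling="spectrum",
    )
    return SpectrumVector.from_power(power, n_fft=n_fft, sample_rate=fs)
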