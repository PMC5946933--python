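"""End-to-end recording analysis and evaluation against ground truth.

Chains the stages: (optional) random 77-300 s analysis-window selection,
impulse detection, spectral-profile classification, burst grouping, and
activity measures, producing the per-file summary a monitoring workflow
needs. Evaluation helpers score detected bursts and impulses against the
synthetic generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .audio import Waveform
from .bursts import ActivityMeasures, Burst, activity_measures, group_bursts, infestation_flag
from .detection import DetectionConfig, detect_impulses, select_analysis_window
from .profiles import (
    DEFAULT_SSE_THRESHOLD,
    ClassifiedImpulse,
    SpectralProfile,
    classify_impulses,
    default_profiles,
    insect_onsets,
)

__all__ = [
    "RecordingAnalysis",
    "analyze_recording",
    "BurstScore",
    "score_bursts",
    "score_impulses",
]


@dataclass(frozen=True)
class RecordingAnalysis:
    """Everything the pipeline derives from one recording segment."""

    measures: ActivityMeasures
    bursts: list[Burst]
    impulses: list[ClassifiedImpulse]
    segment_duration: float
    infested: bool


def analyze_recording(
    waveform: Waveform,
    profiles: Sequence[SpectralProfile] | None = None,
    config: DetectionConfig | None = None,
    sse_threshold: float = DEFAULT_SSE_THRESHOLD,
    subsample_window: bool = False,
    rng: np.random.Generator | int | None = None,
) -> RecordingAnalysis:
    """Run detection, classification, burst grouping and activity measures.

    With ``subsample_window=True`` a random 77-300 s segment is analyzed
    (the routine practice for hour-long recordings); otherwise the whole
    waveform is used.
    """
    if profiles is None:
        profiles = default_profiles()
    segment = (
        select_analysis_window(waveform, rng=rng) if subsample_window else waveform
    )
    impulses = detect_impulses(segment, config)
    classified = classify_impulses(impulses, profiles, sse_threshold)
    bursts = group_bursts(insect_onsets(classified))
    measures = activity_measures(bursts, segment.duration)
    return RecordingAnalysis(
        measures=measures,
        bursts=bursts,
        impulses=classified,
        segment_duration=segment.duration,
        infested=infestation_flag(measures.rb),
    )


@dataclass(frozen=True)
class BurstScore:
    """Burst-level agreement between detections and ground truth."""

    n_truth: int
    n_detected: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def false_rate(self) -> float:
        """Fraction of detected bursts not matching any true burst."""
        if self.n_detected == 0:
            return 0.0
        return (self.n_detected - self.n_matched) / self.n_detected


def score_bursts(
    truth_intervals: Sequence[tuple[float, float]],
    detected: Sequence[Burst],
    pad: float = 0.05,
) -> BurstScore:
    """One-to-one interval matching of detected bursts to true bursts.

    A detected burst matches a true burst when their time intervals overlap
    after padding each true interval by ``pad`` seconds; each true burst
    may claim at most one detection and vice versa (greedy in time order).
    """
    truth = sorted(truth_intervals)
    dets = sorted(detected, key=lambda b: b.start)
    used = [False] * len(dets)
    matched = 0
    for ts, te in truth:
        for i, b in enumerate(dets):
            if used[i]:
                continue
            if b.start <= te + pad and b.end >= ts - pad:
                used[i] = True
                matched += 1
                break
    return BurstScore(n_truth=len(truth), n_detected=len(dets), n_matched=matched)


def score_impulses(
    truth_onsets: Sequence[float],
    detected_onsets: Sequence[float],
    tol: float = 0.002,
) -> tuple[int, int, int]:
    """Greedy onset matching within ``tol`` seconds.

    Returns ``(n_truth, n_detected, n_matched)``.
    """
    truth = sorted(truth_onsets)
    dets = sorted(detected_onsets)
    i = j = matched = 0
    while i < len(truth) and j < len(dets):
        if abs(dets[j] - truth[i]) <= tol:
            matched += 1
            i += 1
            j += 1
        elif dets[j] < truth[i]:
            j += 1
        else:
            i += 1
    return len(truth), len(dets), matched
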