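"""Synthetic recordings, oxygen/activity experiments, and grain counts.

No raw recordings or sensor logs ship with this package; instead this
module generates ground-truthed stand-ins with the statistical structure
the analysis assumes:

* acoustic scenes - trains of brief (1-10 ms) damped-sinusoid impulses in
  bursts of >= 3 with intra-burst gaps under 200 ms, over Gaussian noise,
  with spectrally distinct low-frequency distractor events;
* hermetic experiments - per-treatment residual-O2 decline from 21% toward
  a floor, with the three activity measures coupled to O2 depletion through
  the published regression coefficients plus noise;
* grain-count fixtures that round-trip exactly through the count-and-weigh
  weight-loss formula.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio import DEFAULT_SAMPLE_RATE, Waveform
from .coefficients import MEASURES, REFERENCE_COEFFICIENTS, ActivityCoefficients
from .detection import SpectrumVector, extract_spectrum

__all__ = [
    "KernelSpec",
    "AcousticScenario",
    "GroundTruthEvents",
    "Treatment",
    "ExperimentDesign",
    "render_kernel",
    "kernel_spectrum",
    "generate_recording",
    "generate_experiment",
    "generate_grain_counts",
    "default_schedule",
    "INSECT_KERNEL",
    "DISTRACTOR_KERNEL",
    "STUDY_TREATMENTS",
]

#: Default air volumes (ml) measured for wheat-filled jars, by jar size.
AIR_VOLUME_ML = {500: 260.0, 1000: 480.0}

#: Ambient oxygen fraction of air, percent.
AMBIENT_O2_PCT = 21.0


@dataclass(frozen=True)
class KernelSpec:
    """Shape of one rendered sound impulse.

    A damped band-limited oscillation: raised-cosine onset, exponential
    decay at ``decay_rate`` (1/s), carrier at ``center_frequency`` with
    dominant energy inside ``center_frequency +/- bandwidth``. Duration must
    lie in the 1-10 ms range of insect feeding/movement impulses.
    """

    center_frequency: float
    bandwidth: float
    duration: float
    decay_rate: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0.001 <= self.duration <= 0.010:
            raise ValueError(
                f"impulse duration must be 1-10 ms, got {self.duration * 1e3:.2f} ms"
            )
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1] of full scale")
        if self.center_frequency <= 0 or self.bandwidth <= 0:
            raise ValueError("center_frequency and bandwidth must be positive")


#: Default insect impulse: mid-band click typical of feeding sounds in grain.
INSECT_KERNEL = KernelSpec(
    center_frequency=4000.0, bandwidth=2000.0, duration=0.003,
    decay_rate=700.0, amplitude=0.5,
)

#: Default distractor: low-frequency broadband thud (room/handling noise).
DISTRACTOR_KERNEL = KernelSpec(
    center_frequency=500.0, bandwidth=800.0, duration=0.008,
    decay_rate=250.0, amplitude=0.5,
)


def render_kernel(spec: KernelSpec, sample_rate: float = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Render one impulse kernel as a float array.

    The sample count is ``round(duration * sample_rate)`` with ties to
    even. The rendered peak absolute amplitude equals ``spec.amplitude``
    exactly (the kernel is renormalized after shaping); zero amplitude
    yields an all-zero snippet.
    """
    n = round(spec.duration * sample_rate)
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / sample_rate
    onset_len = min(0.0005, spec.duration / 4.0)
    envelope = np.exp(-spec.decay_rate * t)
    ramp = t < onset_len
    envelope[ramp] *= 0.5 * (1.0 - np.cos(np.pi * t[ramp] / onset_len))
    # a two-tone carrier spreads energy across the stated band
    f_lo = spec.center_frequency - spec.bandwidth / 3.0
    f_hi = spec.center_frequency + spec.bandwidth / 3.0
    carrier = np.sin(2 * np.pi * spec.center_frequency * t) + 0.4 * (
        np.sin(2 * np.pi * f_lo * t) + np.sin(2 * np.pi * f_hi * t)
    )
    x = envelope * carrier
    peak = np.max(np.abs(x))
    if peak > 0 and spec.amplitude > 0:
        x *= spec.amplitude / peak
    else:
        x = np.zeros(n)
    return x


def kernel_spectrum(spec: KernelSpec, sample_rate: float = DEFAULT_SAMPLE_RATE,
                    n_fft: int = 256) -> SpectrumVector:
    """Normalized power spectrum of the rendered kernel (detector's view)."""
    rendered = render_kernel(replace(spec, amplitude=max(spec.amplitude, 0.5)),
                             sample_rate)
    return extract_spectrum(Waveform(rendered, sample_rate), 0.0, spec.duration,
                            n_fft=n_fft)


def _cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass(frozen=True)
class GroundTruthEvents:
    """Exact event log of a generated recording."""

    impulse_onsets: list[float]
    impulse_labels: list[str]
    burst_intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        onsets = list(self.impulse_onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("ground-truth onsets must be strictly increasing")
        for onset, label in zip(onsets, self.impulse_labels):
            if label == "insect" and not any(
                s <= onset <= e for s, e in self.burst_intervals
            ):
                raise ValueError(f"insect onset {onset} outside every burst interval")

    @property
    def insect_onsets(self) -> list[float]:
        return [t for t, lab in zip(self.impulse_onsets, self.impulse_labels)
                if lab == "insect"]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.impulse_onsets, "label": self.impulse_labels}
        )

    def bursts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.burst_intervals, columns=["start_s", "end_s"])


@dataclass(frozen=True)
class AcousticScenario:
    """Parameters of one synthetic acoustic scene."""

    duration: float
    burst_rate: float
    sample_rate: float = DEFAULT_SAMPLE_RATE
    impulses_per_burst: tuple[int, int] = (3, 6)
    intra_burst_gap_range: tuple[float, float] = (0.03, 0.15)
    insect_kernel: KernelSpec = INSECT_KERNEL
    noise_floor_rms: float = 0.05
    distractor_rate: float = 0.1
    distractor_kernel: KernelSpec = DISTRACTOR_KERNEL
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 1.0:
            raise ValueError("scenario duration must be at least 1 s")
        if self.burst_rate < 0 or self.distractor_rate < 0:
            raise ValueError("event rates must be non-negative")
        lo, hi = self.impulses_per_burst
        if lo < 3 or hi < lo:
            raise ValueError("impulses per burst must support k >= 3")
        glo, ghi = self.intra_burst_gap_range
        if not 0 < glo <= ghi < 0.2:
            raise ValueError(
                "intra-burst gaps must lie strictly inside (0, 0.2) s so "
                "generated trains satisfy the burst criterion"
            )
        if self.noise_floor_rms < 0:
            raise ValueError("noise_floor_rms must be non-negative")
        sim = _cosine_similarity(
            kernel_spectrum(self.insect_kernel, self.sample_rate).values,
            kernel_spectrum(self.distractor_kernel, self.sample_rate).values,
        )
        if sim >= 0.9:
            raise ValueError(
                f"insect and distractor kernels are spectrally too similar "
                f"(cosine similarity {sim:.3f} >= 0.9); rejection would be untestable"
            )
        max_span = (hi - 1) * ghi + self.insect_kernel.duration
        if self.burst_rate > 0 and self.burst_rate * (max_span + 0.2) >= 1.0:
            raise ValueError(
                f"burst_rate {self.burst_rate}/s cannot maintain >0.2 s "
                f"inter-burst spacing with bursts spanning up to {max_span:.2f} s"
            )


def generate_recording(
    scenario: AcousticScenario,
) -> tuple[Waveform, GroundTruthEvents]:
    """Generate a recording and its exact ground truth.

    Burst starts follow a homogeneous Poisson process at ``burst_rate``,
    thinned so consecutive bursts are separated by more than 200 ms (which
    keeps distinct ground-truth bursts distinct under the grouping rule).
    Each burst holds ``k`` impulses, ``k`` uniform over
    ``impulses_per_burst`` inclusive, with gaps uniform over
    ``intra_burst_gap_range``. Isolated distractor events are placed away
    from bursts, and Gaussian noise of the stated RMS is added last.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    fs = scenario.sample_rate
    n = int(round(scenario.duration * fs))
    samples = np.zeros(n)

    kernel = render_kernel(scenario.insect_kernel, fs)
    kernel_dur = scenario.insect_kernel.duration

    onsets: list[float] = []
    labels: list[str] = []
    bursts: list[tuple[float, float]] = []

    if scenario.burst_rate > 0:
        t = 0.0
        prev_end = -math.inf
        lo, hi = scenario.impulses_per_burst
        glo, ghi = scenario.intra_burst_gap_range
        while True:
            t += rng.exponential(1.0 / scenario.burst_rate)
            if t >= scenario.duration:
                break
            if t <= prev_end + 0.2:
                continue  # thinning keeps inter-burst gaps > 200 ms
            k = int(rng.integers(lo, hi + 1))
            gaps = rng.uniform(glo, ghi, size=k - 1)
            impulse_times = t + np.concatenate(([0.0], np.cumsum(gaps)))
            end = impulse_times[-1] + kernel_dur
            if end >= scenario.duration:
                continue
            for it in impulse_times:
                _add_kernel(samples, kernel, it, fs, rng)
                onsets.append(float(it))
                labels.append("insect")
            bursts.append((float(impulse_times[0]), float(end)))
            prev_end = end

    if scenario.distractor_rate > 0:
        d_kernel = render_kernel(scenario.distractor_kernel, fs)
        d_dur = scenario.distractor_kernel.duration
        n_events = rng.poisson(scenario.distractor_rate * scenario.duration)
        placed = 0
        attempts = 0
        while placed < n_events and attempts < 100 * n_events:
            attempts += 1
            t = rng.uniform(0.0, scenario.duration - d_dur)
            # keep distractors clear of bursts so ground truth stays unambiguous
            if any(s - 0.25 <= t <= e + 0.25 for s, e in bursts):
                continue
            if any(abs(t - o) < 0.25 for o, lab in zip(onsets, labels)
                   if lab == "distractor"):
                continue
            _add_kernel(samples, d_kernel, t, fs, rng)
            onsets.append(float(t))
            labels.append("distractor")
            placed += 1

    if scenario.noise_floor_rms > 0:
        samples += rng.normal(0.0, scenario.noise_floor_rms, size=n)

    order = np.argsort(onsets, kind="stable")
    truth = GroundTruthEvents(
        impulse_onsets=[onsets[i] for i in order],
        impulse_labels=[labels[i] for i in order],
        burst_intervals=bursts,
    )
    return Waveform(np.clip(samples, -1.0, 1.0), fs), truth


def _add_kernel(samples: np.ndarray, kernel: np.ndarray, onset: float,
                fs: float, rng: np.random.Generator) -> None:
    """Add a kernel at `onset` seconds with mild amplitude jitter."""
    i0 = int(round(onset * fs))
    i1 = min(len(samples), i0 + len(kernel))
    samples[i0:i1] += kernel[: i1 - i0] * rng.uniform(0.7, 1.0)


# ---------------------------------------------------------------------------
# hermetic experiment tables


@dataclass(frozen=True)
class Treatment:
    """One insect-density treatment: jar size fixes the default air volume."""

    n_insects: int
    jar_ml: int
    air_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.n_insects <= 0:
            raise ValueError("n_insects must be positive")
        if self.air_volume_ml is None:
            if self.jar_ml not in AIR_VOLUME_ML:
                raise ValueError(
                    f"no default air volume for {self.jar_ml}-ml jars; "
                    "pass air_volume_ml explicitly"
                )
            object.__setattr__(self, "air_volume_ml", AIR_VOLUME_ML[self.jar_ml])

    @property
    def treatment_id(self) -> str:
        return f"{self.n_insects}x{self.jar_ml}ml"


#: The six study treatments: 25/50/100 adults in 500- and 1000-ml jars.
STUDY_TREATMENTS = tuple(
    Treatment(n, jar) for n in (25, 50, 100) for jar in (500, 1000)
)


def default_schedule() -> list[float]:
    """Observation days: twice daily through day 6, then twice weekly to 28."""
    twice_daily = [round(0.5 * i, 1) for i in range(13)]  # 0.0 .. 6.0
    twice_weekly = [9.5, 13.0, 16.5, 20.0, 23.5, 27.0]
    return twice_daily + twice_weekly


#: Default residual SDs of the activity noise on each model's response
#: scale, back-derived from the published slope standard errors.
DEFAULT_NOISE_SD = {"rb": 1.8e-3, "nb": 0.7, "rbimp": 11.5e-3}


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic hermetic-storage experiment.

    Residual O2 declines exponentially from 21% toward ``o2_floor_pct``
    with rate ``o2_decay_rate_per_insect * n_insects / air_volume_ml``
    per day, so denser treatments in smaller jars cross 5% and 2% earlier.
    Activity values are generated by inverting the activity-vs-depletion
    regressions at each timepoint and adding Gaussian noise on the
    transformed scale, flooring at zero after back-transform.
    """

    treatments: tuple[Treatment, ...] = STUDY_TREATMENTS
    replicates: int = 3
    schedule: tuple[float, ...] = field(default_factory=lambda: tuple(default_schedule()))
    o2_decay_rate_per_insect: float = 2.1
    o2_floor_pct: float = 0.2
    coefficients: dict[str, ActivityCoefficients] = field(
        default_factory=lambda: dict(REFERENCE_COEFFICIENTS)
    )
    noise_sd: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.o2_decay_rate_per_insect < 0:
            raise ValueError("o2 decay rate must be non-negative")
        if not 0 <= self.o2_floor_pct < AMBIENT_O2_PCT:
            raise ValueError("o2 floor must lie in [0, 21)")
        if self.replicates < 1:
            raise ValueError("at least one replicate")
        days = list(self.schedule)
        if not days or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("schedule days must be strictly increasing")
        sds = self.noise_values()
        if any(v < 0 for v in sds.values()):
            raise ValueError("noise SDs must be non-negative")

    def noise_values(self) -> dict[str, float]:
        if isinstance(self.noise_sd, dict):
            return {m: float(self.noise_sd.get(m, 0.0)) for m in MEASURES}
        return {m: float(self.noise_sd) for m in MEASURES}


def residual_o2_curve(days: np.ndarray, rate_per_day: float,
                      floor_pct: float = 0.2) -> np.ndarray:
    """Exponential O2 decline from ambient 21% toward a floor."""
    return floor_pct + (AMBIENT_O2_PCT - floor_pct) * np.exp(-rate_per_day * days)


def generate_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Generate the per-observation experiment table.

    Returns a tidy DataFrame with one row per (treatment, replicate,
    observation day) and columns ``treatment_id, n_insects, jar_ml,
    air_volume_ml, replicate, day, residual_o2_pct, rb, nb, rbimp``.
    ``nb``/``rbimp`` are missing on rows whose generated burst rate is zero
    (no bursts means no impulses per burst).
    """
    rng = np.random.default_rng(design.rng_seed)
    days = np.asarray(design.schedule, dtype=float)
    noise = design.noise_values()
    rows = []
    for treatment in design.treatments:
        rate = design.o2_decay_rate_per_insect * treatment.n_insects / treatment.air_volume_ml
        for rep in range(1, design.replicates + 1):
            o2 = residual_o2_curve(days, rate, design.o2_floor_pct)
            depletion = AMBIENT_O2_PCT - o2
            values: dict[str, np.ndarray] = {}
            for measure in MEASURES:
                coef = design.coefficients[measure]
                response = coef.intercept + coef.slope * depletion
                if noise[measure] > 0:
                    response = response + rng.normal(0.0, noise[measure], size=len(days))
                if measure == "nb":
                    values[measure] = np.maximum(response, 0.0)
                else:
                    raw = treatment.n_insects * (10.0 ** response - 1.0)
                    values[measure] = np.maximum(raw, 0.0)
            # coherence: a segment without bursts has no impulses-per-burst
            no_bursts = values["rb"] <= 0.0
            values["nb"] = np.where(no_bursts, np.nan, values["nb"])
            values["rbimp"] = np.where(no_bursts, 0.0, values["rbimp"])
            for i, day in enumerate(days):
                rows.append(
                    {
                        "treatment_id": treatment.treatment_id,
                        "n_insects": treatment.n_insects,
                        "jar_ml": treatment.jar_ml,
                        "air_volume_ml": treatment.air_volume_ml,
                        "replicate": rep,
                        "day": float(day),
                        "residual_o2_pct": float(o2[i]),
                        "rb": float(values["rb"][i]),
                        "nb": float(values["nb"][i]),
                        "rbimp": float(values["rbimp"][i]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grain-count fixtures for the count-and-weigh formula


def generate_grain_counts(true_loss_pct: float, n_grains: int, rng_seed: int = 0):
    """Construct counts/weights whose count-and-weigh loss equals the target.

    Per-grain undamaged weights are jittered around a nominal 45 mg wheat
    kernel; the damaged-portion weight is then solved in closed form so the
    weight-loss formula returns ``true_loss_pct`` exactly (well within 0.1
    percentage points).
    """
    from .hermetic import GrainCounts  # local import avoids a cycle

    if not 0.0 <= true_loss_pct < 100.0:
        raise ValueError("true_loss_pct must lie in [0, 100)")
    if n_grains < 10:
        raise ValueError("need at least 10 grains for a meaningful fixture")
    rng = np.random.default_rng(rng_seed)

    if true_loss_pct == 0.0:
        nd = 0
    else:
        # pick nd so each damaged grain lost ~30% of its weight
        nd = max(1, math.ceil(true_loss_pct * n_grains / 100.0 / 0.3))
        nd = min(nd, n_grains - 1)
    nu = n_grains - nd

    per_grain = np.maximum(rng.normal(0.045, 0.004, size=nu), 0.02)
    wu = float(per_grain.sum())
    if nd == 0:
        wd = 0.0
    else:
        wd = wu * (nd - true_loss_pct * n_grains / 100.0) / nu
    return GrainCounts(wu=wu, wd=wd, nu=nu, nd=nd)
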