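"""Synthetic generators: kernels, recordings, experiments, grain counts."""

import numpy as np
import pytest
from scipy import stats

from grainacoustics.coefficients import REFERENCE_COEFFICIENTS
from grainacoustics.hermetic import time_to_o2_level, weight_loss
from grainacoustics.simulate import (
    INSECT_KERNEL,
    AcousticScenario,
    ExperimentDesign,
    KernelSpec,
    Treatment,
    generate_experiment,
    generate_grain_counts,
    generate_recording,
    render_kernel,
)


class TestRenderKernel:
    def test_zero_amplitude_renders_silence(self):
        spec = KernelSpec(4000.0, 1000.0, 0.005, 500.0, 0.0)
        assert not np.any(render_kernel(spec))

    def test_sample_count_rounds_ties_to_even(self):
        # 0.005 s at 44100 Hz is 220.5 samples -> 220 under ties-to-even
        spec = KernelSpec(4000.0, 1000.0, 0.005, 500.0, 0.5)
        assert len(render_kernel(spec, 44100.0)) == 220

    def test_peak_equals_requested_amplitude(self):
        spec = KernelSpec(3000.0, 1000.0, 0.004, 700.0, 0.37)
        kernel = render_kernel(spec)
        assert np.max(np.abs(kernel)) == pytest.approx(0.37, rel=0.01)

    def test_dominant_energy_within_stated_band(self):
        spec = KernelSpec(4000.0, 1000.0, 0.005, 500.0, 0.5)
        kernel = render_kernel(spec, 44100.0)
        freqs = np.fft.rfftfreq(8192, 1 / 44100.0)
        power = np.abs(np.fft.rfft(kernel, 8192)) ** 2
        assert 3000.0 <= freqs[np.argmax(power)] <= 5000.0

    @pytest.mark.parametrize("duration", [0.0005, 0.011, 0.05])
    def test_duration_outside_1_to_10_ms_rejected(self, duration):
        with pytest.raises(ValueError, match="1-10 ms"):
            KernelSpec(4000.0, 1000.0, duration, 500.0, 0.5)


class TestGenerateRecording:
    def test_empty_scenario_is_silent(self):
        scenario = AcousticScenario(
            duration=2.0, burst_rate=0.0, distractor_rate=0.0,
            noise_floor_rms=0.0, rng_seed=0,
        )
        waveform, truth = generate_recording(scenario)
        assert not np.any(waveform.samples)
        assert truth.impulse_onsets == []
        assert truth.burst_intervals == []

    def test_burst_count_within_poisson_99_interval(self):
        scenario = AcousticScenario(duration=100.0, burst_rate=0.2, rng_seed=5)
        _, truth = generate_recording(scenario)
        lo = stats.poisson.ppf(0.005, 20.0)
        hi = stats.poisson.ppf(0.995, 20.0)
        assert lo <= len(truth.burst_intervals) <= hi

    def test_same_seed_bit_identical(self):
        scenario = AcousticScenario(duration=5.0, burst_rate=0.2, rng_seed=99)
        w1, t1 = generate_recording(scenario)
        w2, t2 = generate_recording(scenario)
        np.testing.assert_array_equal(w1.samples, w2.samples)
        assert t1.impulse_onsets == t2.impulse_onsets

    def test_burst_structure_satisfies_grouping_criterion(self, standard_scene):
        """Generated trains have >= 3 impulses, gaps < 200 ms inside bursts,
        and > 200 ms between consecutive bursts, by construction."""
        scenario, _, truth = standard_scene
        intervals = truth.burst_intervals
        for (s0, e0), (s1, _) in zip(intervals, intervals[1:]):
            assert s1 - e0 > 0.2
        for start, end in intervals:
            onsets = [t for t in truth.insect_onsets if start <= t <= end]
            assert len(onsets) >= 3
            gaps = np.diff(onsets)
            assert np.all(gaps < 0.2)

    def test_infeasible_burst_rate_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            AcousticScenario(duration=10.0, burst_rate=1.5, rng_seed=0)

    def test_kernels_must_be_spectrally_distinct(self):
        with pytest.raises(ValueError, match="similar"):
            AcousticScenario(
                duration=2.0, burst_rate=0.1,
                distractor_kernel=INSECT_KERNEL, rng_seed=0,
            )


class TestGenerateExperiment:
    def test_noise_free_day_zero_matches_generating_intercept(self):
        design = ExperimentDesign(noise_sd=0.0, rng_seed=0)
        table = generate_experiment(design)
        day0 = table[table.day == 0.0]
        assert (day0.residual_o2_pct == 21.0).all()
        transformed = np.log10(day0.rb / day0.n_insects + 1.0)
        expected = REFERENCE_COEFFICIENTS["rb"].intercept  # 2.26e-3
        np.testing.assert_allclose(transformed, expected, atol=1e-12)

    def test_zero_decay_rate_keeps_oxygen_flat(self):
        design = ExperimentDesign(o2_decay_rate_per_insect=0.0, rng_seed=0)
        table = generate_experiment(design)
        assert (table.residual_o2_pct == 21.0).all()

    def test_denser_treatment_crosses_2pct_first(self):
        design = ExperimentDesign(
            treatments=(Treatment(100, 500), Treatment(25, 1000)),
            replicates=1, rng_seed=3,
        )
        table = generate_experiment(design)
        crossings = {}
        for tid, group in table.groupby("treatment_id"):
            series = list(
                group.sort_values("day")[["day", "residual_o2_pct"]]
                .itertuples(index=False, name=None)
            )
            crossings[tid] = time_to_o2_level(series, 2.0)
        assert crossings["100x500ml"] < crossings["25x1000ml"]

    def test_noise_free_records_lie_on_generating_lines(self):
        """With zero noise and depletion kept below the activity zero-crossing,
        every record falls exactly on its generating regression line."""
        design = ExperimentDesign(
            treatments=(Treatment(25, 1000),),
            schedule=tuple(np.arange(0.5, 6.1, 0.5)),
            replicates=1, noise_sd=0.0, rng_seed=0,
        )
        table = generate_experiment(design)
        depletion = 21.0 - table.residual_o2_pct
        for measure in ("rb", "rbimp"):
            coef = REFERENCE_COEFFICIENTS[measure]
            observed = np.log10(table[measure] / table.n_insects + 1.0)
            np.testing.assert_allclose(
                observed, coef.intercept + coef.slope * depletion, atol=1e-12
            )
        coef = REFERENCE_COEFFICIENTS["nb"]
        np.testing.assert_allclose(
            table.nb, coef.intercept + coef.slope * depletion, atol=1e-12
        )

    def test_deterministic_under_seed(self):
        design = ExperimentDesign(rng_seed=42)
        t1 = generate_experiment(design)
        t2 = generate_experiment(design)
        assert t1.equals(t2)

    def test_negative_decay_rate_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(o2_decay_rate_per_insect=-1.0)


class TestGenerateGrainCounts:
    def test_zero_loss_means_no_damaged_grains(self):
        gc = generate_grain_counts(0.0, 100, rng_seed=0)
        assert gc.nd == 0 and gc.wd == 0.0
        assert weight_loss(gc) == 0.0

    def test_round_trip_through_weight_loss_formula(self):
        gc = generate_grain_counts(1.0, 250, rng_seed=7)
        assert 0.9 <= weight_loss(gc) <= 1.1

    @pytest.mark.parametrize("target", [0.5, 2.0, 10.0, 50.0])
    def test_formula_recovers_target_exactly(self, target):
        gc = generate_grain_counts(target, 500, rng_seed=1)
        assert weight_loss(gc) == pytest.approx(target, abs=0.1)

    def test_deterministic_under_seed(self):
        a = generate_grain_counts(3.0, 200, rng_seed=5)
        b = generate_grain_counts(3.0, 200, rng_seed=5)
        assert a == b

    def test_too_few_grains_rejected(self):
        with pytest.raises(ValueError):
            generate_grain_counts(1.0, 5, rng_seed=0)
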