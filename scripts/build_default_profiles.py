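"""Regenerate the two bundled synthetic spectral profiles.

Each profile is the averaged spectrum of verified insect impulses detected
in a synthetic recording: profile 1 averages 139 impulses drawn from a
62-s interval, profile 2 averages 33 impulses from a 20-s interval,
mirroring the sizes of the two field-recorded templates the matching
procedure conventionally uses. Run from the repository root:

    python scripts/build_default_profiles.py
"""

from __future__ import annotations

from pathlib import Path

from grainacoustics.detection import detect_impulses
from grainacoustics.profiles import build_profile, save_profile
from grainacoustics.simulate import AcousticScenario, generate_recording

OUT = Path(__file__).resolve().parents[1] / "src" / "grainacoustics" / "data" / "profiles"


def verified_insect_spectra(seed: int, n_wanted: int, interval_s: float,
                            burst_rate: float):
    """Detect impulses in a dense synthetic scene and keep verified insect ones."""
    scenario = AcousticScenario(
        duration=600.0, burst_rate=burst_rate, distractor_rate=0.05, rng_seed=seed
    )
    waveform, truth = generate_recording(scenario)
    impulses = detect_impulses(waveform)
    insect = set()
    spectra = []
    t0 = None
    for imp in impulses:
        # verified = within 2 ms of a ground-truth insect onset
        if any(abs(imp.onset - o) <= 0.002 for o in truth.insect_onsets):
            if t0 is None:
                t0 = imp.onset
            if imp.onset - t0 > interval_s:
                break
            spectra.append(imp.spectrum)
            if len(spectra) >= n_wanted:
                break
    return spectra


def main() -> None:
    for label, seed, n, interval, rate in (
        ("synthetic_profile_1", 20, 139, 62.0, 0.65),
        ("synthetic_profile_2", 21, 33, 20.0, 0.45),
    ):
        spectra = verified_insect_spectra(seed, n, interval, rate)
        profile = build_profile(spectra, label, source_duration=interval)
        path = save_profile(profile, OUT)
        print(f"{label}: {profile.n_impulses} impulses over {interval:.0f} s -> {path}")


if __name__ == "__main__":
    main()
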