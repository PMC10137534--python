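"""Synthetic EEG cohort generator with controllable GCS-dependent structure.

The signal model is deliberately simple and exactly controllable: each
channel is a sum of band-limited Gaussian noise processes (one per
sub-band, FIR-shaped white noise rescaled to its target energy, with a
spectral emphasis at a configurable peak frequency) plus a broadband noise
floor.  Consciousness-level structure enters through per-level band-power
profiles: the deepest coma level (GCS 3) has the smallest power target in
every channel and band, frontal beta power is maximal at GCS 8, and for
GCS >= 6 the interaction stages (nurse, family) carry a configurable gain
and a small upward peak-frequency shift of the alpha/beta content,
emulating the reactivity of lighter coma.  Long rest stages are
occasionally truncated (keeping their leading portion), which is what makes
some patients yield fewer than nine analysis segments downstream.

No attempt is made at physiological EEG morphology (spindles, artifacts,
age effects); the generator emulates the *statistical* structure the
analysis pipeline consumes, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .bands import BandDefinition, CANONICAL_BANDS, CHANNEL_LABELS, band_by_name
from .recording import Recording, StageSchedule, DEFAULT_SCHEDULE

#: Baseline band power (uV^2 per sample, i.e. mean square) before level scaling.
_BASE_BAND_POWER = {"delta": 20.0, "theta": 4.0, "alpha": 1.5, "beta": 0.6}

#: Per-level channel multipliers (F, C, T, P), emulating the qualitative
#: lobe activity pattern of the study population: GCS 3 globally minimal,
#: GCS 4 parietal/temporal, GCS 5 central/temporal, GCS 6-7 temporal,
#: GCS 8 moderate overall with a strong frontal-beta boost.
_LEVEL_CHANNEL_SCALE: dict[int, dict[str, float]] = {
    3: {"F3-F4": 0.25, "C3-C4": 0.25, "T3-T4": 0.25, "P3-P4": 0.25},
    4: {"F3-F4": 1.00, "C3-C4": 1.10, "T3-T4": 1.60, "P3-P4": 1.80},
    5: {"F3-F4": 0.90, "C3-C4": 1.70, "T3-T4": 1.30, "P3-P4": 1.00},
    6: {"F3-F4": 1.10, "C3-C4": 1.20, "T3-T4": 1.90, "P3-P4": 0.90},
    7: {"F3-F4": 1.00, "C3-C4": 1.45, "T3-T4": 1.70, "P3-P4": 1.30},
    8: {"F3-F4": 0.70, "C3-C4": 0.60, "T3-T4": 0.65, "P3-P4": 0.75},
}

#: GCS 8 beta-band boost on anterior channels (frontal beta activation).
_GCS8_BETA_BOOST = {"F3-F4": 3.0 / 0.70, "C3-C4": 2.0 / 0.60}

#: Nominal in-band spectral peak per level (Hz); rises with consciousness.
_LEVEL_PEAK_FREQ: dict[int, dict[str, float]] = {
    3: {"delta": 1.0, "theta": 4.8, "alpha": 8.6, "beta": 15.0},
    4: {"delta": 1.3, "theta": 5.2, "alpha": 9.0, "beta": 16.0},
    5: {"delta": 1.6, "theta": 5.6, "alpha": 9.5, "beta": 17.0},
    6: {"delta": 1.9, "theta": 6.0, "alpha": 10.0, "beta": 18.0},
    7: {"delta": 2.2, "theta": 6.4, "alpha": 10.6, "beta": 19.0},
    8: {"delta": 2.6, "theta": 7.0, "alpha": 11.5, "beta": 21.0},
}

#: Interaction-stage gain on alpha+beta content per level.
_LEVEL_STAGE_GAIN = {3: 1.0, 4: 1.0, 5: 1.0, 6: 1.15, 7: 1.25, 8: 1.35}

#: Study population: number of patients per GCS level.
DEFAULT_PATIENTS_PER_LEVEL = {3: 8, 4: 4, 5: 9, 6: 9, 7: 7, 8: 2}


@dataclass(frozen=True)
class GcsBandProfile:
    """Spectral profile of one consciousness level.

    band_energy_targets maps (channel, band) to the target per-sample mean
    square power (uV^2); a window of n samples therefore has expected
    Parseval energy ``target * n``.  stage_gain multiplies the alpha+beta
    power during the named (interaction) stages; interaction_peak_shift_hz
    shifts the alpha/beta spectral peak upward during those stages.
    """

    gcs_level: int
    band_energy_targets: dict[tuple[str, str], float]
    stage_gain: dict[str, float] = field(default_factory=dict)
    peak_freq: dict[str, float] = field(default_factory=dict)
    interaction_peak_shift_hz: float = 0.0

    def __post_init__(self) -> None:
        if not 3 <= self.gcs_level <= 8:
            raise ValueError(f"gcs_level must be in [3, 8], got {self.gcs_level}")
        for key, v in self.band_energy_targets.items():
            if v <= 0:
                raise ValueError(f"energy target for {key} must be > 0")
        for g in self.stage_gain.values():
            if g < 0:
                raise ValueError("stage gains must be >= 0")
        for name, f in self.peak_freq.items():
            band = band_by_name(name)
            if not band.contains(f):
                raise ValueError(
                    f"peak_freq {f} Hz outside band {name!r} [{band.f_lo}, {band.f_hi}]"
                )

    def target(self, channel: str, band: str) -> float:
        return self.band_energy_targets[(channel, band)]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generation settings.

    truncation_rate is the probability that a long (split) rest stage is
    shortened to ``truncated_length`` minutes, keeping its leading portion.
    patient_sigma is the standard deviation of the per-patient log-normal
    jitter applied to every band-power target (0 disables inter-patient
    variability, which is what a null-calibration cohort needs).
    noise_floor is broadband (0.5-30 Hz) noise power, uV^2 per sample.
    """

    patients_per_level: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_PATIENTS_PER_LEVEL)
    )
    fs: float = 500.0
    schedule: StageSchedule = DEFAULT_SCHEDULE
    truncation_rate: float = 0.04
    truncated_length: float = 8.0
    master_seed: int = 0
    noise_floor: float = 0.2
    patient_sigma: float = 0.15

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.patients_per_level.values()):
            raise ValueError("patient counts must be >= 0")
        if not 0 <= self.truncation_rate <= 1:
            raise ValueError("truncation_rate must be in [0, 1]")
        highest_edge = max(b.f_hi for b in CANONICAL_BANDS)
        if self.fs <= 2 * highest_edge:
            raise ValueError(f"fs={self.fs} must exceed twice the highest band edge")
        if self.noise_floor < 0 or self.patient_sigma < 0:
            raise ValueError("noise_floor and patient_sigma must be >= 0")


def default_profiles() -> dict[int, GcsBandProfile]:
    """Well-separated per-level profiles emulating the study's ordering.

    GCS 3 holds the strict minimum power target for every (channel, band);
    frontal beta power is maximal at GCS 8; interaction gain and peak shift
    are active for GCS >= 6 only.
    """
    profiles: dict[int, GcsBandProfile] = {}
    for level in range(3, 9):
        targets: dict[tuple[str, str], float] = {}
        for ch in CHANNEL_LABELS:
            for band in CANONICAL_BANDS:
                scale = _LEVEL_CHANNEL_SCALE[level][ch]
                if level == 8 and band.name == "beta" and ch in _GCS8_BETA_BOOST:
                    scale *= _GCS8_BETA_BOOST[ch]
                targets[(ch, band.name)] = _BASE_BAND_POWER[band.name] * scale
        gain = _LEVEL_STAGE_GAIN[level]
        profiles[level] = GcsBandProfile(
            gcs_level=level,
            band_energy_targets=targets,
            stage_gain={"nurse": gain, "family": gain},
            peak_freq=dict(_LEVEL_PEAK_FREQ[level]),
            interaction_peak_shift_hz=0.5 if level >= 6 else 0.0,
        )
    return profiles


def null_profiles() -> dict[int, GcsBandProfile]:
    """Identical profiles for every level (for type-I error calibration)."""
    base = default_profiles()[5]
    return {
        level: GcsBandProfile(
            gcs_level=level,
            band_energy_targets=dict(base.band_energy_targets),
            stage_gain={},
            peak_freq=dict(base.peak_freq),
            interaction_peak_shift_hz=0.0,
        )
        for level in range(3, 9)
    }


@lru_cache(maxsize=256)
def _shaping_taps(
    band: BandDefinition, fs: float, peak_freq: float | None, numtaps: int | None = None
) -> np.ndarray:
    """FIR taps confining white noise to a band, optionally peaked in-band.

    The default length scales with fs to keep the transition skirts
    narrow (~1.6 Hz), so >=95% of the shaped power stays in band.
    """
    if numtaps is None:
        numtaps = max(int(round(1001 * fs / 500.0)) | 1, 255)
    ny = fs / 2.0
    if peak_freq is None:
        return _signal.firwin(numtaps, [band.f_lo, band.f_hi], fs=fs, pass_zero=False)
    if not band.contains(peak_freq):
        raise ValueError(f"peak_freq {peak_freq} outside band {band.name!r}")
    eps = 1e-6
    freqs = [0.0, band.f_lo - eps, band.f_lo, band.f_hi, band.f_hi + eps, ny]
    gains = [0.0, 0.0, 0.35, 0.35, 0.0, 0.0]
    # insert the peak emphasis strictly inside the band
    if band.f_lo < peak_freq < band.f_hi:
        freqs.insert(3, peak_freq)
        gains.insert(3, 1.0)
    else:  # peak at an edge: raise that edge's gain instead
        gains[2 if peak_freq == band.f_lo else 3] = 1.0
    return _signal.firwin2(numtaps, np.array(freqs) / ny, gains)


def generate_band_limited_noise(
    band: BandDefinition,
    duration: float,
    fs: float,
    target_energy: float,
    seed,
    peak_freq: float | None = None,
) -> np.ndarray:
    """Gaussian noise confined to ``band`` with exact total energy.

    Returns duration*fs samples whose sum of squares equals target_energy
    (by final rescaling).  ``seed`` may be an int, SeedSequence or
    Generator; identical arguments give identical output.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if target_energy < 0:
        raise ValueError("target_energy must be >= 0")
    band.validate_for_fs(fs)
    n = int(round(duration * fs))
    if target_energy == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    h = _shaping_taps(band, fs, peak_freq)
    shaped = _signal.oaconvolve(white, h, mode="same")
    energy = float(np.sum(shaped**2))
    if energy == 0:  # pragma: no cover - degenerate numeric corner
        return np.zeros(n)
    return shaped * np.sqrt(target_energy / energy)


_FLOOR_BAND = BandDefinition("broadband", 0.5, 30.0)


def generate_patient_recording(
    profile: GcsBandProfile, config: SyntheticCohortConfig, seed
) -> Recording:
    """One patient's staged multichannel recording.

    Stage by stage, each channel is the sum of the four shaped band
    processes (targets from the profile, jittered once per patient when
    patient_sigma > 0, interaction stages applying the alpha/beta gain and
    peak shift) plus the broadband floor.  Split rest stages are truncated
    with probability truncation_rate, keeping their leading portion.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    # per-patient multiplicative jitter, one factor per (channel, band)
    jitter: dict[tuple[str, str], float] = {}
    for ch in CHANNEL_LABELS:
        for band in CANONICAL_BANDS:
            jitter[(ch, band.name)] = (
                float(np.exp(rng.normal(0.0, config.patient_sigma)))
                if config.patient_sigma > 0
                else 1.0
            )

    # stage durations (minutes), with possible rest truncation
    durations: list[float] = []
    for stage in config.schedule.stages:
        if stage.split and rng.random() < config.truncation_rate:
            durations.append(min(config.truncated_length, stage.minutes))
        else:
            durations.append(stage.minutes)

    stage_chunks: list[np.ndarray] = []
    annotations: list[tuple[str, float, float]] = []
    t = 0.0
    for stage, minutes in zip(config.schedule.stages, durations):
        dur_s = minutes * 60.0
        n = int(round(dur_s * config.fs))
        chunk = np.zeros((len(CHANNEL_LABELS), n))
        interacting = stage.kind == "interaction"
        gain = profile.stage_gain.get(stage.name, 1.0) if interacting else 1.0
        shift = profile.interaction_peak_shift_hz if interacting else 0.0
        for ci, ch in enumerate(CHANNEL_LABELS):
            for band in CANONICAL_BANDS:
                power = profile.target(ch, band.name) * jitter[(ch, band.name)]
                peak = profile.peak_freq.get(band.name)
                if band.name in ("alpha", "beta"):
                    power *= gain
                    if peak is not None and shift:
                        peak = min(peak + shift, band.f_hi)
                chunk[ci] += generate_band_limited_noise(
                    band, dur_s, config.fs, power * n, rng, peak_freq=peak
                )
            if config.noise_floor > 0:
                chunk[ci] += generate_band_limited_noise(
                    _FLOOR_BAND, dur_s, config.fs, config.noise_floor * n, rng
                )
        stage_chunks.append(chunk)
        annotations.append((stage.name, t, dur_s))
        t += dur_s

    return Recording(
        channels=np.concatenate(stage_chunks, axis=1),
        fs=config.fs,
        stage_annotations=annotations,
        gcs=profile.gcs_level,
    )


def cohort_manifest(config: SyntheticCohortConfig) -> pd.DataFrame:
    """The patient_id -> GCS manifest implied by a cohort configuration."""
    rows = [
        {"patient_id": f"P{level}{k + 1:02d}", "gcs": level}
        for level in sorted(config.patients_per_level)
        for k in range(config.patients_per_level[level])
    ]
    return pd.DataFrame(rows, columns=["patient_id", "gcs"])


def iter_cohort(
    config: SyntheticCohortConfig,
    profiles: dict[int, GcsBandProfile] | None = None,
):
    """Yield the cohort's recordings one at a time (memory-friendly).

    One recording per patient, levels in ascending order; per-patient seeds
    are spawned from the master seed by patient position
    (``SeedSequence(master_seed, spawn_key=(index,))``), so the cohort is a
    pure function of (config, profiles).
    """
    if profiles is None:
        profiles = default_profiles()
    for level, count in sorted(config.patients_per_level.items()):
        if count > 0 and level not in profiles:
            raise ValueError(f"no profile supplied for requested GCS level {level}")
    index = 0
    for level in sorted(config.patients_per_level):
        for k in range(config.patients_per_level[level]):
            child = np.random.SeedSequence(config.master_seed, spawn_key=(index,))
            rec = generate_patient_recording(profiles[level], config, child)
            rec.patient_id = f"P{level}{k + 1:02d}"
            yield rec
            index += 1


def generate_cohort(
    config: SyntheticCohortConfig,
    profiles: dict[int, GcsBandProfile] | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """A full in-memory cohort plus its label manifest.

    Convenience wrapper around :func:`iter_cohort`; for large cohorts
    prefer streaming the iterator into feature extraction instead of
    materializing every recording at once.
    """
    recordings = list(iter_cohort(config, profiles))
    return recordings, cohort_manifest(config)
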