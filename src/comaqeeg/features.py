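"""Welch PSD estimation and the 10-feature band descriptor set.

For every (channel, band) pair of a segment, ten descriptors are computed:

======== ==============================================================
Energy   Parseval energy of the band-filtered time series,
         Ex = (1/N) sum_k |S(k)|^2 = sum_n s(n)^2  (uV^2 * sample)
Maxf     frequency of the PSD peak within the band (Hz)
Maxp     the peak PSD value (uV^2/Hz)
AUC1     trapezoidal area under the band PSD from the band's lower edge
         up to the peak (A1, uV^2)
AUC2     area from the peak to the band's upper edge (A2, uV^2)
Rate1    A1 / (A1 + A2)
Rate2    A1 / A2           (NaN when A2 = 0)
Rate3    A2 / (A1 + A2)
NPower   (1/fs) * sum_f P_f^2
TPower   sum_f P_f^2  =  fs * NPower
======== ==============================================================

Four channels x four bands x ten features give the 160-dimensional
instance vector, ordered channel-major (F3-F4, C3-C4, T3-T4, P3-P4), bands
in ascending frequency (delta, theta, alpha, beta), features in the table
order above.  The ordering is frozen for file compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandDefinition, CANONICAL_BANDS, CHANNEL_LABELS
from .preprocess import bandpass_samples
from .segmentation import Segment

FEATURE_NAMES: tuple[str, ...] = (
    "Energy", "Maxf", "Maxp", "AUC1", "AUC2",
    "Rate1", "Rate2", "Rate3", "NPower", "TPower",
)

#: Metadata columns accompanying the 160 feature columns in tabular output.
METADATA_COLUMNS: tuple[str, ...] = ("patient_id", "gcs", "stage_name", "window_label")


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings.

    The estimator averages modified (windowed) periodograms over 50 %
    overlapping frames.  Defaults: 256-sample Hamming frames zero-padded to
    1024 FFT points, giving a grid fine enough (~0.49 Hz at fs=500) to
    represent the 0.5 Hz delta edge.
    """

    window_length: int = 256
    overlap_fraction: float = 0.5
    window_shape: str = "hamming"
    n_fft: int = 1024

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.n_fft < self.window_length:
            raise ValueError("n_fft must be >= window_length")


@dataclass
class PsdEstimate:
    """A one-sided PSD: frequency grid (Hz) and power density (uV^2/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if len(self.frequencies) and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def welch_psd(samples: np.ndarray, fs: float, config: WelchConfig = WelchConfig()) -> PsdEstimate:
    """Welch PSD of a sample sequence: averaged modified periodograms.

    The signal is cut into overlapping frames of ``window_length`` samples
    advancing by ``window_length * (1 - overlap_fraction)``; each frame is
    tapered, its (zero-padded) periodogram taken, and the periodograms
    averaged.  One-sided, density-scaled (uV^2/Hz), window-power
    normalized (divided by fs * sum(w^2)) so the integral of the PSD over
    frequency estimates the signal variance for white noise; equivalent to
    ``scipy.signal.welch`` with the same settings.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = config.window_length
    if samples.size < n:
        raise ValueError(
            f"signal of {samples.size} samples shorter than one window ({n} samples)"
        )
    window = signal.get_window(config.window_shape, n, fftbins=True)
    step = n - int(n * config.overlap_fraction)
    frames = np.lib.stride_tricks.sliding_window_view(samples, n)[::step]
    spectra = np.fft.rfft(frames * window, n=config.n_fft, axis=1)
    power = (spectra.real**2 + spectra.imag**2).mean(axis=0)
    power /= fs * float(np.sum(window**2))
    power[1:] *= 2.0  # one-sided: double all but DC ...
    if config.n_fft % 2 == 0:
        power[-1] /= 2.0  # ... and the Nyquist bin
    freqs = np.fft.rfftfreq(config.n_fft, d=1.0 / fs)
    return PsdEstimate(freqs, power)


def parseval_energy(band_samples: np.ndarray) -> float:
    """Signal energy from the frequency domain: (1/N) sum_k |S(k)|^2.

    Equals the time-domain sum of squares by Parseval's theorem; computed
    from the DFT of the (band-filtered) segment, using the real-input
    half-spectrum with conjugate-symmetry weights.
    """
    x = np.asarray(band_samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("parseval_energy: empty input")
    n = x.size
    spectrum = np.fft.rfft(x)
    mags = spectrum.real**2 + spectrum.imag**2
    total = 2.0 * float(mags.sum()) - float(mags[0])
    if n % 2 == 0:
        total -= float(mags[-1])
    return total / n


def band_slice(psd: PsdEstimate, band: BandDefinition) -> PsdEstimate:
    """Restrict a PSD to the bins with f_lo <= f <= f_hi (inclusive ends)."""
    mask = (psd.frequencies >= band.f_lo) & (psd.frequencies <= band.f_hi)
    if not np.any(mask):
        raise ValueError(f"no PSD bins fall inside band {band.name!r}")
    return PsdEstimate(psd.frequencies[mask], psd.power[mask])


def peak_features(band_psd: PsdEstimate) -> tuple[float, float]:
    """(Maxf, Maxp): the peak PSD value and its frequency.

    Ties are broken toward the lowest frequency (np.argmax returns the
    first maximum on an increasing grid).
    """
    if len(band_psd.power) == 0:
        raise ValueError("peak_features: empty PSD")
    i = int(np.argmax(band_psd.power))
    return float(band_psd.frequencies[i]), float(band_psd.power[i])


def area_features(
    band_psd: PsdEstimate, maxf: float
) -> tuple[float, float, float, float, float]:
    """(A1, A2, Rate1, Rate2, Rate3) from the band PSD, split at the peak.

    Trapezoidal areas from the band's lower edge up to the peak frequency
    (A1) and from the peak to the upper edge (A2); the peak bin is shared,
    so A1 + A2 equals the total band area exactly.  Rate2 = A1/A2 is stored
    as NaN when A2 = 0; Rate1 and Rate3 fall back to the degenerate split
    (0, 1) when the total area is zero.
    """
    idx = np.flatnonzero(np.isclose(band_psd.frequencies, maxf))
    if idx.size == 0:
        raise ValueError(f"Maxf={maxf} is not a grid frequency of the band PSD")
    i = int(idx[0])
    f, p = band_psd.frequencies, band_psd.power
    a1 = float(np.trapezoid(p[: i + 1], f[: i + 1])) if i > 0 else 0.0
    a2 = float(np.trapezoid(p[i:], f[i:])) if i < len(f) - 1 else 0.0
    total = a1 + a2
    if total > 0:
        rate1, rate3 = a1 / total, a2 / total
    else:
        rate1, rate3 = 0.0, 1.0
    rate2 = a1 / a2 if a2 > 0 else float("nan")
    return a1, a2, rate1, rate2, rate3


def power_features(band_psd: PsdEstimate, fs: float) -> tuple[float, float]:
    """(NPower, TPower): sum of squared PSD values, with and without 1/fs."""
    tpower = float(np.sum(band_psd.power**2))
    return tpower / fs, tpower


@dataclass
class BandFeatureSet:
    """The ten descriptors of one (channel, band) pair."""

    Energy: float
    Maxf: float
    Maxp: float
    AUC1: float
    AUC2: float
    Rate1: float
    Rate2: float
    Rate3: float
    NPower: float
    TPower: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


@dataclass
class FeatureVector:
    """A 160-dimensional instance plus its provenance metadata."""

    values: np.ndarray
    patient_id: str
    gcs: int | None
    stage_name: str
    window_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(feature_column_names()),):
            raise ValueError(f"feature vector must have length {len(feature_column_names())}")


def feature_column_names(
    channels: tuple[str, ...] = CHANNEL_LABELS,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
) -> list[str]:
    """Frozen column order: channel-major x band x feature."""
    return [f"{ch}|{b.name}|{feat}" for ch in channels for b in bands for feat in FEATURE_NAMES]


def band_features(
    band_samples: np.ndarray, band: BandDefinition, fs: float, config: WelchConfig
) -> BandFeatureSet:
    """Ten descriptors of one band-filtered channel segment."""
    energy = parseval_energy(band_samples)
    psd = band_slice(welch_psd(band_samples, fs, config), band)
    maxf, maxp = peak_features(psd)
    a1, a2, r1, r2, r3 = area_features(psd, maxf)
    npow, tpow = power_features(psd, fs)
    return BandFeatureSet(energy, maxf, maxp, a1, a2, r1, r2, r3, npow, tpow)


def extract_feature_vector(
    segment: Segment,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    welch_config: WelchConfig = WelchConfig(),
) -> FeatureVector:
    """The 160-feature instance vector of one analysis segment.

    Energy comes from the band-filtered time series (Parseval); the other
    nine descriptors come from the band-sliced Welch PSD of that series.
    """
    if segment.n_channels != len(CHANNEL_LABELS):
        raise ValueError(
            f"segment has {segment.n_channels} channels, expected {len(CHANNEL_LABELS)}"
        )
    values: list[float] = []
    for ch in range(segment.n_channels):
        for band in bands:
            filtered = bandpass_samples(segment.samples[ch], band, segment.fs)
            values.extend(band_features(filtered, band, segment.fs, welch_config).as_tuple())
    return FeatureVector(
        values=np.asarray(values),
        patient_id=segment.patient_id,
        gcs=segment.gcs,
        stage_name=segment.stage_name,
        window_label=segment.window_label,
    )


def extract_recording_features(
    recording,
    schedule,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    welch_config: WelchConfig = WelchConfig(),
) -> list[FeatureVector]:
    """All instance vectors of one (already denoised) recording.

    Equivalent to segmenting and calling :func:`extract_feature_vector`
    per segment, but band-decomposes the whole recording once and slices
    the band-limited channels per segment, which avoids re-filtering the
    overlapping T10 windows (differences versus the per-segment path are
    confined to filter edge effects at segment boundaries).
    """
    from .preprocess import decompose_bands
    from .segmentation import build_segments

    band_recordings = decompose_bands(recording, bands)
    segments_per_band = {
        name: build_segments(rec, schedule) for name, rec in band_recordings.items()
    }
    reference = build_segments(recording, schedule)
    vectors = []
    for si, seg in enumerate(reference):
        values: list[float] = []
        for ch in range(seg.n_channels):
            for band in bands:
                band_seg = segments_per_band[band.name][si]
                values.extend(
                    band_features(band_seg.samples[ch], band, seg.fs, welch_config).as_tuple()
                )
        vectors.append(
            FeatureVector(
                values=np.asarray(values),
                patient_id=seg.patient_id,
                gcs=seg.gcs,
                stage_name=seg.stage_name,
                window_label=seg.window_label,
            )
        )
    return vectors


def vectors_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack instance vectors into a table: metadata columns + 160 features."""
    cols = feature_column_names()
    records = []
    for v in vectors:
        row = {
            "patient_id": v.patient_id,
            "gcs": v.gcs,
            "stage_name": v.stage_name,
            "window_label": v.window_label,
        }
        row.update(dict(zip(cols, v.values)))
        records.append(row)
    return pd.DataFrame.from_records(records, columns=list(METADATA_COLUMNS) + cols)
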