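"""Canonical EEG sub-band definitions and the four-channel bipolar montage."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.f_hi > fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz exceeds Nyquist {fs / 2} Hz"
            )

    def contains(self, f: float) -> bool:
        return self.f_lo <= f <= self.f_hi


#: The four sub-bands used throughout, in ascending frequency order.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

#: Bipolar montage channel order: frontal, central, temporal, parietal.
CHANNEL_LABELS: tuple[str, ...] = ("F3-F4", "C3-C4", "T3-T4", "P3-P4")


def band_by_name(name: str) -> BandDefinition:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")
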