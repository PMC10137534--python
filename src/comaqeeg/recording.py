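"""Annotated multichannel EEG recordings and the staged recording protocol.

The acquisition protocol alternates rest and interaction stages at the
bedside: 5 min rest, 5 min nurse interaction (auditory + tactile stimuli),
10 min rest, 5 min family interaction, 10 min rest — 35 min in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import CHANNEL_LABELS


@dataclass(frozen=True)
class Stage:
    """One protocol stage: a name, a nominal duration, and its kind.

    ``split`` marks the long rest stages that are expanded into
    first-half / second-half / total analysis windows downstream.
    """

    name: str
    minutes: float
    kind: str = "rest"  # "rest" or "interaction"
    split: bool = False

    @property
    def seconds(self) -> float:
        return self.minutes * 60.0


@dataclass(frozen=True)
class StageSchedule:
    """Ordered stage list defining the recording protocol."""

    stages: tuple[Stage, ...]

    @property
    def total_minutes(self) -> float:
        return sum(s.minutes for s in self.stages)

    def stage(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(f"schedule has no stage named {name!r}")

    @property
    def stage_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.stages)


#: The 35-minute five-stage protocol.
DEFAULT_SCHEDULE = StageSchedule(
    stages=(
        Stage("first_rest", 5, "rest"),
        Stage("nurse", 5, "interaction"),
        Stage("second_rest", 10, "rest", split=True),
        Stage("family", 5, "interaction"),
        Stage("last_rest", 10, "rest", split=True),
    )
)


@dataclass
class Recording:
    """A multichannel EEG recording with stage annotations.

    channels
        Array of shape (n_channels, n_samples), microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered channel names; default the four bipolar derivations.
    stage_annotations
        Ordered, non-overlapping (stage_name, start_s, duration_s) triples
        within the record.
    patient_id
        Opaque identifier.
    gcs
        Glasgow Coma Scale level 3-8, or None when unknown.
    """

    channels: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNEL_LABELS
    stage_annotations: list[tuple[str, float, float]] = field(default_factory=list)
    patient_id: str = ""
    gcs: int | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a 2-D (n_channels, n_samples) array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.channels.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.channels.shape[0]} channels"
            )
        self._validate_annotations()

    def _validate_annotations(self) -> None:
        t_prev_end = 0.0
        for name, start, dur in self.stage_annotations:
            if dur <= 0:
                raise ValueError(f"annotation {name!r} has non-positive duration")
            if start < t_prev_end - 1e-9:
                raise ValueError(f"annotation {name!r} overlaps its predecessor")
            if start + dur > self.duration_s + 1e-9:
                raise ValueError(f"annotation {name!r} extends past end of record")
            t_prev_end = start + dur

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_channels(self, channels: np.ndarray) -> "Recording":
        """Copy of this recording with the sample data replaced."""
        return replace(self, channels=np.asarray(channels, dtype=np.float64))

    def slice_seconds(self, start_s: float, duration_s: float) -> np.ndarray:
        """Samples of all channels in the half-open window [start, start+dur)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round((start_s + duration_s) * self.fs))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError("requested window lies outside the record")
        return self.channels[:, i0:i1]
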