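"""Expansion of a staged recording into up to nine analysis segments.

Each interaction stage and the first rest contribute one full-stage window.
Each long (10-min) rest contributes three windows: its first five minutes
(F5), its second five minutes (S5), and the total ten minutes (T10), so a
complete recording yields 3 + 2x3 = 9 segments.  Windows shorter than their
nominal length are dropped, never padded: a truncated rest keeps its F5
window only (S5 and T10 both require the full nominal duration), which is
why truncated recordings yield fewer than nine instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recording import Recording, StageSchedule, DEFAULT_SCHEDULE

logger = logging.getLogger(__name__)

#: Window labels: full stage, first half, second half, total of a split rest.
WINDOW_FULL = "FULL"
WINDOW_F5 = "F5"
WINDOW_S5 = "S5"
WINDOW_T10 = "T10"


@dataclass
class Segment:
    """One analysis window cut from a patient's recording."""

    patient_id: str
    gcs: int | None
    stage_name: str
    window_label: str
    samples: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


def build_segments(
    recording: Recording, schedule: StageSchedule = DEFAULT_SCHEDULE
) -> list[Segment]:
    """Cut a recording into its protocol analysis segments.

    Returns the segments in protocol order.  Raises on annotation names not
    present in the schedule; a recording without annotations yields an empty
    list and a warning.
    """
    if not recording.stage_annotations:
        logger.warning(
            "recording %r has no stage annotations; no segments emitted", recording.patient_id
        )
        return []

    known = set(schedule.stage_names)
    segments: list[Segment] = []
    annotated = {name for name, _, _ in recording.stage_annotations}
    for name, start, dur in recording.stage_annotations:
        if name not in known:
            raise ValueError(f"annotation stage {name!r} not in schedule {sorted(known)}")
        stage = schedule.stage(name)
        nominal = stage.seconds
        if not stage.split:
            if dur + 1e-9 < nominal:
                logger.warning(
                    "patient %r stage %r lasts %.1f s < nominal %.1f s; dropped",
                    recording.patient_id, name, dur, nominal,
                )
                continue
            segments.append(_cut(recording, name, WINDOW_FULL, start, nominal))
        else:
            half = nominal / 2.0
            if dur + 1e-9 >= half:
                segments.append(_cut(recording, name, WINDOW_F5, start, half))
            else:
                logger.warning(
                    "patient %r stage %r lasts %.1f s < half nominal; all windows dropped",
                    recording.patient_id, name, dur,
                )
            if dur + 1e-9 >= nominal:
                segments.append(_cut(recording, name, WINDOW_S5, start + half, half))
                segments.append(_cut(recording, name, WINDOW_T10, start, nominal))
            else:
                logger.warning(
                    "patient %r stage %r truncated (%.1f of %.1f s); S5/T10 dropped",
                    recording.patient_id, name, dur, nominal,
                )
    missing = known - annotated
    if missing:
        logger.warning(
            "patient %r is missing stage annotations %s", recording.patient_id, sorted(missing)
        )
    return segments


def _cut(rec: Recording, stage: str, label: str, start_s: float, dur_s: float) -> Segment:
    return Segment(
        patient_id=rec.patient_id,
        gcs=rec.gcs,
        stage_name=stage,
        window_label=label,
        samples=rec.slice_seconds(start_s, dur_s),
        fs=rec.fs,
    )
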