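"""EDF+ reading and writing for staged EEG recordings.

Writing is implemented directly against the EDF+ specification (16-bit
samples, one-second data records, stage annotations as EDF+ time-stamped
annotation lists); reading goes through :mod:`mne`, which gives the
round-trip test two independent codecs.  Physical values are microvolts;
quantization error is bounded by one digital step of the stored physical
range.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np

from .bands import CHANNEL_LABELS
from .recording import Recording

logger = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fmt(value: float, width: int) -> bytes:
    """ASCII-format a number into a fixed-width EDF header field."""
    for prec in range(6, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b.ljust(width)


def write_recording(recording: Recording, path) -> Path:
    """Write a recording as an EDF+C file with one-second data records.

    Requires an integer sampling rate and a whole number of seconds of
    data (both hold for the staged protocol at 500 Hz).
    """
    path = Path(path)
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records = recording.n_samples / fs
    if n_records != int(n_records):
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = int(n_records)
    if n_records == 0:
        raise ValueError("cannot write an empty recording")

    # digitize each channel over its own physical range
    phys_min, phys_max, digital = [], [], []
    for ch in recording.channels:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        gain = (hi - lo) / (_DIG_MAX - _DIG_MIN)
        d = np.round((ch - lo) / gain + _DIG_MIN).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(d)

    # annotation payload: record 0 carries the stage annotations
    tals = [b"+0\x14\x14\x00"]
    for name, start, dur in recording.stage_annotations:
        tals.append(f"+{start:g}\x15{dur:g}\x14{name}\x14\x00".encode("ascii"))
    record0 = b"".join(tals)
    per_record_stamp = [f"+{r:d}\x14\x14\x00".encode("ascii") for r in range(n_records)]
    ann_bytes = max(len(record0), max(len(s) for s in per_record_stamp), 32)
    ann_samples = math.ceil(ann_bytes / 2)

    n_signals = recording.n_channels + 1
    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"{recording.patient_id or 'X'} X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_signals + 1)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_signals), 4),
        ]
    )
    labels = list(recording.channel_labels) + ["EDF Annotations"]
    transducers = ["AgAgCl electrode"] * recording.n_channels + [""]
    dims = ["uV"] * recording.n_channels + [""]
    pmins = phys_min + [-1.0]
    pmaxs = phys_max + [1.0]
    spr = [fs] * recording.n_channels + [ann_samples]
    signal_header = b"".join(
        [
            b"".join(_pad(x, 16) for x in labels),
            b"".join(_pad(x, 80) for x in transducers),
            b"".join(_pad(x, 8) for x in dims),
            b"".join(_fmt(x, 8) for x in pmins),
            b"".join(_fmt(x, 8) for x in pmaxs),
            b"".join(_fmt(_DIG_MIN, 8) for _ in range(n_signals)),
            b"".join(_fmt(_DIG_MAX, 8) for _ in range(n_signals)),
            b"".join(_pad("", 80) for _ in range(n_signals)),
            b"".join(_pad(str(x), 8) for x in spr),
            b"".join(_pad("", 32) for _ in range(n_signals)),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * fs : (r + 1) * fs].tobytes())
            blob = record0 if r == 0 else per_record_stamp[r]
            fh.write(blob.ljust(2 * ann_samples, b"\x00"))
    return path


def read_recording(path, expected_channels: int | None = len(CHANNEL_LABELS)) -> Recording:
    """Read an EDF(+) file into a Recording (microvolts).

    Stage annotations come from the EDF+ annotation track; a file without
    annotations loads with an empty schedule and a warning.  A channel
    count differing from ``expected_channels`` (pass None to skip the
    check) raises.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"malformed EDF file {path.name}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne holds EEG in volts
    labels = tuple(raw.ch_names)
    if expected_channels is not None and len(labels) != expected_channels:
        raise ValueError(
            f"{path.name}: expected {expected_channels} channels, found {len(labels)}"
        )
    annotations = [
        (desc, float(onset), float(dur))
        for desc, onset, dur in zip(
            raw.annotations.description, raw.annotations.onset, raw.annotations.duration
        )
        if dur > 0
    ]
    annotations.sort(key=lambda a: a[1])
    if not annotations:
        logger.warning("%s: no stage annotations found; empty schedule", path.name)
    return Recording(
        channels=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        stage_annotations=annotations,
        patient_id=path.stem,
    )


def quantization_step(path) -> list[float]:
    """Per-channel physical quantization step from the EDF header fields."""
    with open(path, "rb") as fh:
        fh.seek(252)
        n_signals = int(fh.read(4).decode().strip())
        fh.seek(256 + 16 * n_signals + 80 * n_signals + 8 * n_signals)
        pmin = [float(fh.read(8).decode().strip()) for _ in range(n_signals)]
        pmax = [float(fh.read(8).decode().strip()) for _ in range(n_signals)]
        dmin = [float(fh.read(8).decode().strip()) for _ in range(n_signals)]
        dmax = [float(fh.read(8).decode().strip()) for _ in range(n_signals)]
    return [
        (hi - lo) / (dhi - dlo) for lo, hi, dlo, dhi in zip(pmin, pmax, dmin, dmax)
    ][:-1]  # drop the annotation track
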