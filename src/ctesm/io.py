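"""Reading multichannel EEG and cutting it into overlapping frames.

EDF and BrainVision files are read through mne; the package's own CSV
dialect (one column per channel, header row, sampling rate from the cohort
sidecar or an explicit argument) round-trips bit-identically with the
synthetic writer. A minimal EDF writer (16-bit, one-second data records) is
provided so synthetic cohorts can be exported to the field's interchange
format without extra dependencies.

Framing follows the convention of overlapping 2 s windows with 1 s overlap:
frames are laid left-to-right from sample 0 with step = frame length −
overlap, 0-based half-open sample ranges, and trailing samples that do not
fill a whole frame are dropped so every frame's spectral estimates are
comparable. No filtering, re-referencing or artifact rejection is applied;
``window`` accepts a ``preprocess`` callable for users who need one.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .synthetic import Recording

__all__ = ["FrameSet", "FormatError", "read_recording", "window", "write_edf"]


class FormatError(RuntimeError):
    """The file could not be parsed as a supported EEG format."""


@dataclass(frozen=True)
class FrameSet:
    """Overlapping fixed-length windows cut from one Recording."""

    frames: np.ndarray  # (n_frames, frame_samples, n_channels)
    sampling_rate_hz: float
    frame_length_s: float
    overlap_s: float
    source_subject: str
    label: str

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_samples(self) -> int:
        return self.frames.shape[1]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[2]


def window(
    recording: Recording,
    frame_length_s: float = 2.0,
    overlap_s: float = 1.0,
    preprocess: Callable[[np.ndarray], np.ndarray] | None = None,
) -> FrameSet:
    """Segment a recording into overlapping frames.

    Frame i covers samples ``[i*step, i*step + frame_samples)`` with
    ``step = frame_samples - overlap_samples``; the frame count is
    ``floor((n_samples - frame_samples)/step) + 1``.
    """
    if overlap_s < 0:
        raise ValueError("overlap_s must be non-negative")
    if overlap_s >= frame_length_s:
        raise ValueError("overlap_s must be smaller than frame_length_s")
    fs = recording.sampling_rate_hz
    frame_samples = int(round(frame_length_s * fs))
    overlap_samples = int(round(overlap_s * fs))
    step = frame_samples - overlap_samples
    sig = recording.signal
    if preprocess is not None:
        sig = np.asarray(preprocess(sig))
        if sig.shape != recording.signal.shape:
            raise ValueError("preprocess must preserve the signal shape")
    n = sig.shape[0]
    if n < frame_samples:
        raise ValueError(
            f"recording duration {n / fs:g} s is shorter than the "
            f"frame length {frame_length_s:g} s"
        )
    n_frames = (n - frame_samples) // step + 1
    starts = np.arange(n_frames) * step
    frames = np.stack([sig[s : s + frame_samples] for s in starts])
    return FrameSet(
        frames=frames,
        sampling_rate_hz=fs,
        frame_length_s=frame_length_s,
        overlap_s=overlap_s,
        source_subject=recording.subject_id,
        label=recording.label,
    )


# ---------------------------------------------------------------------------
# Readers


def _read_csv_recording(
    path: Path,
    sampling_rate_hz: float | None,
    label: str,
    subject_id: str | None,
) -> Recording:
    if sampling_rate_hz is None:
        sampling_rate_hz, label_sc, sid_sc = _lookup_sidecar(path)
        label = label_sc or label
        subject_id = subject_id or sid_sc
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty CSV") from None
        rows = list(reader)
    if not rows:
        raise FormatError(f"{path}: CSV has a header but no samples")
    try:
        sig = np.array([[float(v) for v in row] for row in rows])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample value ({exc})") from None
    if sig.shape[1] != len(header):
        raise FormatError(f"{path}: ragged CSV rows")
    return Recording(
        signal=sig,
        sampling_rate_hz=sampling_rate_hz,
        label=label,
        subject_id=subject_id or path.stem,
        channel_names=tuple(header),
    )


def _lookup_sidecar(path: Path) -> tuple[float, str | None, str | None]:
    sidecar = path.parent / "cohort.csv"
    if sidecar.exists():
        with open(sidecar, newline="") as fh:
            for row in csv.DictReader(fh):
                if row.get("file") == path.name or row.get("subject_id") == path.stem:
                    return float(row["sampling_rate_hz"]), row.get("label"), row.get("subject_id")
    raise ValueError(
        f"{path}: sampling rate not given and no cohort.csv sidecar entry found"
    )


def _read_mne_recording(path: Path, kind: str, label: str, subject_id: str | None) -> Recording:
    import mne

    try:
        if kind == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: failed to parse as {kind} ({exc})") from exc
    data = raw.get_data()  # channels x samples, volts
    return Recording(
        signal=data.T * 1e6,  # back to microvolts
        sampling_rate_hz=float(raw.info["sfreq"]),
        label=label,
        subject_id=subject_id or path.stem,
        channel_names=tuple(raw.ch_names),
    )


def read_recording(
    path: str | Path,
    format_hint: str | None = None,
    sampling_rate_hz: float | None = None,
    label: str = "unknown",
    subject_id: str | None = None,
) -> Recording:
    """Read one EEG recording from EDF, BrainVision (.vhdr) or CSV.

    The format is taken from ``format_hint`` (``"edf"``, ``"brainvision"``,
    ``"csv"``) or inferred from the suffix. For CSV the sampling rate comes
    from ``sampling_rate_hz`` or the ``cohort.csv`` sidecar next to the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = (format_hint or "").lower() or {
        ".edf": "edf",
        ".vhdr": "brainvision",
        ".csv": "csv",
    }.get(path.suffix.lower(), "")
    if not kind:
        raise FormatError(f"{path}: cannot infer format from suffix; pass format_hint")
    if kind == "csv":
        return _read_csv_recording(path, sampling_rate_hz, label, subject_id)
    if kind in ("edf", "brainvision"):
        return _read_mne_recording(path, kind, label, subject_id)
    raise FormatError(f"unknown format hint {kind!r}")


def read_cohort(directory: str | Path) -> list[Recording]:
    """Read every recording listed in a directory's ``cohort.csv`` sidecar."""
    directory = Path(directory)
    sidecar = directory / "cohort.csv"
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    recordings = []
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh):
            recordings.append(
                read_recording(
                    directory / row["file"],
                    sampling_rate_hz=float(row["sampling_rate_hz"]),
                    label=row["label"],
                    subject_id=row["subject_id"],
                )
            )
    return recordings


# ---------------------------------------------------------------------------
# Minimal EDF writer


def _edf_field(value, width: int) -> bytes:
    text = value if isinstance(value, str) else f"{value:g}"
    if len(text) > width:
        # shorten numeric fields until they fit the fixed-width header slot
        for prec in range(6, 0, -1):
            text = f"{float(value):.{prec}g}"
            if len(text) <= width:
                break
    if len(text) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} chars")
    return text.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a Recording as a plain EDF file (16-bit, 1-s data records).

    The sampling rate must be a whole number of samples per second and the
    duration a whole number of seconds (both hold for the synthetic cohorts).
    Signals are stored in microvolts with per-channel physical scaling over
    the full 16-bit digital range.
    """
    path = Path(path)
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per channel
    n_samples, n_ch = recording.signal.shape
    if n_samples % spr != 0:
        raise ValueError("EDF export requires a whole number of seconds of data")
    n_records = n_samples // spr

    phys_min = recording.signal.min(axis=0)
    phys_max = recording.signal.max(axis=0)
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((recording.signal - phys_min) / gain + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(recording.subject_id, 80),
            _edf_field(f"label {recording.label}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + n_ch)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_edf_field(name[:16], 16) for name in recording.channel_names),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_field(phys_min[c], 8) for c in range(n_ch)),
            b"".join(_edf_field(phys_max[c], 8) for c in range(n_ch)),
            b"".join(_edf_field(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(_edf_field(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            block = digital[r * spr : (r + 1) * spr]  # (spr, n_ch)
            fh.write(block.T.tobytes())  # per signal, contiguous
    return path
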