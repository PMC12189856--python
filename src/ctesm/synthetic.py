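"""Synthetic two-class resting-state EEG cohorts.

Every recording is the sum of one band-limited sinusoid per canonical EEG
band (random frequency within the band, random phase, per-class amplitude
multipliers), a 1/f-shaped stochastic background, and white Gaussian noise.
The class effect is expressed through the band multipliers — e.g. a beta
multiplier of 3 for the PD class triples the beta component amplitude for
every PD subject — which gives downstream spectral features a controllable,
known ground truth.

The generator makes no attempt at physiological artifacts (blinks, EMG) or
volume conduction; it exists to give the feature extractor and classifier a
signal with a known spectral contrast between classes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CANONICAL_BANDS",
    "CohortSpec",
    "Recording",
    "generate_cohort",
    "write_cohort_csv",
    "write_cohort_edf",
]

#: Canonical EEG band edges in Hz. The beta band (13-30 Hz) carries the
#: oscillatory disruption associated with Parkinson's disease.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

CLASSES = ("PD", "HC")


class SpecValidationError(ValueError):
    """A CohortSpec field violates its invariant; the message names the field."""


@dataclass(frozen=True)
class Recording:
    """One subject's multichannel EEG: samples x channels, microvolt scale."""

    signal: np.ndarray
    sampling_rate_hz: float
    label: str
    subject_id: str
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim != 2:
            raise ValueError("signal must be a 2-D samples x channels array")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "signal", sig)
        if not self.channel_names:
            object.__setattr__(
                self,
                "channel_names",
                tuple(f"ch{i + 1}" for i in range(sig.shape[1])),
            )
        if len(self.channel_names) != sig.shape[1]:
            raise ValueError("channel_names length must match n_channels")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def _default_class_effect() -> dict[str, dict[str, float]]:
    # PD: elevated beta-band amplitude, the canonical resting-state contrast.
    return {"PD": {"beta": 2.0}, "HC": {}}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    ``class_effect`` maps class name -> {band name -> amplitude multiplier};
    bands not listed default to multiplier 1. ``n_subjects`` may override the
    per-class count (e.g. ``{"PD": 15, "HC": 16}`` for a 31-subject cohort).
    """

    n_subjects_per_class: int = 12
    n_channels: int = 40
    sampling_rate_hz: float = 500.0
    duration_s: float = 16.0
    class_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_class_effect
    )
    noise_sd: float = 1.0
    background_exponent: float = 1.0
    background_sd: float = 1.0
    component_amplitude: float = 2.0
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CANONICAL_BANDS)
    )
    n_subjects: Mapping[str, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_class < 1:
            raise SpecValidationError("n_subjects_per_class must be >= 1")
        if self.n_channels < 1:
            raise SpecValidationError("n_channels must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise SpecValidationError("sampling_rate_hz must be positive")
        if self.duration_s <= 0:
            raise SpecValidationError("duration_s must be positive")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be non-negative")
        if self.component_amplitude < 0:
            raise SpecValidationError("component_amplitude must be non-negative")
        highest_edge = max(hi for _, hi in self.bands.values())
        if self.sampling_rate_hz <= 2 * highest_edge:
            raise SpecValidationError(
                "sampling_rate_hz must exceed twice the highest band edge"
            )
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi):
                raise SpecValidationError(f"bands[{name}] must satisfy 0 <= low < high")
        for cls, effects in self.class_effect.items():
            for band, mult in effects.items():
                if band not in self.bands:
                    raise SpecValidationError(
                        f"class_effect[{cls}] names unknown band {band!r}"
                    )
                if mult <= 0:
                    raise SpecValidationError(
                        f"class_effect[{cls}][{band}] multiplier must be positive"
                    )
        if self.n_subjects is not None:
            for cls, n in self.n_subjects.items():
                if cls not in CLASSES:
                    raise SpecValidationError(f"n_subjects names unknown class {cls!r}")
                if n < 1:
                    raise SpecValidationError(f"n_subjects[{cls}] must be >= 1")

    def counts(self) -> dict[str, int]:
        base = {cls: self.n_subjects_per_class for cls in CLASSES}
        if self.n_subjects is not None:
            base.update(self.n_subjects)
        return base


def _one_over_f_background(
    rng: np.random.Generator, n_samples: int, fs: float, exponent: float, sd: float
) -> np.ndarray:
    """White noise spectrally shaped to a 1/f^exponent power law.

    FFT amplitudes of a white-noise draw are multiplied by f^(-exponent/2)
    so the resulting power spectrum falls off as f^(-exponent); the DC bin
    is zeroed. The output is rescaled to the requested standard deviation.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n_samples)
    cur_sd = shaped.std()
    if cur_sd > 0 and sd > 0:
        shaped *= sd / cur_sd
    elif sd == 0:
        shaped[:] = 0.0
    return shaped


def _subject_signal(
    rng: np.random.Generator, spec: CohortSpec, multipliers: Mapping[str, float]
) -> np.ndarray:
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    t = np.arange(n) / spec.sampling_rate_hz
    sig = np.zeros((n, spec.n_channels))
    for band, (lo, hi) in spec.bands.items():
        mult = multipliers.get(band, 1.0)
        # One component per band per channel: frequency shared within the
        # subject (drawn uniformly in the band), phase per channel.
        f0 = rng.uniform(lo, hi)
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        amps = spec.component_amplitude * mult * rng.uniform(
            0.8, 1.2, size=spec.n_channels
        )
        sig += amps * np.sin(2 * np.pi * f0 * t[:, None] + phases)
    for ch in range(spec.n_channels):
        sig[:, ch] += _one_over_f_background(
            rng, n, spec.sampling_rate_hz, spec.background_exponent, spec.background_sd
        )
    if spec.noise_sd > 0:
        sig += rng.normal(0.0, spec.noise_sd, size=sig.shape)
    return sig


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``2 x n_subjects_per_class`` labelled Recordings.

    One seed stream is split per subject by counter (``SeedSequence.spawn``)
    so subjects are statistically independent and the cohort is bit-identical
    for identical specs.
    """
    spec.validate()
    counts = spec.counts()
    total = sum(counts.values())
    seed_seq = np.random.SeedSequence(spec.seed)
    child_seqs = seed_seq.spawn(total)
    recordings: list[Recording] = []
    idx = 0
    for cls in CLASSES:
        multipliers = dict(spec.class_effect.get(cls, {}))
        for k in range(counts[cls]):
            rng = np.random.default_rng(child_seqs[idx])
            sig = _subject_signal(rng, spec, multipliers)
            recordings.append(
                Recording(
                    signal=sig,
                    sampling_rate_hz=spec.sampling_rate_hz,
                    label=cls,
                    subject_id=f"{cls.lower()}{k + 1:03d}",
                )
            )
            idx += 1
    return recordings


def write_cohort_csv(recordings: Sequence[Recording], out_dir: str | Path) -> Path:
    """Write each Recording as a CSV (one column per channel, header row) plus
    a ``cohort.csv`` sidecar with subject_id, label and sampling rate.

    Returns the sidecar path. Floats are written with ``repr`` so the CSV
    round-trips bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar = out_dir / "cohort.csv"
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "sampling_rate_hz", "file"])
        for rec in recordings:
            fname = f"{rec.subject_id}.csv"
            writer.writerow([rec.subject_id, rec.label, repr(rec.sampling_rate_hz), fname])
            with open(out_dir / fname, "w", newline="") as sig_fh:
                sig_writer = csv.writer(sig_fh)
                sig_writer.writerow(rec.channel_names)
                for row in rec.signal:
                    sig_writer.writerow([repr(float(v)) for v in row])
    return sidecar


def write_cohort_edf(recordings: Sequence[Recording], out_dir: str | Path) -> list[Path]:
    """Write each Recording as an EDF file (plus the CSV sidecar table)."""
    from .io import write_edf  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    with open(out_dir / "cohort.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "sampling_rate_hz", "file"])
        for rec in recordings:
            fname = f"{rec.subject_id}.edf"
            writer.writerow([rec.subject_id, rec.label, repr(rec.sampling_rate_hz), fname])
            path = out_dir / fname
            write_edf(rec, path)
            paths.append(path)
    return paths
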