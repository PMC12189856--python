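"""Frame-wise, channel-wise biologically informed EEG features.

Per frame-channel pair the extractor computes, in a fixed, versioned order:

* mean Welch power in the five canonical bands (delta, theta, alpha, beta,
  gamma) — band power here is the *mean* PSD over the band's frequency
  bins, not the integral;
* the beta-to-alpha power ratio, the classical marker of parkinsonian
  beta-band disruption;
* median frequency (where the cumulative PSD first reaches half the total);
* spectral entropy in bits of the PSD normalized to a probability mass;
* the mean absolute wavelet coefficient at each DWT detail level plus the
  final approximation (Daubechies-4, 5 levels by default — at 500 Hz the
  detail levels roughly track the canonical bands);
* approximate entropy ApEn(m=2, r=0.2·SD), the template-matching regularity
  statistic (an amplitude-histogram entropy variant is available via
  ``apen_method="amplitude"``);
* skewness, kurtosis and zero-crossing rate. Moments use the population
  convention (divide by N) and kurtosis is *not* excess-adjusted, so a
  Gaussian signal has kurtosis ≈ 3.

Features that are undefined on a degenerate frame (zero variance, zero
total power) are replaced by a sentinel (default 0) and the frame/channel/
feature triple is recorded in the instance's ``flags``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .io import FrameSet
from .synthetic import CANONICAL_BANDS

__all__ = [
    "BandDefinition",
    "FeatureConfig",
    "FeatureInstance",
    "SpectralEstimate",
    "UndefinedFeatureError",
    "approximate_entropy",
    "band_power",
    "band_ratio",
    "extract_features",
    "kurtosis",
    "median_frequency",
    "read_feature_table",
    "skewness",
    "spectral_entropy",
    "wavelet_level_means",
    "welch_psd",
    "write_feature_table",
    "zero_crossing_rate",
]

FEATURE_ORDER_VERSION = "ctesm-features-v1"


class UndefinedFeatureError(ValueError):
    """The feature has no defined value on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name}: need 0 <= low < high")


DEFAULT_BANDS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(name, lo, hi) for name, (lo, hi) in CANONICAL_BANDS.items()
)


@dataclass(frozen=True)
class SpectralEstimate:
    """A one-sided PSD estimate: frequencies (Hz) and power density values."""

    frequencies: np.ndarray
    psd: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and psd must be 1-D and equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("psd must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "psd", p)


@dataclass
class FeatureInstance:
    """channels x features matrix for one frame, with provenance."""

    matrix: np.ndarray
    feature_names: tuple[str, ...]
    label: str
    subject_id: str
    frame_index: int
    flags: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix must be n_channels x n_features")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass(frozen=True)
class FeatureConfig:
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    welch_segment_s: float = 1.0
    welch_overlap: float = 0.5
    welch_window: str = "hann"
    wavelet: str = "db4"
    wavelet_levels: int = 5
    apen_m: int = 2
    apen_r: float = 0.2
    apen_method: str = "template"  # or "amplitude"
    ratio_epsilon: float = 1e-12
    sentinel: float = 0.0

    def feature_names(self) -> tuple[str, ...]:
        names = [f"power_{b.name}" for b in self.bands]
        names += ["beta_alpha_ratio", "median_frequency", "spectral_entropy"]
        names += [f"wavelet_d{j}" for j in range(1, self.wavelet_levels + 1)]
        names += [f"wavelet_a{self.wavelet_levels}"]
        names += ["apen", "skewness", "kurtosis", "zcr"]
        return tuple(names)


# ---------------------------------------------------------------------------
# Spectral features


def welch_psd(
    x: np.ndarray,
    sampling_rate_hz: float,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectralEstimate:
    """Welch averaged-periodogram PSD of a single frame-channel vector.

    Hann taper, 50% segment overlap by default (two or more averages inside
    a 2 s frame at a 1 s segment). Total power integrates to approximately
    the signal variance (Parseval, within taper bias).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * sampling_rate_hz))
    if x.ndim != 1:
        raise ValueError("welch_psd expects a 1-D frame-channel vector")
    if x.size < nperseg:
        raise ValueError(
            f"input length {x.size} is shorter than the Welch segment {nperseg}"
        )
    freqs, psd = sps.welch(
        x,
        fs=sampling_rate_hz,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend=False,
    )
    return SpectralEstimate(frequencies=freqs, psd=psd)


def _band_mask(est: SpectralEstimate, low_hz: float, high_hz: float) -> np.ndarray:
    return (est.frequencies >= low_hz) & (est.frequencies < high_hz)


def band_power(est: SpectralEstimate, band: BandDefinition) -> float:
    """Mean PSD over the band's frequency bins (low <= f < high)."""
    mask = _band_mask(est, band.low_hz, band.high_hz)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}) contains no PSD bins"
        )
    return float(est.psd[mask].mean())


def band_ratio(
    p_beta: float, p_alpha: float, epsilon: float = 1e-12
) -> tuple[float, bool]:
    """Beta-to-alpha power ratio with an epsilon floor on the denominator.

    Returns ``(ratio, floored)`` where ``floored`` records that the alpha
    power was at or below the floor and the ratio is therefore unreliable.
    """
    if p_beta < 0 or p_alpha < 0:
        raise ValueError("band powers must be non-negative")
    floored = p_alpha <= epsilon
    return float(p_beta / max(p_alpha, epsilon)), floored


def median_frequency(est: SpectralEstimate) -> float:
    """Smallest frequency at which cumulative PSD reaches half the total."""
    total = est.psd.sum()
    if total <= 0:
        raise UndefinedFeatureError("median frequency undefined for zero total power")
    cum = np.cumsum(est.psd)
    idx = int(np.searchsorted(cum, 0.5 * total))
    return float(est.frequencies[idx])


def spectral_entropy(est: SpectralEstimate) -> float:
    """Shannon entropy (bits) of the PSD normalized to a probability mass."""
    total = est.psd.sum()
    if total <= 0:
        raise UndefinedFeatureError("spectral entropy undefined for zero total power")
    p = est.psd / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


# ---------------------------------------------------------------------------
# Wavelet features


def wavelet_level_means(
    x: np.ndarray, wavelet: str = "db4", levels: int = 5
) -> np.ndarray:
    """Mean absolute DWT coefficient per detail level (finest first) plus the
    final approximation level: ``[d1, ..., dL, aL]``."""
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if levels > max_level:
        raise ValueError(
            f"requested {levels} levels but input length {x.size} supports "
            f"at most {max_level} for wavelet {wavelet}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels)  # [aL, dL, ..., d1]
    details = coeffs[:0:-1]  # d1 ... dL
    means = [float(np.abs(c).mean()) for c in details]
    means.append(float(np.abs(coeffs[0]).mean()))
    return np.array(means)


# ---------------------------------------------------------------------------
# Entropy and statistical features


def approximate_entropy(
    x: np.ndarray, m: int = 2, r: float = 0.2, method: str = "template"
) -> tuple[float, bool]:
    """Approximate entropy of a frame-channel vector.

    ``method="template"`` (default) is the standard ApEn(m, r·SD):
    Φ_m − Φ_{m+1}, where Φ_m is the mean log fraction of length-m templates
    lying within Chebyshev distance r·SD of each template (self-matches
    included). Lower values mean a more regular, predictable signal.

    ``method="amplitude"`` is an alternative reading that computes the
    Shannon entropy (natural log) of the signal's amplitude distribution
    over 10 equal-width histogram bins.

    Returns ``(value, degenerate)``; a zero-variance input yields
    ``(0.0, True)`` — perfectly regular, flagged.
    """
    x = np.asarray(x, dtype=float)
    if r <= 0:
        raise ValueError("tolerance fraction r must be positive")
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    sd = x.std()
    if sd == 0:
        return 0.0, True
    if method == "amplitude":
        counts, _ = np.histogram(x, bins=10)
        p = counts[counts > 0] / n
        return float(-(p * np.log(p)).sum()), False
    if method != "template":
        raise ValueError(f"unknown ApEn method {method!r}")
    tol = r * sd
    # Chebyshev template distances built once from the pairwise sample
    # distance matrix; D_m[i, j] = max_{k<m} |x[i+k] - x[j+k]|, grown
    # incrementally so the m+1 pass reuses the length-m maxima.
    d0 = np.abs(x[:, None] - x[None, :])
    dm = d0
    for k in range(1, m):
        nt = n - k
        dm = np.maximum(dm[:nt, :nt], d0[k:, k:])

    def phi_of(dmat: np.ndarray) -> float:
        counts = (dmat <= tol).mean(axis=1)
        return float(np.log(counts).mean())

    phi_m = phi_of(dm)
    nt = n - m
    dm1 = np.maximum(dm[:nt, :nt], d0[m:, m:])
    return phi_m - phi_of(dm1), False


def skewness(x: np.ndarray) -> float:
    """Population skewness: mean(((x−μ)/σ)^3), dividing by N."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise UndefinedFeatureError("skewness undefined for zero variance")
    return float(np.mean(((x - mu) / sd) ** 3))


def kurtosis(x: np.ndarray) -> float:
    """Population kurtosis mean(((x−μ)/σ)^4), not excess-adjusted (no −3)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise UndefinedFeatureError("kurtosis undefined for zero variance")
    return float(np.mean(((x - mu) / sd) ** 4))


def zero_crossing_rate(x: np.ndarray) -> float:
    """Fraction of adjacent sample pairs whose product is negative."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(x[1:] * x[:-1] < 0))


# ---------------------------------------------------------------------------
# Assembly


def _band_by_name(cfg: FeatureConfig, name: str) -> BandDefinition:
    for b in cfg.bands:
        if b.name == name:
            return b
    raise ValueError(f"feature config defines no {name!r} band")


def extract_features(
    frameset: FrameSet, config: FeatureConfig | None = None
) -> list[FeatureInstance]:
    """One FeatureInstance (channels x features) per frame of a FrameSet.

    Channel order is preserved; undefined features become the configured
    sentinel and are recorded in the instance's ``flags`` as
    ``(channel_index, feature_name)``. Extraction is deterministic.
    """
    cfg = config or FeatureConfig()
    names = cfg.feature_names()
    beta = _band_by_name(cfg, "beta")
    alpha = _band_by_name(cfg, "alpha")
    fs = frameset.sampling_rate_hz
    instances: list[FeatureInstance] = []
    for fi in range(frameset.n_frames):
        frame = frameset.frames[fi]  # (samples, channels)
        mat = np.empty((frameset.n_channels, len(names)))
        flags: list[tuple[int, str]] = []
        for ch in range(frameset.n_channels):
            x = frame[:, ch]
            est = welch_psd(
                x, fs, cfg.welch_segment_s, cfg.welch_overlap, cfg.welch_window
            )
            col = 0
            powers = {}
            for b in cfg.bands:
                powers[b.name] = band_power(est, b)
                mat[ch, col] = powers[b.name]
                col += 1
            ratio, floored = band_ratio(
                powers[beta.name], powers[alpha.name], cfg.ratio_epsilon
            )
            mat[ch, col] = ratio
            if floored:
                flags.append((ch, "beta_alpha_ratio"))
            col += 1
            try:
                mat[ch, col] = median_frequency(est)
            except UndefinedFeatureError:
                mat[ch, col] = cfg.sentinel
                flags.append((ch, "median_frequency"))
            col += 1
            try:
                mat[ch, col] = spectral_entropy(est)
            except UndefinedFeatureError:
                mat[ch, col] = cfg.sentinel
                flags.append((ch, "spectral_entropy"))
            col += 1
            wl = wavelet_level_means(x, cfg.wavelet, cfg.wavelet_levels)
            mat[ch, col : col + wl.size] = wl
            col += wl.size
            apen, degenerate = approximate_entropy(
                x, cfg.apen_m, cfg.apen_r, cfg.apen_method
            )
            mat[ch, col] = apen
            if degenerate:
                flags.append((ch, "apen"))
            col += 1
            for fn, fname in ((skewness, "skewness"), (kurtosis, "kurtosis")):
                try:
                    mat[ch, col] = fn(x)
                except UndefinedFeatureError:
                    mat[ch, col] = cfg.sentinel
                    flags.append((ch, fname))
                col += 1
            mat[ch, col] = zero_crossing_rate(x)
        instances.append(
            FeatureInstance(
                matrix=mat,
                feature_names=names,
                label=frameset.label,
                subject_id=frameset.source_subject,
                frame_index=fi,
                flags=flags,
            )
        )
    return instances


def extract_cohort_features(
    framesets: Sequence[FrameSet], config: FeatureConfig | None = None
) -> list[FeatureInstance]:
    """Concatenate per-recording extraction over a cohort of FrameSets."""
    out: list[FeatureInstance] = []
    for fset in framesets:
        out.extend(extract_features(fset, config))
    return out


# ---------------------------------------------------------------------------
# Serialization


def write_feature_table(
    instances: Sequence[FeatureInstance], path: str | Path
) -> Path:
    """Serialize FeatureInstances as one long-format CSV table.

    Columns: subject_id, frame_index, label, channel, then one column per
    feature in the run's frozen order.
    """
    if not instances:
        raise ValueError("no instances to write")
    names = instances[0].feature_names
    rows = []
    for inst in instances:
        if inst.feature_names != names:
            raise ValueError("inconsistent feature_names across instances")
        for ch in range(inst.matrix.shape[0]):
            rows.append(
                {
                    "subject_id": inst.subject_id,
                    "frame_index": inst.frame_index,
                    "label": inst.label,
                    "channel": ch,
                    **{name: inst.matrix[ch, j] for j, name in enumerate(names)},
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> list[FeatureInstance]:
    """Inverse of :func:`write_feature_table`."""
    df = pd.read_csv(path)
    meta_cols = ["subject_id", "frame_index", "label", "channel"]
    names = tuple(c for c in df.columns if c not in meta_cols)
    instances = []
    for (sid, fi, label), grp in df.groupby(
        ["subject_id", "frame_index", "label"], sort=False
    ):
        grp = grp.sort_values("channel")
        instances.append(
            FeatureInstance(
                matrix=grp[list(names)].to_numpy(),
                feature_names=names,
                label=str(label),
                subject_id=str(sid),
                frame_index=int(fi),
            )
        )
    return instances
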