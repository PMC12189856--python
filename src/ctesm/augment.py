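"""Feature-level data augmentation: noise, amplitude scaling, modulation.

Each original channels x features matrix X yields ``n_variants`` synthetic
matrices via three steps:

1. add zero-mean Gaussian noise (SD ``noise_sd``, default 0.05 on the raw
   feature scale);
2. multiply by one scalar drawn uniformly from ``[scale_low, scale_high]``
   (default [0.9, 1.1]) to mimic amplitude fluctuations;
3. dynamic modulation — per-entry offsets drawn uniformly in
   ``±modulation_strength·SD(X)``, exactly de-meaned — followed by
   re-centering the matrix to its post-noise mean, so feature centering is
   maintained: a synthetic instance's mean differs from its parent's only by
   the averaged noise, i.e. by O(noise_sd/sqrt(C·F)).

With the default 50 variants an N-instance set expands to N x 51. All
synthetic instances inherit their parent's class label. Because the noise SD
is applied on the raw feature scale it is sensitive to heterogeneous feature
units; ``standardize_noise=True`` rescales the noise per feature column by
that instance's per-feature SD instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureInstance

__all__ = ["AugmentationSpec", "AugmentedDataset", "augment"]


@dataclass(frozen=True)
class AugmentationSpec:
    noise_sd: float = 0.05
    scale_low: float = 0.9
    scale_high: float = 1.1
    n_variants: int = 50
    modulation_strength: float = 0.1
    standardize_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.scale_low > self.scale_high:
            raise ValueError("scale_low must not exceed scale_high")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.modulation_strength < 0:
            raise ValueError("modulation_strength must be non-negative")


@dataclass
class AugmentedDataset:
    """Originals plus synthetic variants, with per-instance provenance."""

    instances: list[FeatureInstance]
    is_synthetic: np.ndarray  # bool per instance
    parent_index: np.ndarray  # index into `instances` of each parent (self for originals)

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def labels(self) -> list[str]:
        return [inst.label for inst in self.instances]

    def matrices(self) -> np.ndarray:
        return np.stack([inst.matrix for inst in self.instances])


def _synthesize(
    matrix: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.normal(0.0, spec.noise_sd, size=matrix.shape)
    if spec.standardize_noise:
        col_sd = matrix.std(axis=0, keepdims=True)
        noise = noise * np.where(col_sd > 0, col_sd, 1.0)
    x1 = matrix + noise
    mu1 = x1.mean()
    x2 = x1 * rng.uniform(spec.scale_low, spec.scale_high)
    if spec.modulation_strength > 0:
        offsets = rng.uniform(
            -spec.modulation_strength, spec.modulation_strength, size=matrix.shape
        ) * x1.std()
        offsets -= offsets.mean()
        x3 = x2 + offsets
    else:
        x3 = x2
    # re-center to the post-noise mean: feature centering is preserved
    return x3 + (mu1 - x3.mean())


def augment(
    instances: Sequence[FeatureInstance], spec: AugmentationSpec | None = None
) -> AugmentedDataset:
    """Expand a feature-instance set ``(n_variants + 1)``-fold.

    Output order: each original followed by its variants, so
    ``len(out) == len(instances) * (spec.n_variants + 1)``. Deterministic
    given ``spec.seed``; variant streams are split per original instance.
    """
    spec = spec or AugmentationSpec()
    spec.validate()
    if not instances:
        raise ValueError("augment requires a non-empty instance collection")
    child_seqs = np.random.SeedSequence(spec.seed).spawn(len(instances))
    out: list[FeatureInstance] = []
    synthetic: list[bool] = []
    parents: list[int] = []
    for i, inst in enumerate(instances):
        parent_pos = len(out)
        out.append(inst)
        synthetic.append(False)
        parents.append(parent_pos)
        rng = np.random.default_rng(child_seqs[i])
        for v in range(spec.n_variants):
            out.append(
                FeatureInstance(
                    matrix=_synthesize(inst.matrix, spec, rng),
                    feature_names=inst.feature_names,
                    label=inst.label,
                    subject_id=inst.subject_id,
                    frame_index=inst.frame_index,
                )
            )
            synthetic.append(True)
            parents.append(parent_pos)
    return AugmentedDataset(
        instances=out,
        is_synthetic=np.array(synthetic),
        parent_index=np.array(parents),
    )
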