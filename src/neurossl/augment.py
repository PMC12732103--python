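"""Medically safe 3D augmentations for pretraining.

The policy is deliberately conservative — small rotations (<= 10 degrees),
axis flips, mild Gaussian blur, multiplicative intensity jitter within
+/- 10%, and random 3D crops — so that augmented views remain plausible
scans of the same brain.  The mask undergoes the identical geometric
transform (nearest-neighbour for the mask, trilinear for intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .cohort import Volume

__all__ = ["AugmentationPolicy", "augment"]


@dataclass(frozen=True)
class AugmentationPolicy:
    flip_axes: tuple[int, ...] = (0, 1, 2)
    flip_prob: float = 0.5
    rotation_deg: float = 10.0            # max |angle|, clinically safe regime
    blur_sigma: tuple[float, float] = (0.0, 1.0)
    intensity_jitter: float = 0.10        # multiplicative, +/- fraction
    crop_size: int | None = None          # None = no crop

    def validate(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.rotation_deg < 0 or self.rotation_deg > 10.0:
            raise ValueError("rotation limited to <= 10 degrees")
        if self.intensity_jitter < 0 or self.intensity_jitter > 0.10:
            raise ValueError("intensity jitter limited to <= 10%")
        if self.blur_sigma[0] < 0 or self.blur_sigma[1] < self.blur_sigma[0]:
            raise ValueError("blur_sigma must be a non-negative range")


def augment(v: Volume, policy: AugmentationPolicy, rng: np.random.Generator) -> Volume:
    """Apply flip -> rotation -> blur -> jitter -> crop; deterministic given rng."""
    policy.validate()
    data, mask = v.data, v.mask
    if policy.crop_size is not None and policy.crop_size > data.shape[0]:
        raise ValueError("crop size exceeds grid size")

    for ax in policy.flip_axes:
        if rng.random() < policy.flip_prob:
            data = np.flip(data, axis=ax)
            mask = np.flip(mask, axis=ax)

    if policy.rotation_deg > 0:
        angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
        axes = tuple(rng.choice(3, size=2, replace=False))
        data = ndimage.rotate(data, angle, axes=axes, reshape=False, order=1, mode="constant")
        mask = ndimage.rotate(mask.astype(np.uint8), angle, axes=axes, reshape=False,
                              order=0, mode="constant").astype(bool)

    lo, hi = policy.blur_sigma
    if hi > 0:
        sigma = rng.uniform(lo, hi)
        if sigma > 1e-6:
            data = ndimage.gaussian_filter(data, sigma)

    if policy.intensity_jitter > 0:
        factor = rng.uniform(1.0 - policy.intensity_jitter, 1.0 + policy.intensity_jitter)
        data = data * factor

    if policy.crop_size is not None and policy.crop_size < data.shape[0]:
        c = policy.crop_size
        starts = [int(rng.integers(0, s - c + 1)) for s in data.shape]
        sl = tuple(slice(st, st + c) for st in starts)
        data, mask = data[sl], mask[sl]

    if not mask.any():  # keep the volume valid even under extreme crops
        mask = np.ones_like(mask)
    return replace(v, data=np.ascontiguousarray(data), mask=np.ascontiguousarray(mask))
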