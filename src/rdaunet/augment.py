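"""Joint image/mask augmentation: the five-transform policy.

The five transforms and their default ranges are: size scaling chosen from
{1.0, 1.2}, rotation within ±15°, x/y shifts within ±10 px, shear within
±5°, and horizontal flip with probability 0.5.  A sampled transform is one
affine map composed in the fixed order scale → rotate → shear → shift →
flip, all about the image centre, and is applied identically to the image
(bilinear, zero fill) and its mask (nearest-neighbour, zero fill), so masks
stay binary.  Expansion emits each original plus `multiplier − 1`
independently sampled augmented copies (default multiplier 3, which takes a
712-slice corpus to 2136).

Axis convention: dx moves content toward larger column indices (right), dy
toward larger row indices (down); shear is horizontal (x picks up a
tan(shear)·y term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from .ct_io import SamplePair, MaskSlice
from .errors import PairingError, ParameterError

__all__ = ["AugmentPolicy", "TransformSpec", "sample_transform",
           "apply_transform", "expand_dataset"]


@dataclass(frozen=True)
class AugmentPolicy:
    scale_choices: tuple = (1.0, 1.2)
    rotation_range_deg: float = 15.0
    shift_range_px: float = 10.0
    shear_range_deg: float = 5.0
    hflip_prob: float = 0.5
    multiplier: int = 3

    def __post_init__(self):
        if self.multiplier < 1:
            raise ParameterError("multiplier must be >= 1")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ParameterError("hflip_prob must be in [0,1]")
        for r in (self.rotation_range_deg, self.shift_range_px, self.shear_range_deg):
            if r < 0:
                raise ParameterError("transform ranges must be non-negative")
        if not self.scale_choices or any(s <= 0 for s in self.scale_choices):
            raise ParameterError("scale choices must be positive")


@dataclass(frozen=True)
class TransformSpec:
    scale: float = 1.0
    angle_deg: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    shear_deg: float = 0.0
    hflip: bool = False

    @property
    def is_identity(self) -> bool:
        return (self.scale == 1.0 and self.angle_deg == 0.0 and self.dx == 0.0
                and self.dy == 0.0 and self.shear_deg == 0.0 and not self.hflip)


def sample_transform(policy: AugmentPolicy, rng: np.random.Generator) -> TransformSpec:
    """Draw each component independently and uniformly from its range."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return TransformSpec(
        scale=float(policy.scale_choices[rng.integers(len(policy.scale_choices))]),
        angle_deg=float(rng.uniform(-policy.rotation_range_deg,
                                    policy.rotation_range_deg)),
        dx=float(rng.uniform(-policy.shift_range_px, policy.shift_range_px)),
        dy=float(rng.uniform(-policy.shift_range_px, policy.shift_range_px)),
        shear_deg=float(rng.uniform(-policy.shear_range_deg,
                                    policy.shear_range_deg)),
        hflip=bool(rng.random() < policy.hflip_prob),
    )


def _forward_matrix(t: TransformSpec, shape) -> np.ndarray:
    """Homogeneous 3x3 forward map in (x, y) = (col, row) coordinates,
    composed scale -> rotate -> shear -> shift -> flip about the centre."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    def mat(a, b, c, d, tx=0.0, ty=0.0):
        return np.array([[a, b, tx], [c, d, ty], [0, 0, 1.0]])

    s = mat(t.scale, 0, 0, t.scale)
    th = np.deg2rad(t.angle_deg)
    r = mat(np.cos(th), -np.sin(th), np.sin(th), np.cos(th))
    sh = mat(1.0, np.tan(np.deg2rad(t.shear_deg)), 0.0, 1.0)
    tr = mat(1, 0, 0, 1, t.dx, t.dy)
    f = mat(-1.0, 0, 0, 1.0) if t.hflip else np.eye(3)
    center = mat(1, 0, 0, 1, cx, cy)
    uncenter = mat(1, 0, 0, 1, -cx, -cy)
    return center @ f @ tr @ sh @ r @ s @ uncenter


def apply_transform(pair: SamplePair, t: TransformSpec) -> SamplePair:
    """Apply one sampled transform jointly to image and mask.

    Output shape is unchanged; regions mapped from outside the frame are
    filled with 0 (background) in both channels.
    """
    if pair.image.shape != pair.mask.pixels.shape:
        raise PairingError("image and mask shapes differ")
    if t.is_identity:
        return SamplePair(pair.image.copy(), MaskSlice(pair.mask.pixels.copy()),
                          pair.slice_id)
    hxy = _forward_matrix(t, pair.image.shape)
    hinv = np.linalg.inv(hxy)
    # convert (x, y) homogeneous map to the (row, col) convention of ndimage
    perm = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1.0]])
    hrc = perm @ hinv @ perm
    matrix, offset = hrc[:2, :2], hrc[:2, 2]
    img = affine_transform(pair.image, matrix, offset=offset, order=1,
                           mode="constant", cval=0.0)
    msk = affine_transform(pair.mask.pixels, matrix, offset=offset, order=0,
                           mode="constant", cval=0)
    return SamplePair(np.clip(img, 0.0, 1.0), MaskSlice(msk), pair.slice_id)


def expand_dataset(pairs, policy: AugmentPolicy, rng: np.random.Generator):
    """Expand n pairs to multiplier × n: each original plus multiplier − 1
    independently augmented copies with derived slice ids."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pairs = list(pairs)
    if not pairs:
        warnings.warn("expand_dataset: empty input, empty output", stacklevel=2)
        return []
    out = []
    for p in pairs:
        out.append(p)
        for k in range(policy.multiplier - 1):
            t = sample_transform(policy, rng)
            aug = apply_transform(p, t)
            out.append(SamplePair(aug.image, aug.mask,
                                  f"{p.slice_id}#aug{k + 1}"))
    return out
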