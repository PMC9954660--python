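"""Synthetic abdominal-CT-like phantoms with exact organ and lesion masks.

Each phantom is a 2D slice of soft-tissue background containing one
fluid-filled bladder-like organ, optional lesion blobs inside it, and (for
the near-bone taxonomy) a high-HU bone crescent.  Shapes follow the case
taxonomy seen in clinical series: round, elongated, irregular-boundary,
organ abutting bone, and organ near the top of the field of view; lesions
come as a single large blob, several large blobs, small blobs, or one
irregular blob.

Masks record the exact pre-noise geometry, so ground truth is perfect by
construction, and the tissue HU means are separated by more than twice the
noise standard deviation, so the segmentation task is solvable from
intensity alone.  That makes the phantoms a wiring test for the training
pipeline, not a claim of anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .ct_io import (CTSlice, MaskSlice, SamplePair, DEFAULT_WINDOW,
                    apply_hu_window, save_pairs)
from .errors import SpecError, ParameterError

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "ORGAN_SHAPES", "LESION_PATTERNS"]

ORGAN_SHAPES = ("round", "elongated", "irregular", "near_bone", "near_top")
LESION_PATTERNS = ("none", "single_large", "multi_large", "small", "irregular")


@dataclass(frozen=True)
class PhantomSpec:
    """Tissue intensities and geometry ranges for one phantom slice.

    HU means: soft-tissue body 40, urine 10, lesion 60, bone 700 — plausible
    non-contrast abdominal contrasts that survive the default soft-tissue
    window.  noise_sigma defaults to 8 HU so every pair of tissue means is
    separated by more than 2·sigma (the closest pair, body vs lesion, differs
    by 20 HU).
    """

    side: int = 224
    body_hu: float = 40.0
    urine_hu: float = 10.0
    lesion_hu: float = 60.0
    bone_hu: float = 700.0
    noise_sigma: float = 8.0
    texture_amplitude: float = 4.0
    organ_shape: str = "round"
    lesion_pattern: str = "none"
    lesion_count_range: tuple = (1, 3)
    organ_area_range: tuple = (0.03, 0.20)

    def __post_init__(self):
        if self.side < 16:
            raise SpecError("side must be at least 16 px")
        if self.organ_shape not in ORGAN_SHAPES:
            raise SpecError(f"unknown organ_shape {self.organ_shape!r}")
        if self.lesion_pattern not in LESION_PATTERNS:
            raise SpecError(f"unknown lesion_pattern {self.lesion_pattern!r}")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        lo, hi = self.organ_area_range
        if not (0.0 < lo < hi < 0.5):
            raise SpecError("organ_area_range must lie strictly inside (0, 0.5)")
        means = (self.body_hu, self.urine_hu, self.lesion_hu, self.bone_hu)
        for i, a in enumerate(means):
            for b in means[i + 1:]:
                if abs(a - b) <= 2.0 * self.noise_sigma:
                    raise SpecError(
                        f"tissue means {a} and {b} closer than 2*noise_sigma "
                        f"({self.noise_sigma}); task not separable by construction")


def _ellipse_mask(side, cy, cx, ry, rx, angle, perturb_amp, rng):
    """Binary ellipse, optionally with a smooth random radial perturbation."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    rho = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    if perturb_amp > 0:
        theta = np.arctan2(v, u)
        bound = np.ones_like(theta)
        for k in range(2, 6):
            bound += (perturb_amp / k) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        return rho <= bound
    return rho <= 1.0


def _draw_organ(spec: PhantomSpec, rng):
    side = spec.side
    area_frac = rng.uniform(*spec.organ_area_range)
    area = area_frac * side * side
    if spec.organ_shape == "elongated":
        aspect = rng.uniform(1.8, 2.6)
    else:
        aspect = rng.uniform(1.0, 1.25)
    # area = pi * rx * ry, rx = aspect * ry
    ry = np.sqrt(area / (np.pi * aspect))
    rx = aspect * ry
    angle = rng.uniform(0, np.pi)
    rmax = max(rx, ry) * (1.35 if spec.organ_shape == "irregular" else 1.05)
    if spec.organ_shape == "near_top":
        cy = rmax + rng.uniform(0, 0.05 * side)
    else:
        cy = rng.uniform(rmax, side - rmax)
    cx = rng.uniform(rmax, side - rmax)
    amp = 0.35 if spec.organ_shape == "irregular" else 0.0
    organ = _ellipse_mask(side, cy, cx, ry, rx, angle, amp, rng)
    bone = np.zeros((side, side), dtype=bool)
    if spec.organ_shape == "near_bone":
        # bone crescent: annular arc hugging (and clipping) one side of the organ
        yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
        phi0 = rng.uniform(0, 2 * np.pi)
        r_in = 0.85 * max(rx, ry)
        r_out = r_in + max(2.0, 0.22 * max(rx, ry))
        r = np.hypot(yy - cy, xx - cx)
        ang = np.arctan2(yy - cy, xx - cx)
        dphi = np.angle(np.exp(1j * (ang - phi0)))
        bone = (r >= r_in) & (r <= r_out) & (np.abs(dphi) < np.pi / 3)
        organ &= ~bone
    return organ, bone, (cy, cx, ry, rx)


def _draw_lesions(spec: PhantomSpec, organ: np.ndarray, rng):
    side = spec.side
    if spec.lesion_pattern == "none":
        return np.zeros_like(organ)
    interior = binary_erosion(organ, iterations=max(2, side // 112))
    if not interior.any():
        raise SpecError("organ too small to host a lesion")
    r_eff = np.sqrt(organ.sum() / np.pi)
    pattern = spec.lesion_pattern
    if pattern == "single_large":
        blobs = [(rng.uniform(0.40, 0.55) * r_eff, 0.0)]
    elif pattern == "multi_large":
        n = rng.integers(2, 4)
        blobs = [(rng.uniform(0.28, 0.40) * r_eff, 0.0) for _ in range(n)]
    elif pattern == "small":
        lo, hi = spec.lesion_count_range
        n = rng.integers(lo, hi + 1)
        blobs = [(max(rng.uniform(0.08, 0.15) * r_eff, 1.5), 0.0) for _ in range(n)]
    else:  # irregular
        blobs = [(rng.uniform(0.35, 0.5) * r_eff, 0.45)]
    ys, xs = np.nonzero(interior)
    lesion = np.zeros_like(organ)
    for radius, amp in blobs:
        j = rng.integers(len(ys))
        cy, cx = float(ys[j]), float(xs[j])
        rr = radius * rng.uniform(0.9, 1.1)
        lesion |= _ellipse_mask(side, cy, cx, rr, rr * rng.uniform(0.85, 1.18),
                                rng.uniform(0, np.pi), amp, rng)
    return lesion & organ  # containment is structural


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator):
    """Render one phantom: returns (CTSlice, organ MaskSlice, lesion MaskSlice).

    The image is body-HU soft tissue with a smooth low-frequency texture,
    the organ filled with urine-HU, lesions at lesion-HU, bone at bone-HU,
    plus white Gaussian HU noise.  Masks are the exact pre-noise geometry.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    side = spec.side
    organ, bone, _ = _draw_organ(spec, rng)
    lesion = _draw_lesions(spec, organ, rng)
    hu = np.full((side, side), spec.body_hu, dtype=np.float64)
    if spec.texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal((side, side)), sigma=side / 16)
        tex *= spec.texture_amplitude / max(tex.std(), 1e-9)
        hu += tex
    hu[organ] = spec.urine_hu
    hu[lesion] = spec.lesion_hu
    hu[bone] = spec.bone_hu
    if spec.noise_sigma > 0:
        hu += rng.normal(0.0, spec.noise_sigma, hu.shape)
    hu = np.clip(np.rint(hu), -2048, 4096).astype(np.int32)
    return (CTSlice(hu), MaskSlice(organ.astype(np.uint8)),
            MaskSlice(lesion.astype(np.uint8)))


def generate_dataset(n: int, template: PhantomSpec | None = None, seed: int = 0,
                     shape_weights: dict | None = None,
                     lesion_weights: dict | None = None,
                     window=DEFAULT_WINDOW, out_dir=None):
    """Generate n phantoms with shapes/patterns drawn from mixture weights.

    Returns a list of (organ SamplePair, lesion SamplePair) with windowed
    images.  Lesion-task sampling never draws the 'none' pattern unless it is
    explicitly weighted, so every lesion pair has foreground.  If `out_dir`
    is given, organ and lesion corpora are written as PNG pairs with
    manifests compatible with :mod:`rdaunet.ct_io`.
    """
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    shapes, sw = _weights(shape_weights, ORGAN_SHAPES)
    patterns, lw = _weights(lesion_weights,
                            ("single_large", "multi_large", "small", "irregular"))
    out = []
    for i in range(n):
        shape = shapes[rng.choice(len(shapes), p=sw)]
        pattern = patterns[rng.choice(len(patterns), p=lw)]
        spec = PhantomSpec(**{**template.__dict__,
                              "organ_shape": shape, "lesion_pattern": pattern})
        ct, organ, lesion = generate_phantom(spec, rng)
        img = apply_hu_window(ct, window)
        sid = f"phantom{i:05d}"
        out.append((SamplePair(img, organ, sid), SamplePair(img, lesion, sid)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        save_pairs([p for p, _ in out], out_dir / "organ")
        save_pairs([p for _, p in out], out_dir / "lesion")
    return out


def _weights(weights, default_keys):
    if weights is None:
        keys = list(default_keys)
        w = np.full(len(keys), 1.0 / len(keys))
        return keys, w
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=np.float64)
    if (w < 0).any() or w.sum() <= 0:
        raise ParameterError("mixture weights must be non-negative and sum > 0")
    return keys, w / w.sum()
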