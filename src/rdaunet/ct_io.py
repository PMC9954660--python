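"""CT slice and mask I/O, Hounsfield windowing, resizing and dataset splits.

Conventions
-----------
* HU-valued pixels are signed integers in [-2048, 4096].
* 16-bit PNG storage of HU uses a fixed offset: stored = HU + 1024, so the
  full soft-tissue/bone range fits an unsigned 16-bit channel losslessly.
* Masks are 8-bit PNGs with {0, 255} mapped to {0, 1}.
* Windowing maps [hu_low, hu_high] affinely onto [0, 1] with clamping; the
  default window is the abdominal soft-tissue display window
  (level 40 / width 400, i.e. -160..240 HU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .errors import FormatError, ContentError, PairingError, ParameterError

__all__ = [
    "HU_MIN", "HU_MAX", "PNG_HU_OFFSET", "DEFAULT_WINDOW",
    "CTSlice", "WindowSpec", "MaskSlice", "SamplePair", "DatasetSplit",
    "OverlayReport", "load_slice", "apply_hu_window", "resize_pair",
    "overlay_check", "split_dataset", "write_slice_png", "write_mask_png",
    "load_mask", "save_pairs", "load_pairs",
]

HU_MIN, HU_MAX = -2048, 4096
PNG_HU_OFFSET = 1024


@dataclass
class CTSlice:
    """One 2D CT slice of signed HU-valued pixels."""

    pixels: np.ndarray
    slice_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ContentError("CTSlice requires a non-empty 2D pixel array")
        if self.pixels.min() < HU_MIN or self.pixels.max() > HU_MAX:
            raise ContentError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{self.pixels.min()}, {self.pixels.max()}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """An HU display window [hu_low, hu_high]."""

    hu_low: float
    hu_high: float

    def __post_init__(self):
        if not self.hu_low < self.hu_high:
            raise ParameterError(
                f"degenerate window: low={self.hu_low} >= high={self.hu_high}")


DEFAULT_WINDOW = WindowSpec(-160, 240)


@dataclass
class MaskSlice:
    """A binary foreground mask aligned with a CT slice."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.size == 0:
            raise ContentError("MaskSlice requires a non-empty 2D array")
        vals = np.unique(p)
        if not np.isin(vals, (0, 1)).all():
            raise ContentError(f"mask values must be 0/1, got {vals[:10]}")
        self.pixels = p.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SamplePair:
    """A windowed image in [0,1] aligned with its binary mask."""

    image: np.ndarray
    mask: MaskSlice
    slice_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if not isinstance(self.mask, MaskSlice):
            self.mask = MaskSlice(self.mask)
        if self.image.shape != self.mask.pixels.shape:
            raise PairingError(
                f"image {self.image.shape} and mask {self.mask.pixels.shape} differ")


@dataclass
class DatasetSplit:
    train: list
    val: list
    ratio: float
    seed: int


# ----------------------------------------------------------------- loading

def load_slice(path, format: str = "auto", png_offset: int = PNG_HU_OFFSET) -> CTSlice:
    """Read a CT slice from DICOM or 16-bit grayscale PNG into HU values.

    DICOM rescale slope/intercept are applied; PNG stored values are
    interpreted as HU + `png_offset`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        format = "dicom" if path.suffix.lower() in (".dcm", ".dicom") else "png16"
    if format == "dicom":
        return _load_dicom(path)
    if format == "png16":
        return _load_png16(path, png_offset)
    raise ParameterError(f"unknown format {format!r}")


def _load_dicom(path: Path) -> CTSlice:
    import pydicom
    from pydicom.errors import InvalidDicomError

    try:
        ds = pydicom.dcmread(str(path))
        raw = ds.pixel_array
    except (InvalidDicomError, Exception) as exc:  # pydicom raises broadly
        if isinstance(exc, (KeyboardInterrupt, SystemExit)):
            raise
        raise FormatError(f"cannot read DICOM {path}: {exc}") from exc
    if raw.ndim != 2:
        raise ContentError(f"expected single-frame grayscale DICOM, got shape {raw.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = np.rint(raw.astype(np.float64) * slope + intercept).astype(np.int32)
    return CTSlice(hu, slice_id=path.stem)


def _load_png16(path: Path, offset: int) -> CTSlice:
    try:
        img = Image.open(path)
        img.load()
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot read PNG {path}: {exc}") from exc
    if img.mode not in ("I", "I;16", "L"):
        raise ContentError(f"expected grayscale PNG, got mode {img.mode!r}")
    arr = np.asarray(img, dtype=np.int32)
    return CTSlice(arr - offset, slice_id=path.stem)


def write_slice_png(ct: CTSlice, path, png_offset: int = PNG_HU_OFFSET) -> None:
    """Write HU pixels as 16-bit PNG (stored = HU + offset)."""
    stored = (ct.pixels.astype(np.int32) + png_offset)
    if stored.min() < 0 or stored.max() > 65535:
        raise ContentError("HU values do not fit 16-bit storage with this offset")
    Image.fromarray(stored.astype(np.uint16)).save(path)


def load_mask(path) -> MaskSlice:
    """Read an 8-bit mask PNG; any nonzero value counts as foreground."""
    try:
        img = Image.open(path)
        img.load()
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    arr = np.asarray(img.convert("L"))
    return MaskSlice((arr > 127).astype(np.uint8))


def write_mask_png(mask: MaskSlice, path) -> None:
    Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(path)


# ------------------------------------------------------------- windowing

def apply_hu_window(ct: CTSlice, window: WindowSpec = DEFAULT_WINDOW) -> np.ndarray:
    """Affinely map [hu_low, hu_high] to [0,1], clamping outside values."""
    lo, hi = window.hu_low, window.hu_high
    out = (ct.pixels.astype(np.float64) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def resize_pair(pair: SamplePair, side: int = 224) -> SamplePair:
    """Resize image (bilinear) and mask (nearest-neighbour) to side × side."""
    if side <= 0:
        raise ParameterError(f"side must be positive, got {side}")
    if pair.image.shape == (side, side):
        return SamplePair(pair.image.copy(), MaskSlice(pair.mask.pixels.copy()),
                          pair.slice_id)
    img = _sk_resize(pair.image, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(pair.mask.pixels, (side, side), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return SamplePair(np.clip(img, 0.0, 1.0), MaskSlice(msk.astype(np.uint8)),
                      pair.slice_id)


# ------------------------------------------------------------ QC overlay

@dataclass
class OverlayReport:
    """Visual and numeric check that an image/mask pair correspond."""

    overlay: np.ndarray            # (H, W, 3) RGB in [0,1], contour in red
    coverage: float                # fraction of mask foreground above threshold
    threshold: float
    empty_mask: bool


def overlay_check(pair: SamplePair, intensity_threshold: float = 0.1) -> OverlayReport:
    """Render the mask contour over the image and report how much of the
    mask's foreground carries windowed intensity above `intensity_threshold`.

    A low coverage means the annotation sits on air/out-of-window pixels and
    the pairing deserves a second look.
    """
    from scipy.ndimage import binary_erosion

    img = pair.image
    m = pair.mask.pixels.astype(bool)
    if img.shape != m.shape:
        raise PairingError(f"image {img.shape} vs mask {m.shape}")
    contour = m & ~binary_erosion(m)
    overlay = np.repeat(img[:, :, None], 3, axis=2)
    overlay[contour] = (1.0, 0.0, 0.0)
    n_fg = int(m.sum())
    if n_fg == 0:
        warnings.warn("overlay_check: mask has no foreground; coverage undefined",
                      stacklevel=2)
        return OverlayReport(overlay, 0.0, intensity_threshold, True)
    coverage = float((img[m] > intensity_threshold).mean())
    return OverlayReport(overlay, coverage, intensity_threshold, False)


# ---------------------------------------------------------------- splits

def split_dataset(pairs, ratio: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Shuffle with a seeded RNG and split: first floor(ratio·n) to train."""
    if not 0.0 < ratio < 1.0:
        raise ParameterError(f"split ratio must be in (0,1), got {ratio}")
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ParameterError("need at least 2 pairs to split")
    order = np.random.default_rng(seed).permutation(len(pairs))
    n_train = int(np.floor(ratio * len(pairs)))
    train = [pairs[i] for i in order[:n_train]]
    val = [pairs[i] for i in order[n_train:]]
    return DatasetSplit(train, val, ratio, seed)


# -------------------------------------------------------------- manifests

def save_pairs(pairs, out_dir, split_labels=None) -> Path:
    """Write normalized pairs as PNG files plus a manifest CSV.

    Images are stored as 16-bit PNGs scaled by 65535 (they are already
    windowed to [0,1]); masks as 8-bit {0,255} PNGs.  Returns the manifest
    path.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(pairs):
        sid = p.slice_id or f"slice{i:05d}"
        ipath = out_dir / "images" / f"{sid}.png"
        mpath = out_dir / "masks" / f"{sid}.png"
        Image.fromarray(np.rint(p.image * 65535).astype(np.uint16)).save(ipath)
        write_mask_png(p.mask, mpath)
        rows.append(dict(slice_id=sid, image_path=str(ipath), mask_path=str(mpath),
                         split=split_labels[i] if split_labels else ""))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_pairs(manifest_csv, split: str | None = None):
    """Read pairs back from a manifest written by :func:`save_pairs`."""
    df = pd.read_csv(manifest_csv, keep_default_na=False)
    if split:
        df = df[df["split"] == split]
    pairs = []
    for row in df.itertuples():
        img = np.asarray(Image.open(row.image_path), dtype=np.float64) / 65535.0
        mask = load_mask(row.mask_path)
        pairs.append(SamplePair(img, mask, str(row.slice_id)))
    return pairs
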