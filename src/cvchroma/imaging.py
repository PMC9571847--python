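"""Image I/O, region-of-interest resolution, and RGB histogram extraction.

Coordinates are 0-based (row, column); rectangles are half-open
[r0, r1) × [c0, c1).  Histograms are 3 × 256 per-channel pixel counts over
the ROI — the intermediate representation of the photographic workflow, from
which the mean specimen colour is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ImageRecord",
    "ROISpec",
    "RGBHistogram",
    "load_image",
    "resolve_roi",
    "compute_histogram",
    "histogram_mean",
]


@dataclass(frozen=True)
class ImageRecord:
    """An 8-bit RGB raster plus provenance."""

    pixels: np.ndarray  # H×W×3 uint8
    source_path: str = "<memory>"
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an H×W×3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ROISpec:
    """Region of interest: rectangle, polygon, or explicit boolean mask.

    * ``rectangle`` — coordinates (r0, r1, c0, c1), half-open in both axes.
    * ``polygon`` — sequence of (row, col) vertices; a pixel belongs to the
      ROI when its center lies inside the polygon (even-odd fill rule).
    * ``mask`` — boolean H×W array matching the image.
    """

    kind: str
    coordinates: tuple = ()
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "polygon", "mask"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "rectangle":
            if len(self.coordinates) != 4:
                raise ValueError("rectangle ROI needs (r0, r1, c0, c1)")
            r0, r1, c0, c1 = self.coordinates
            if not (r0 < r1 and c0 < c1):
                raise ValueError(
                    f"rectangle requires r0 < r1 and c0 < c1; got "
                    f"[{r0}, {r1}) × [{c0}, {c1})"
                )
        elif self.kind == "polygon" and len(self.coordinates) < 3:
            raise ValueError("polygon ROI needs at least three vertices")
        elif self.kind == "mask" and self.mask is None:
            raise ValueError("mask ROI needs a boolean mask array")

    @staticmethod
    def rectangle(r0: int, r1: int, c0: int, c1: int) -> "ROISpec":
        return ROISpec(kind="rectangle", coordinates=(r0, r1, c0, c1))

    @staticmethod
    def centered_fraction(shape: tuple[int, int], fraction: float = 0.6) -> "ROISpec":
        """Centered rectangle covering ``fraction`` of each image dimension.

        The default ROI when a sample sheet gives no explicit region.
        """
        if not (0 < fraction <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        h, w = shape
        rh = max(1, round(h * fraction))
        rw = max(1, round(w * fraction))
        r0 = (h - rh) // 2
        c0 = (w - rw) // 2
        return ROISpec.rectangle(r0, r0 + rh, c0, c0 + rw)


@dataclass(frozen=True)
class RGBHistogram:
    """Per-channel 256-bin pixel-count histograms over an ROI."""

    counts: np.ndarray  # 3×256 int64
    n_pixels: int

    def __post_init__(self) -> None:
        if self.counts.shape != (3, 256):
            raise ValueError(f"expected a 3×256 count array, got {self.counts.shape}")
        if self.n_pixels < 1:
            raise ValueError("histogram requires at least one pixel")
        if np.any(self.counts < 0):
            raise ValueError("negative histogram count")
        sums = self.counts.sum(axis=1)
        if not np.all(sums == self.n_pixels):
            raise ValueError(
                f"channel count sums {sums.tolist()} != n_pixels {self.n_pixels}"
            )


def load_image(path, allow_grayscale: bool = False) -> ImageRecord:
    """Read a PNG/TIFF/JPEG photograph as an 8-bit RGB :class:`ImageRecord`.

    16-bit inputs are rescaled to 8-bit as value·255/65535 with
    round-half-to-even.  An alpha channel is dropped with a warning; JPEG
    inputs trigger a warning that chroma subsampling perturbs chromaticity.
    Grayscale images are rejected unless ``allow_grayscale`` replicates the
    single channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            fmt = im.format
            im.load()
            arr = np.asarray(im)
    except Exception as exc:  # Pillow raises several decode error types
        raise ValueError(f"cannot decode {path} as a raster image: {exc}") from exc

    if fmt == "JPEG":
        warnings.warn(
            f"{path}: JPEG chroma subsampling perturbs measured chromaticity; "
            "prefer lossless formats for quantitative work",
            stacklevel=2,
        )

    if arr.ndim == 2:
        if not allow_grayscale:
            raise ValueError(
                f"{path} is grayscale; pass allow_grayscale=True to replicate "
                "the channel into RGB"
            )
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{path}: unsupported raster layout with shape {arr.shape}")
    if arr.shape[2] == 4:
        warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 or 4 channels, got {arr.shape[2]}")

    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(float) * 255.0 / 65535.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype}")

    return ImageRecord(pixels=arr, source_path=str(path))


def resolve_roi(image: ImageRecord, roi: ROISpec) -> np.ndarray:
    """Resolve an ROI specification to a boolean H×W mask with ≥ 1 true pixel."""
    h, w = image.shape
    if roi.kind == "rectangle":
        r0, r1, c0, c1 = (int(v) for v in roi.coordinates)
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        if r0c >= r1c or c0c >= c1c:
            raise ValueError(
                f"rectangle [{r0}, {r1}) × [{c0}, {c1}) does not intersect the "
                f"{h}×{w} image"
            )
        mask = np.zeros((h, w), dtype=bool)
        mask[r0c:r1c, c0c:c1c] = True
    elif roi.kind == "polygon":
        from matplotlib.path import Path as MplPath

        verts = [(c, r) for r, c in roi.coordinates]  # (x=col, y=row)
        rr, cc = np.mgrid[0:h, 0:w]
        pts = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
        mask = MplPath(verts).contains_points(pts).reshape(h, w)
        if not mask.any():
            raise ValueError("polygon ROI contains no pixel centers")
    else:  # mask
        mask = np.asarray(roi.mask, dtype=bool)
        if mask.shape != (h, w):
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {(h, w)}"
            )
        if not mask.any():
            raise ValueError("mask ROI selects no pixels")
    return mask


def compute_histogram(image: ImageRecord, mask: np.ndarray) -> RGBHistogram:
    """Per-channel 256-bin histograms of the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    selected = image.pixels[mask]  # N×3
    n = selected.shape[0]
    if n == 0:
        raise ValueError("empty mask: no pixels to histogram")
    counts = np.stack(
        [np.bincount(selected[:, c], minlength=256) for c in range(3)]
    ).astype(np.int64)
    return RGBHistogram(counts=counts, n_pixels=n)


def histogram_mean(hist: RGBHistogram) -> np.ndarray:
    """Mean encoded RGB implied by the histogram, each channel in [0, 1].

    The count-weighted mean of bin values divided by 255 — the reduction
    from the per-channel histograms to the single colour fed into the
    XYZ conversion.
    """
    bins = np.arange(256, dtype=float)
    means = (hist.counts * bins).sum(axis=1) / hist.n_pixels
    return means / 255.0
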