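"""Slide raster access.

A :class:`SlideRaster` is the minimal pixel-access contract the tiling and
classification stages need: dimensions plus a ``read_region`` that always
returns exactly the requested number of pixels, padding with white beyond
the slide boundary (biopsy tissue sits on a white background, so padding
with white is indistinguishable from empty glass).

Two concrete rasters are provided: an in-memory array wrapper used by the
synthetic generator and tests, and a file-backed reader for PNG and
(tiled) TIFF images.  Whole-slide formats that need a pyramid reader
(e.g. MIRAX) are not supported here; any object satisfying the protocol —
for example a wrapper around an OpenSlide handle reading level 0 — can be
passed wherever a ``SlideRaster`` is accepted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

WHITE = 255


class SlideReadError(RuntimeError):
    """Raised when a slide file cannot be opened or decoded (scan failure)."""


@runtime_checkable
class SlideRaster(Protocol):
    """Pixel accessor for one slide image.

    Coordinates are 0-based with the origin at the top-left corner.
    """

    slide_id: str
    width_px: int
    height_px: int

    def read_region(self, x0: int, y0: int, w: int, h: int) -> np.ndarray:
        """Return an ``(h, w, 3)`` uint8 RGB array, white-padded at edges."""
        ...


def _padded_read(pixels: np.ndarray, x0: int, y0: int, w: int, h: int) -> np.ndarray:
    if w <= 0 or h <= 0:
        raise ValueError(f"requested region {w}x{h} is empty")
    out = np.full((h, w, 3), WHITE, dtype=np.uint8)
    H, W = pixels.shape[:2]
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + w, W), min(y0 + h, H)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = pixels[sy0:sy1, sx0:sx1]
    return out


class ArraySlide:
    """In-memory RGB slide."""

    format_tag = "array"

    def __init__(self, pixels: np.ndarray, slide_id: str = "slide"):
        pixels = np.asarray(pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        self.pixels = pixels.astype(np.uint8, copy=False)
        self.slide_id = slide_id
        self.height_px, self.width_px = pixels.shape[:2]

    def read_region(self, x0: int, y0: int, w: int, h: int) -> np.ndarray:
        return _padded_read(self.pixels, x0, y0, w, h)


class ImageSlide(ArraySlide):
    """Slide backed by a PNG or TIFF file, decoded fully on open.

    Suitable for the desk-scale images this package targets; gigapixel
    pyramidal formats should be wrapped behind their own ``SlideRaster``.
    """

    def __init__(self, path: str | Path, slide_id: str | None = None):
        path = Path(path)
        try:
            if path.suffix.lower() in {".tif", ".tiff"}:
                import tifffile

                pixels = tifffile.imread(path)
            else:
                from PIL import Image

                with Image.open(path) as im:
                    pixels = np.asarray(im.convert("RGB"))
        except Exception as exc:  # decode errors of any flavour = scan failure
            raise SlideReadError(f"cannot read slide {path}: {exc}") from exc
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        if pixels.shape[-1] == 4:
            pixels = pixels[..., :3]
        super().__init__(pixels, slide_id or path.stem)
        self.path = path
        self.format_tag = path.suffix.lstrip(".").lower()


def open_slide(path: str | Path, slide_id: str | None = None) -> ImageSlide:
    """Open a PNG/TIFF slide, raising :class:`SlideReadError` on failure."""
    path = Path(path)
    if not path.exists():
        raise SlideReadError(f"slide file not found: {path}")
    return ImageSlide(path, slide_id)


def write_slide(pixels: np.ndarray, path: str | Path) -> None:
    """Write an RGB array as PNG or tiled TIFF, by extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, pixels, tile=(256, 256))
    else:
        from PIL import Image

        Image.fromarray(pixels).save(path)
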