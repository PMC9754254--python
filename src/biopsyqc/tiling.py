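"""Patch tiling: slide -> indexed 256x256 patches with a location database.

A slide is partitioned into a regular grid of non-overlapping, half-open
``[x0, x0+size) x [y0, y0+size)`` tiles; edge tiles are padded with white
rather than dropped so lesions at the slide border stay visible to the
classifier.  Every tile gets a :class:`PatchRecord` holding the bijection
``patch_index <-> (grid_col, grid_row) <-> (x0, y0)``; the per-slide table
of records is the :class:`PatchDB`, which also stores patch-level and
slide-level classification results once prediction has run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .slide_io import SlideRaster

DEFAULT_PATCH_SIZE = 256

#: default luminance cut-off (0-255) below which a pixel counts as tissue
DEFAULT_LUMA_THRESHOLD = 230.0
#: minimum fraction of sub-threshold pixels for a patch to count as tissue
DEFAULT_MIN_TISSUE_FRACTION = 0.05


@dataclass(frozen=True)
class TissueParams:
    """Parameters of the luminance-based tissue detector.

    ``enabled=False`` switches background filtering off entirely: every
    patch is flagged as tissue and will be classified.
    """

    luma_threshold: float = DEFAULT_LUMA_THRESHOLD
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION
    enabled: bool = True


@dataclass(frozen=True)
class PatchRecord:
    slide_id: str
    patch_index: int
    grid_col: int
    grid_row: int
    x0: int
    y0: int
    size: int
    tissue_flag: bool


def patch_origin(grid_col: int, grid_row: int, size: int = DEFAULT_PATCH_SIZE) -> tuple[int, int]:
    """Pixel origin (x0, y0) of the tile at (grid_col, grid_row)."""
    if grid_col < 0 or grid_row < 0:
        raise ValueError("grid coordinates must be non-negative")
    return grid_col * size, grid_row * size


def index_of(x: int, y: int, size: int, n_cols: int) -> int:
    """Patch index of the tile containing pixel (x, y).

    Inverse of :func:`patch_origin` for any pixel inside the tile.
    """
    if x < 0 or y < 0:
        raise ValueError("pixel coordinates must be non-negative")
    col, row = x // size, y // size
    if col >= n_cols:
        raise ValueError(f"x={x} falls outside a grid with {n_cols} columns")
    return row * n_cols + col


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec.601 luma of an RGB uint8 array."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def is_tissue(patch_pixels: np.ndarray, params: TissueParams | None = None) -> bool:
    """True iff enough pixels are darker than the luminance threshold."""
    params = params or TissueParams()
    if not params.enabled:
        return True
    frac = float(np.mean(luminance(patch_pixels) < params.luma_threshold))
    return frac > params.min_tissue_fraction


class PatchDB:
    """Per-slide table of patch records plus classification results.

    Backed by a :class:`pandas.DataFrame`; persisted as CSV.  After
    prediction, the columns ``p_M``/``p_D``/``p_N``/``pred_class`` hold the
    patch-level classification, and :attr:`slide_class` the slide-level
    result, so the database carries all three layers of information:
    patch identity/location, patch classification, slide classification.
    """

    PRED_COLS = ("p_M", "p_D", "p_N", "pred_class")

    def __init__(self, slide_id: str, patch_size: int, n_cols: int, n_rows: int,
                 records: Sequence[PatchRecord]):
        self.slide_id = slide_id
        self.patch_size = patch_size
        self.n_cols = n_cols
        self.n_rows = n_rows
        self.df = pd.DataFrame([r.__dict__ for r in records]).sort_values(
            "patch_index", ignore_index=True
        )
        self.slide_class: str | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[PatchRecord]:
        cols = ["slide_id", "patch_index", "grid_col", "grid_row", "x0", "y0",
                "size", "tissue_flag"]
        return [PatchRecord(**{c: row[c] for c in cols})
                for row in self.df[cols].to_dict("records")]

    def tissue_indices(self) -> np.ndarray:
        return self.df.loc[self.df.tissue_flag, "patch_index"].to_numpy()

    def location_of(self, patch_index: int) -> tuple[int, int]:
        row = self.df.loc[self.df.patch_index == patch_index]
        if row.empty:
            raise KeyError(f"patch_index {patch_index} not in DB for {self.slide_id}")
        return int(row.iloc[0].grid_col), int(row.iloc[0].grid_row)

    def read_patch(self, raster: SlideRaster, patch_index: int) -> np.ndarray:
        col, row = self.location_of(patch_index)
        x0, y0 = patch_origin(col, row, self.patch_size)
        return raster.read_region(x0, y0, self.patch_size, self.patch_size)

    def store_predictions(self, predictions: Iterable) -> None:
        """Attach :class:`~biopsyqc.classify.PatchPrediction` results."""
        for c in self.PRED_COLS:
            if c not in self.df.columns:
                self.df[c] = np.nan if c != "pred_class" else None
        idx = self.df.set_index("patch_index").index
        for p in predictions:
            loc = idx.get_loc(p.patch_index)
            self.df.loc[loc, ["p_M", "p_D", "p_N"]] = list(p.probs)
            self.df.loc[loc, "pred_class"] = p.argmax_class

    # -- persistence ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = self.df.copy()
        df.attrs = {}
        df.insert(0, "slide_class", self.slide_class)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PatchDB":
        df = pd.read_csv(path)
        slide_class = df.pop("slide_class").iloc[0]
        size = int(df["size"].iloc[0])
        n_cols = int(df.grid_col.max()) + 1
        n_rows = int(df.grid_row.max()) + 1
        db = cls.__new__(cls)
        db.slide_id = str(df.slide_id.iloc[0])
        db.patch_size = size
        db.n_cols = n_cols
        db.n_rows = n_rows
        db.df = df.sort_values("patch_index", ignore_index=True)
        db.slide_class = None if pd.isna(slide_class) else str(slide_class)
        return db


def tile_slide(raster: SlideRaster, patch_size: int = DEFAULT_PATCH_SIZE,
               tissue_params: TissueParams | None = None) -> PatchDB:
    """Tile a slide into a complete grid of patches with tissue flags.

    Grid dimensions are ``ceil(width/size) x ceil(height/size)``; edge
    tiles are white-padded by the raster's ``read_region`` contract.
    """
    tissue_params = tissue_params or TissueParams()
    n_cols = math.ceil(raster.width_px / patch_size)
    n_rows = math.ceil(raster.height_px / patch_size)
    records = []
    for row in range(n_rows):
        for col in range(n_cols):
            x0, y0 = patch_origin(col, row, patch_size)
            pixels = raster.read_region(x0, y0, patch_size, patch_size)
            records.append(PatchRecord(
                slide_id=raster.slide_id,
                patch_index=row * n_cols + col,
                grid_col=col, grid_row=row, x0=x0, y0=y0, size=patch_size,
                tissue_flag=is_tissue(pixels, tissue_params),
            ))
    return PatchDB(raster.slide_id, patch_size, n_cols, n_rows, records)


def extract_training_patches(
    raster: SlideRaster,
    annotations,  # iterable of shapely polygons, or None for class N
    class_label: str,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_overlap: float = 0.25,
    tissue_params: TissueParams | None = None,
) -> tuple[np.ndarray, list[str], list[PatchRecord]]:
    """Extract labeled training patches from one annotated slide.

    Class N slides carry no annotations: every tissue patch is an N
    example.  For M/D slides only patches whose area overlaps the lesion
    annotation by at least ``min_overlap`` (default 25%) are kept, with
    the slide's class as label; everything outside the annotation is
    discarded rather than used as N (annotations are not exhaustive).
    """
    if class_label not in {"M", "D", "N"}:
        raise ValueError(f"class_label must be M, D or N, got {class_label!r}")
    db = tile_slide(raster, patch_size, tissue_params)

    if class_label == "N":
        keep = [r for r in db.records if r.tissue_flag]
    else:
        from shapely.geometry import box
        from shapely.ops import unary_union

        polys = list(annotations or [])
        if not polys:
            raise ValueError(f"class {class_label} slide requires lesion annotations")
        lesion = unary_union(polys)
        min_area = min_overlap * patch_size * patch_size
        keep = []
        for r in db.records:
            tile = box(r.x0, r.y0, r.x0 + patch_size, r.y0 + patch_size)
            if lesion.intersection(tile).area >= min_area:
                keep.append(r)

    patches = np.stack(
        [raster.read_region(r.x0, r.y0, patch_size, patch_size) for r in keep]
    ) if keep else np.empty((0, patch_size, patch_size, 3), dtype=np.uint8)
    return patches, [class_label] * len(keep), keep
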