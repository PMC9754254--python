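"""Deterministic synthetic "WSI-like" slide generator.

Emulates the statistical structure the QC pipeline assumes about
gastrointestinal endoscopic biopsy slides, at desk scale:

* a white glass background carrying a few elliptical tissue fragments;
* three procedurally textured lesion classes — N (smooth pink mucosa with
  gland/ring motifs and sparse nuclei), D (denser, elongated, dark-blue
  nuclei on a slightly darker stroma), M (crowded irregular dark blobs of
  variable size on a dense stroma);
* routine slide/scan artifacts injected at configurable rates — locally
  blurred (out-of-focus) regions, dark fold streaks, stain shifts, and
  air-bubble discs.  Artifacts perturb pixels only; ground-truth labels
  are derived from the planted geometry, never from artifact damage,
  mirroring a workflow that trains through artifacts instead of
  re-preparing slides;
* free-text diagnosis records whose keyword class matches (or, for the
  injected error styles, deliberately mismatches) the slide content;
* multi-slide specimens: serial sections cut from one paraffin block.

All randomness flows from a single integer seed: identical spec + seed
give byte-identical pixels, ground truth and text.

Patch-level ground truth follows a 25%-overlap rule: a grid tile is
labeled with the lesion class when at least a quarter of its area lies
inside a lesion polygon, N when it holds tissue, and background
otherwise.  The rule is a package choice (annotation-boundary labeling
has no single field convention) and is exposed as a parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Point, box, mapping, shape
from shapely.ops import unary_union

from .dx_rules import DxRecord, classify_dx
from .slide_io import ArraySlide, write_slide
from .tiling import DEFAULT_PATCH_SIZE

LESION_OVERLAP_RULE = 0.25  # fraction of tile area inside lesion polygon
TISSUE_TILE_FRACTION = 0.05  # min tissue-area fraction for a tile to be tissue


@dataclass(frozen=True)
class ArtifactParams:
    """Per-tile rates (expected instances per grid tile) of each artifact."""

    blur_rate: float = 0.05
    fold_rate: float = 0.05
    stain_shift_rate: float = 0.05
    bubble_rate: float = 0.05

    def scaled(self, factor: float) -> "ArtifactParams":
        return ArtifactParams(*(getattr(self, f) * factor for f in
                                ("blur_rate", "fold_rate", "stain_shift_rate",
                                 "bubble_rate")))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic slide."""

    seed: int
    width_px: int = 1280
    height_px: int = 1024
    organ: str = "gastric"
    slide_class: str = "N"
    lesion_fraction: float = 0.5
    n_tissue_blobs: int = 3
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)
    patch_size: int = DEFAULT_PATCH_SIZE

    def validate(self) -> None:
        if self.width_px < self.patch_size or self.height_px < self.patch_size:
            raise ValueError(
                f"slide dimensions {self.width_px}x{self.height_px} are smaller "
                f"than one {self.patch_size}px patch")
        if self.slide_class not in {"M", "D", "N"}:
            raise ValueError(f"slide_class must be M, D or N, got {self.slide_class!r}")
        if self.organ not in {"gastric", "colorectal"}:
            raise ValueError(f"organ must be gastric or colorectal, got {self.organ!r}")
        if self.slide_class in {"M", "D"} and not 0 < self.lesion_fraction <= 1:
            raise ValueError("lesion_fraction must be in (0, 1] for M/D slides")


@dataclass
class GroundTruth:
    """Planted truth for one synthetic slide."""

    slide_class: str
    organ: str
    label_grid: np.ndarray  # (n_rows, n_cols) array of {"M","D","N","background"}
    lesion_polygons: list  # shapely polygons, all inside tissue
    tissue_geom: object  # shapely geometry of the tissue fragments
    heading_text: str = ""
    diagnosis_text: str = ""
    dx_class: str = ""
    patch_size: int = DEFAULT_PATCH_SIZE
    width_px: int = 0
    height_px: int = 0
    seed: int = 0

    def tissue_patch_count(self) -> int:
        return int(np.sum(self.label_grid != "background"))

    def lesion_patch_fraction(self) -> float:
        n_tissue = self.tissue_patch_count()
        if n_tissue == 0:
            return 0.0
        n_lesion = int(np.sum(np.isin(self.label_grid, ["M", "D"])))
        return n_lesion / n_tissue

    # -- persistence: JSON + GeoJSON polygons ---------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "slide_class": self.slide_class,
            "organ": self.organ,
            "label_grid": self.label_grid.tolist(),
            "lesion_polygons": [mapping(p) for p in self.lesion_polygons],
            "tissue_geom": mapping(self.tissue_geom),
            "heading_text": self.heading_text,
            "diagnosis_text": self.diagnosis_text,
            "dx_class": self.dx_class,
            "patch_size": self.patch_size,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            slide_class=data["slide_class"], organ=data["organ"],
            label_grid=np.array(data["label_grid"], dtype=object),
            lesion_polygons=[shape(p) for p in data["lesion_polygons"]],
            tissue_geom=shape(data["tissue_geom"]),
            heading_text=data["heading_text"],
            diagnosis_text=data["diagnosis_text"],
            dx_class=data["dx_class"], patch_size=data["patch_size"],
            width_px=data["width_px"], height_px=data["height_px"],
            seed=data["seed"],
        )


# ---------------------------------------------------------------------
# texture recipes
# ---------------------------------------------------------------------

_TEXTURE = {
    # base stroma color, nucleus color, nuclei per 256x256, nucleus radii,
    # elongation (axis ratio), gland rings per 256x256
    "N": dict(base=(242, 205, 215), nucleus=(110, 80, 150), density=40,
              radius=(1.5, 2.5), elong=1.2, glands=4),
    "D": dict(base=(231, 186, 201), nucleus=(60, 50, 120), density=260,
              radius=(2.0, 3.5), elong=3.0, glands=1),
    "M": dict(base=(216, 168, 190), nucleus=(48, 34, 88), density=520,
              radius=(1.5, 5.5), elong=1.6, glands=0),
}


def _draw_ellipses(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                   n: int, color, radius, elong) -> None:
    """Stamp n randomly oriented ellipses (nuclei) inside mask."""
    from skimage.draw import ellipse

    H, W = mask.shape
    ys, xs = np.nonzero(mask)
    if len(ys) == 0 or n <= 0:
        return
    pick = rng.integers(0, len(ys), size=n)
    r_min, r_max = radius
    radii = rng.uniform(r_min, r_max, size=n)
    angles = rng.uniform(0, np.pi, size=n)
    ratios = rng.uniform(1.0, elong, size=n)
    color = np.asarray(color, dtype=np.float64)
    for cy, cx, r, ang, q in zip(ys[pick], xs[pick], radii, angles, ratios):
        rr, cc = ellipse(cy, cx, r * q, r, shape=(H, W), rotation=ang)
        keep = mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        # soft blend so nuclei edges are not aliased hard
        img[rr, cc] = 0.25 * img[rr, cc] + 0.75 * color


def _draw_glands(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 n: int) -> None:
    """Light gland lumens with a darker epithelial rim (N motif)."""
    from skimage.draw import disk

    H, W = mask.shape
    ys, xs = np.nonzero(mask)
    if len(ys) == 0 or n <= 0:
        return
    pick = rng.integers(0, len(ys), size=n)
    for cy, cx in zip(ys[pick], xs[pick]):
        r = rng.uniform(8, 18)
        rr, cc = disk((cy, cx), r + 3, shape=(H, W))
        keep = mask[rr, cc]
        img[rr[keep], cc[keep]] = 0.5 * img[rr[keep], cc[keep]] + 0.5 * np.array(
            [205, 160, 185], dtype=np.float64)
        rr, cc = disk((cy, cx), r, shape=(H, W))
        keep = mask[rr, cc]
        img[rr[keep], cc[keep]] = 0.4 * img[rr[keep], cc[keep]] + 0.6 * np.array(
            [250, 235, 242], dtype=np.float64)


def paint_texture(img: np.ndarray, mask: np.ndarray, cls: str,
                  rng: np.random.Generator) -> None:
    """Paint the class texture on img (float64, in place) inside mask."""
    t = _TEXTURE[cls]
    area = mask.sum()
    if area == 0:
        return
    base = np.asarray(t["base"], dtype=np.float64)
    noise = rng.normal(0, 6, size=(*mask.shape, 3))
    img[mask] = np.clip(base + noise[mask], 0, 255)
    per_patch = DEFAULT_PATCH_SIZE ** 2
    _draw_glands(img, mask, rng, int(round(t["glands"] * area / per_patch)))
    _draw_ellipses(img, mask, rng, int(round(t["density"] * area / per_patch)),
                   t["nucleus"], t["radius"], t["elong"])
    if cls == "M":  # extra high-frequency chromatin-like speckle
        speckle = rng.normal(0, 11, size=(*mask.shape, 3))
        img[mask] = np.clip(img[mask] + speckle[mask], 0, 255)


def render_texture_patch(cls: str, seed: int,
                         patch_size: int = DEFAULT_PATCH_SIZE,
                         lesion_coverage: float = 1.0,
                         tissue_fraction: float = 1.0) -> np.ndarray:
    """Render one standalone tissue patch (for patch training).

    Grid tiles cut from a slide are rarely texture-pure: a lesion-labeled
    tile holds the lesion over only part of its area (anything above the
    25% overlap rule) on otherwise negative mucosa, and tiles at tissue
    edges include white glass.  ``lesion_coverage`` and
    ``tissue_fraction`` reproduce that composition so patches drawn here
    match the distribution the classifier sees on whole slides.
    """
    rng = np.random.default_rng(seed)
    img = np.full((patch_size, patch_size, 3), 255.0)
    yy, xx = np.mgrid[0:patch_size, 0:patch_size]
    if tissue_fraction >= 1.0:
        tissue = np.ones((patch_size, patch_size), dtype=bool)
    else:
        # tissue edge: half-plane at random orientation covering the
        # requested fraction of the patch
        ang = rng.uniform(0, 2 * np.pi)
        proj = np.cos(ang) * xx + np.sin(ang) * yy
        cut = np.quantile(proj, tissue_fraction)
        tissue = proj <= cut
    paint_texture(img, tissue, "N", rng)
    if cls in {"M", "D"} and lesion_coverage > 0:
        target = lesion_coverage * patch_size ** 2
        rad = math.sqrt(target / math.pi)
        cy = rng.uniform(0.3, 0.7) * patch_size
        cx = rng.uniform(0.3, 0.7) * patch_size
        lesion = (((xx - cx) ** 2 + (yy - cy) ** 2) <= rad ** 2) & tissue
        paint_texture(img, lesion, cls, rng)
    return img.astype(np.uint8)


def sample_patches(n_per_class: int, seed: int,
                   patch_size: int = DEFAULT_PATCH_SIZE,
                   min_coverage: float = 0.35,
                   partial_tissue_rate: float = 0.3
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render a balanced, composition-realistic patch set for all classes.

    Lesion patches carry a lesion disc covering U(min_coverage, 1) of the
    patch; a fraction of patches of every class sit at a tissue edge.
    """
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for cls in ("M", "D", "N"):
        for _ in range(n_per_class):
            cov = float(rng.uniform(min_coverage, 1.0))
            tf = (float(rng.uniform(0.4, 1.0))
                  if rng.random() < partial_tissue_rate else 1.0)
            patches.append(render_texture_patch(
                cls, int(rng.integers(2**31 - 1)), patch_size,
                lesion_coverage=cov, tissue_fraction=tf))
            labels.append(cls)
    return np.stack(patches), np.asarray(labels)


# ---------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------

def _inject_artifacts(img: np.ndarray, rng: np.random.Generator,
                      params: ArtifactParams, patch_size: int) -> None:
    from scipy.ndimage import gaussian_filter
    from skimage.draw import disk, line

    H, W = img.shape[:2]
    n_tiles = math.ceil(W / patch_size) * math.ceil(H / patch_size)

    def count(rate: float) -> int:
        return int(rng.binomial(n_tiles, min(rate, 1.0)))

    for _ in range(count(params.blur_rate)):  # out-of-focus region
        s = int(rng.uniform(0.5, 1.2) * patch_size)
        y = int(rng.integers(0, max(H - s, 1)))
        x = int(rng.integers(0, max(W - s, 1)))
        img[y:y + s, x:x + s] = gaussian_filter(
            img[y:y + s, x:x + s], sigma=(3.0, 3.0, 0))

    for _ in range(count(params.fold_rate)):  # dark tissue-fold streak
        y0, x0 = int(rng.integers(0, H)), int(rng.integers(0, W))
        ang = rng.uniform(0, np.pi)
        length = int(rng.uniform(0.8, 2.0) * patch_size)
        y1 = int(np.clip(y0 + length * np.sin(ang), 0, H - 1))
        x1 = int(np.clip(x0 + length * np.cos(ang), 0, W - 1))
        rr, cc = line(y0, x0, y1, x1)
        for dy in range(-2, 3):
            yy = np.clip(rr + dy, 0, H - 1)
            img[yy, cc] = img[yy, cc] * 0.55

    for _ in range(count(params.stain_shift_rate)):  # local stain shift
        s = int(rng.uniform(0.8, 1.5) * patch_size)
        y = int(rng.integers(0, max(H - s, 1)))
        x = int(rng.integers(0, max(W - s, 1)))
        shift = np.array([rng.uniform(5, 18), rng.uniform(-14, -4),
                          rng.uniform(-5, 10)])
        img[y:y + s, x:x + s] = np.clip(img[y:y + s, x:x + s] + shift, 0, 255)

    for _ in range(count(params.bubble_rate)):  # air bubble: pale disc, dark rim
        r = rng.uniform(0.15, 0.4) * patch_size
        cy, cx = int(rng.integers(0, H)), int(rng.integers(0, W))
        rr, cc = disk((cy, cx), r, shape=(H, W))
        img[rr, cc] = 0.65 * img[rr, cc] + 0.35 * 255.0
        rr, cc = disk((cy, cx), r, shape=(H, W))
        inner = disk((cy, cx), max(r - 3, 1), shape=(H, W))
        rim = np.ones(img.shape[:2], dtype=bool)
        rim[...] = False
        rim[rr, cc] = True
        rim[inner[0], inner[1]] = False
        img[rim] = img[rim] * 0.5


# ---------------------------------------------------------------------
# slide assembly
# ---------------------------------------------------------------------

def _ellipse_geom(cx: float, cy: float, rx: float, ry: float):
    return affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=64), rx, ry)


def labels_from_geometry(tissue_geom, lesion_polygons, slide_class: str,
                         width_px: int, height_px: int,
                         patch_size: int = DEFAULT_PATCH_SIZE,
                         min_overlap: float = LESION_OVERLAP_RULE) -> np.ndarray:
    """Recompute the per-tile label grid from planted geometry.

    This is the single source of truth for ground-truth labels; the
    emitted grid in :class:`GroundTruth` is produced by this function, and
    tests re-invoke it to confirm label/polygon consistency.
    """
    n_cols = math.ceil(width_px / patch_size)
    n_rows = math.ceil(height_px / patch_size)
    lesion = unary_union(lesion_polygons) if lesion_polygons else None
    tile_area = patch_size * patch_size
    grid = np.full((n_rows, n_cols), "background", dtype=object)
    for r in range(n_rows):
        for c in range(n_cols):
            tile = box(c * patch_size, r * patch_size,
                       (c + 1) * patch_size, (r + 1) * patch_size)
            if tissue_geom.intersection(tile).area / tile_area <= TISSUE_TILE_FRACTION:
                continue
            if lesion is not None and \
                    lesion.intersection(tile).area >= min_overlap * tile_area:
                grid[r, c] = slide_class
            else:
                grid[r, c] = "N"
    return grid


def generate_slide(spec: SyntheticSpec) -> tuple[ArraySlide, GroundTruth]:
    """Generate one synthetic slide and its ground truth.

    Deterministic: the same spec yields byte-identical pixels and truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    W, H = spec.width_px, spec.height_px
    img = np.full((H, W, 3), 255.0)

    # tissue fragments: random ellipses kept inside the canvas
    blobs = []
    for _ in range(spec.n_tissue_blobs):
        rx = rng.uniform(0.14, 0.26) * W
        ry = rng.uniform(0.14, 0.26) * H
        cx = rng.uniform(rx, W - rx)
        cy = rng.uniform(ry, H - ry)
        blobs.append((cx, cy, rx, ry))
    tissue_geom = unary_union([_ellipse_geom(*b) for b in blobs])

    yy, xx = np.mgrid[0:H, 0:W]
    tissue_mask = np.zeros((H, W), dtype=bool)
    for cx, cy, rx, ry in blobs:
        tissue_mask |= ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0

    paint_texture(img, tissue_mask, "N", rng)

    # plant lesion discs so that ~lesion_fraction of tissue tiles are hit
    lesion_polygons: list = []
    if spec.slide_class in {"M", "D"}:
        ps = spec.patch_size
        base_grid = labels_from_geometry(tissue_geom, [], "N", W, H, ps)
        tissue_tiles = [tuple(t) for t in np.argwhere(base_grid != "background")]
        tile_area = ps ** 2
        coverage = {}
        for r, c in tissue_tiles:
            tile = box(c * ps, r * ps, (c + 1) * ps, (r + 1) * ps)
            coverage[(r, c)] = tissue_geom.intersection(tile)
        n_target = max(1, round(spec.lesion_fraction * len(tissue_tiles)))
        lesion_mask = np.zeros((H, W), dtype=bool)
        discs: list[tuple[float, float, float]] = []

        def plant(r: int, c: int) -> None:
            # center the disc on the tissue inside the tile so the clipped
            # lesion keeps enough area to pass the 25% overlap rule
            tis = coverage[(r, c)]
            cx, cy = tis.centroid.x, tis.centroid.y
            cx += rng.uniform(-0.05, 0.05) * ps
            cy += rng.uniform(-0.05, 0.05) * ps
            frac = tis.area / tile_area
            rad = (rng.uniform(0.44, 0.50) if frac >= 0.8
                   else rng.uniform(0.52, 0.60)) * ps
            disc = Point(cx, cy).buffer(rad, quad_segs=32)
            clipped = disc.intersection(tissue_geom)
            if clipped.is_empty:
                return
            lesion_polygons.append(clipped)
            discs.append((cx, cy, rad))

        order = rng.permutation(len(tissue_tiles))
        # seed pass on the best-covered tiles, then corrective passes on
        # tiles the overlap rule has not labeled yet
        ranked = sorted((tissue_tiles[i] for i in order),
                        key=lambda t: -coverage[t].area)
        for tile_rc in ranked[:n_target]:
            plant(*tile_rc)
        for _ in range(3):
            grid_now = labels_from_geometry(tissue_geom, lesion_polygons,
                                            spec.slide_class, W, H, ps)
            labeled = {tuple(t) for t in
                       np.argwhere(grid_now == spec.slide_class)}
            if len(labeled) >= n_target:
                break
            for tile_rc in ranked:
                if len(labeled) >= n_target:
                    break
                if tile_rc not in labeled:
                    plant(*tile_rc)
                    labeled.add(tile_rc)  # optimistic; rechecked next pass
        for cx, cy, rad in discs:
            lesion_mask |= (((xx - cx) ** 2 + (yy - cy) ** 2) <= rad ** 2) \
                & tissue_mask
        paint_texture(img, lesion_mask, spec.slide_class, rng)

    label_grid = labels_from_geometry(tissue_geom, lesion_polygons,
                                      spec.slide_class, W, H, spec.patch_size)

    _inject_artifacts(img, rng, spec.artifact_params, spec.patch_size)

    gt = GroundTruth(
        slide_class=spec.slide_class, organ=spec.organ, label_grid=label_grid,
        lesion_polygons=lesion_polygons, tissue_geom=tissue_geom,
        patch_size=spec.patch_size, width_px=W, height_px=H, seed=spec.seed,
    )
    heading, diagnosis = _typical_texts(gt, rng)
    gt.heading_text = heading
    gt.diagnosis_text = diagnosis
    gt.dx_class = classify_dx(diagnosis)
    raster = ArraySlide(img.astype(np.uint8), slide_id=f"synthetic_{spec.seed}")
    return raster, gt


# ---------------------------------------------------------------------
# diagnosis text
# ---------------------------------------------------------------------

_HEADINGS = {
    "gastric": ["Stomach, endoscopic biopsy"],
    "colorectal": [
        "Colon, colonoscopic biopsy",
        "Rectum, colonoscopic biopsy",
        "Cecum, colonoscopic biopsy",
        "Terminal ileum, colonoscopic biopsy",
        "Rectosigmoid junction, colonoscopic biopsy",
    ],
}

_TYPICAL_DX = {
    ("gastric", "N"): ["Chronic gastritis", "Chronic active gastritis with erosion",
                       "Fundic gland polyp", "Hyperplastic polyp"],
    ("colorectal", "N"): ["Hyperplastic polyp", "Nonspecific inflammation",
                          "Inflammatory polyp", "Lymphoid polyp"],
    ("gastric", "D"): ["Tubular adenoma, low grade dysplasia"],
    ("colorectal", "D"): ["Tubular adenoma, low grade dysplasia",
                          "Tubulovillous adenoma, low grade dysplasia"],
    ("gastric", "M"): ["Adenocarcinoma, moderately differentiated",
                       "Tubular adenoma, high grade dysplasia",
                       "Malignant neoplasm"],
    ("colorectal", "M"): ["Adenocarcinoma, moderately differentiated",
                          "Tubular adenoma, high grade dysplasia"],
}

_AMBIGUOUS_DX = {
    "M": "Atypical glandular proliferation, favor neoplastic",
    "D": "Atypical glandular proliferation, undetermined significance",
    "N": "Regenerative epithelial change with reactive atypia",
}

#: spurious positive line appended by the entry-error style (a data-entry
#: mistake adds a dysplasia diagnosis to a slide whose image is negative)
_SPURIOUS_LINE = "Tubular adenoma, low grade dysplasia"


def _typical_texts(gt: GroundTruth, rng: np.random.Generator) -> tuple[str, str]:
    heading = _HEADINGS[gt.organ][int(rng.integers(len(_HEADINGS[gt.organ])))]
    pool = _TYPICAL_DX[(gt.organ, gt.slide_class)]
    return heading, pool[int(rng.integers(len(pool)))]


def emit_dx_record(gt: GroundTruth, style: str = "typical",
                   accession: str = "A0001", block_id: str = "B0001",
                   seed: int = 0) -> DxRecord:
    """Emit a diagnosis record for a slide, optionally with injected error.

    Styles: ``typical`` (keyword class equals slide class), ``ambiguous``
    (hedged wording of the same class), ``entry_error`` (a spurious
    positive line appended — intended for N slides, making the record
    read as D while the image is negative).  The ``switched_pair`` style
    involves two slides; use :func:`emit_switched_pair`.
    """
    rng = np.random.default_rng(seed)
    heading, diagnosis = _typical_texts(gt, rng)
    heading = gt.heading_text or heading
    if style == "typical":
        diagnosis = gt.diagnosis_text or diagnosis
    elif style == "ambiguous":
        diagnosis = _AMBIGUOUS_DX[gt.slide_class]
    elif style == "entry_error":
        diagnosis = (gt.diagnosis_text or diagnosis) + "\n" + _SPURIOUS_LINE
    else:
        raise ValueError(f"unknown style {style!r}")
    return DxRecord(accession=accession, block_id=block_id, heading=heading,
                    diagnosis_text=diagnosis, organ=gt.organ).classified()


def emit_switched_pair(gt_a: GroundTruth, gt_b: GroundTruth,
                       accession_a: str, block_a: str,
                       accession_b: str, block_b: str) -> tuple[DxRecord, DxRecord]:
    """Two records whose diagnoses are attached to the wrong slides.

    Emulates a specimen switching error: the report text appropriate for
    slide B is filed under slide A's accession and vice versa.
    """
    rec_a = DxRecord(accession=accession_a, block_id=block_a,
                     heading=gt_a.heading_text, diagnosis_text=gt_b.diagnosis_text,
                     organ=gt_a.organ).classified()
    rec_b = DxRecord(accession=accession_b, block_id=block_b,
                     heading=gt_b.heading_text, diagnosis_text=gt_a.diagnosis_text,
                     organ=gt_b.organ).classified()
    return rec_a, rec_b


# ---------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------

def largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion n items to proportions by the largest-remainder method."""
    props = np.asarray(proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError(f"proportions must sum to 1, got {props.sum()}")
    quotas = n * props
    counts = np.floor(quotas).astype(int)
    rest = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:rest]:
        counts[i] += 1
    return counts.tolist()


def generate_corpus(
    n_specimens: int,
    class_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    organ_mix: Sequence[float] = (0.5, 0.5),
    seed: int = 0,
    out_dir: str | Path | None = None,
    serial_rate: float = 0.2,
    width_px: int = 1280,
    height_px: int = 1024,
    lesion_fraction: float = 0.5,
    artifact_params: ArtifactParams | None = None,
) -> pd.DataFrame:
    """Generate a corpus manifest of synthetic slides.

    ``class_mix`` applies over (M, D, N) at the specimen level, rounded by
    largest remainder; ``organ_mix`` over (gastric, colorectal).  A
    fraction ``serial_rate`` of specimens carry a second serial section
    from the same block (same class and organ, different cutting plane).

    When ``out_dir`` is given, slides are written as PNG under
    ``slides/``, ground truth as JSON under ``gt/``, one diagnosis record
    per specimen to ``records.jsonl``, and the manifest to
    ``manifest.csv``.  Otherwise the manifest holds specs only and slides
    are rendered on demand via :func:`generate_slide`.
    """
    if n_specimens <= 0:
        raise ValueError("n_specimens must be positive")
    rng = np.random.default_rng(seed)
    artifact_params = artifact_params or ArtifactParams()

    class_counts = largest_remainder(n_specimens, class_mix)
    classes = np.array(["M"] * class_counts[0] + ["D"] * class_counts[1]
                       + ["N"] * class_counts[2])
    organ_counts = largest_remainder(n_specimens, organ_mix)
    organs = np.array(["gastric"] * organ_counts[0]
                      + ["colorectal"] * organ_counts[1])
    classes = classes[rng.permutation(n_specimens)]
    organs = organs[rng.permutation(n_specimens)]
    n_serial = int(round(serial_rate * n_specimens))
    serial_ids = set(rng.choice(n_specimens, size=n_serial, replace=False).tolist())

    rows = []
    records: list[DxRecord] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "slides").mkdir(parents=True, exist_ok=True)
        (out_dir / "gt").mkdir(parents=True, exist_ok=True)

    for i in range(n_specimens):
        accession = f"A{i:04d}"
        block_id = f"B{i:04d}"
        n_slides = 2 if i in serial_ids else 1
        first_gt = None
        for k in range(n_slides):
            slide_seed = int(rng.integers(0, 2**31 - 1))
            spec = SyntheticSpec(
                seed=slide_seed, width_px=width_px, height_px=height_px,
                organ=str(organs[i]), slide_class=str(classes[i]),
                lesion_fraction=lesion_fraction,
                artifact_params=artifact_params,
            )
            slide_id = f"{accession}_{k:02d}"
            path = gt_path = None
            if out_dir is not None:
                raster, gt = generate_slide(spec)
                if first_gt is None:
                    first_gt = gt
                else:  # serial sections of one block share the report text
                    gt.heading_text = first_gt.heading_text
                    gt.diagnosis_text = first_gt.diagnosis_text
                    gt.dx_class = first_gt.dx_class
                path = out_dir / "slides" / f"{slide_id}.png"
                gt_path = out_dir / "gt" / f"{slide_id}.json"
                write_slide(raster.pixels, path)
                gt.to_json(gt_path)
            rows.append(dict(
                slide_id=slide_id, accession=accession, block_id=block_id,
                organ=str(organs[i]), slide_class=str(classes[i]),
                seed=slide_seed, width_px=width_px, height_px=height_px,
                serial=(n_slides > 1),
                path=str(path) if path else "",
                gt_path=str(gt_path) if gt_path else "",
            ))
        if out_dir is not None and first_gt is not None:
            records.append(DxRecord(
                accession=accession, block_id=block_id,
                heading=first_gt.heading_text,
                diagnosis_text=first_gt.diagnosis_text,
                organ=first_gt.organ).classified())

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from .dx_rules import write_records

        manifest.to_csv(out_dir / "manifest.csv", index=False)
        write_records(records, out_dir / "records.jsonl")
    return manifest


def spec_from_manifest_row(row) -> SyntheticSpec:
    """Rebuild the SyntheticSpec of a manifest row (for on-demand rendering)."""
    return SyntheticSpec(
        seed=int(row["seed"]), width_px=int(row["width_px"]),
        height_px=int(row["height_px"]), organ=str(row["organ"]),
        slide_class=str(row["slide_class"]),
    )


def split_corpus(manifest: pd.DataFrame, ratios: Sequence[float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test splits at specimen (block) level.

    All slides of one block land in the same split so that serial
    sections never straddle a split boundary; block counts follow the
    ratios by largest remainder.
    """
    if manifest.empty:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    blocks = manifest["block_id"].drop_duplicates().to_numpy()
    blocks = blocks[rng.permutation(len(blocks))]
    counts = largest_remainder(len(blocks), ratios)
    assignment: dict[str, str] = {}
    start = 0
    for name, cnt in zip(("train", "val", "test"), counts):
        for b in blocks[start:start + cnt]:
            assignment[b] = name
        start += cnt
    out = manifest.copy()
    out["split"] = out["block_id"].map(assignment)
    return out
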