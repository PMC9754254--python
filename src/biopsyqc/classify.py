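"""Patch-level and slide-level classification.

The pipeline mirrors a patch-based whole-slide classification framework:
a slide is tiled, every tissue patch is scored by a 3-class patch
classifier (M = malignant, D = dysplasia, N = negative for dysplasia),
the per-patch confidence vectors are placed back on the tile grid to form
a small rectangular *reconstructed slide*, and a second classifier maps
that reconstruction to the slide-level class.  Separate model pairs are
kept per organ route (gastric, colorectal).

The classifier itself is pluggable: anything with ``fit(patches, labels)``
and ``predict_proba(patches) -> (n, 3)`` can stand behind the pipeline,
so a full-scale convolutional network can replace the bundled reference
model.  The reference model extracts fixed chromatin/texture features
(channel statistics, dark-pixel fractions at several thresholds, gradient
energy, and a block-pooled intensity map) and fits a small multi-layer
perceptron — deliberately light so the whole pipeline trains in minutes
on one CPU.

Training supports the two data-conditioning steps the pipeline assumes:
class balancing by down-sampling to the minority class, and loss-based
noise removal (after a warm-up fit, the top-q fraction of training
patches by cross-entropy loss is dropped and the model is refit from
scratch on the remainder).

Probabilities are never renormalized after prediction; a reconstruction
cell either holds a softmax-like vector summing to 1 (classified tissue)
or an all-zero vector (background / unclassified), which no probability
vector can equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .slide_io import SlideRaster
from .tiling import PatchDB, TissueParams, tile_slide

#: class order of every probability vector; index 0 is the most severe
#: class, so ``argmax`` ties break toward the clinically serious side.
CLASSES = ("M", "D", "N")

ORGANS = ("gastric", "colorectal")


@dataclass(frozen=True)
class PatchPrediction:
    patch_index: int
    probs: tuple[float, float, float]  # (p_M, p_D, p_N), sums to 1

    @property
    def argmax_class(self) -> str:
        return CLASSES[int(np.argmax(self.probs))]


@dataclass
class ReconstructedSlide:
    """Per-patch confidence vectors arranged on the tile grid."""

    slide_id: str
    grid: np.ndarray  # (n_rows, n_cols, 3); zero vector = background

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]


@dataclass(frozen=True)
class SlidePrediction:
    slide_id: str
    final_class: str
    confidence: tuple[float, float, float]
    model_id: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs shared by the patch and slide classifiers."""

    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    balance: bool = True
    noise_removal_fraction: float = 0.02  # q: top-loss fraction dropped
    warmup_epochs: int = 15

    def __post_init__(self):
        if not 0 <= self.noise_removal_fraction <= 0.1:
            raise ValueError("noise_removal_fraction must be in [0, 0.1]")


class PatchModel(Protocol):
    """Contract for a pluggable 3-class patch classifier."""

    def fit(self, patches: np.ndarray, labels: Sequence[str]) -> "PatchModel": ...

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """(n, 3) array in CLASSES order, rows summing to 1."""
        ...


# ---------------------------------------------------------------------
# feature extraction for the reference model
# ---------------------------------------------------------------------

def _patch_features(patches: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Fixed feature vector per patch: color stats, nuclear-density proxies,
    gradient energy, and an 8x8 block-pooled intensity map.

    Processed in chunks: the float64 intermediates of a full training set
    would otherwise dominate memory.
    """
    patches = np.asarray(patches)
    if len(patches) > chunk:
        return np.concatenate([_patch_features(patches[i:i + chunk], chunk)
                               for i in range(0, len(patches), chunk)])
    patches = patches.astype(np.float64)
    n, H, W, _ = patches.shape
    gray = (0.299 * patches[..., 0] + 0.587 * patches[..., 1]
            + 0.114 * patches[..., 2])
    feats = [patches.reshape(n, -1, 3).mean(axis=1),        # channel means
             patches.reshape(n, -1, 3).std(axis=1)]          # channel stds
    for thr in (100.0, 140.0, 180.0, 220.0):                 # dark fractions
        feats.append((gray < thr).reshape(n, -1).mean(axis=1, keepdims=True))
    gx = np.diff(gray, axis=2, prepend=gray[:, :, :1])
    gy = np.diff(gray, axis=1, prepend=gray[:, :1, :])
    grad = np.hypot(gx, gy)
    feats.append(grad.reshape(n, -1).mean(axis=1, keepdims=True))
    feats.append(grad.reshape(n, -1).std(axis=1, keepdims=True))
    # block-pooled gray map (pad to a multiple of 8 with white)
    bs = 8
    Hp, Wp = math.ceil(H / bs) * bs, math.ceil(W / bs) * bs
    if (Hp, Wp) != (H, W):
        padded = np.full((n, Hp, Wp), 255.0)
        padded[:, :H, :W] = gray
        gray = padded
    pooled = gray.reshape(n, bs, Hp // bs, bs, Wp // bs).mean(axis=(2, 4))
    feats.append(pooled.reshape(n, -1))
    return np.concatenate(feats, axis=1)


class MLPPatchModel:
    """Reference patch classifier: fixed features + small MLP."""

    def __init__(self, seed: int = 0, epochs: int = 200,
                 learning_rate: float = 1e-3, hidden: tuple[int, ...] = (64,)):
        self.seed = seed
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.hidden = hidden
        self._pipe = None

    def _build(self, max_iter: int):
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=self.hidden, max_iter=max_iter,
                          learning_rate_init=self.learning_rate,
                          random_state=self.seed),
        )

    def fit(self, patches: np.ndarray, labels: Sequence[str],
            max_iter: int | None = None) -> "MLPPatchModel":
        import warnings

        X = _patch_features(patches)
        self._pipe = self._build(max_iter or self.epochs)
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self._pipe.fit(X, np.asarray(labels))
        return self

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        if self._pipe is None:
            raise RuntimeError("model is not fitted")
        raw = self._pipe.predict_proba(_patch_features(patches))
        order = [list(self._pipe.classes_).index(c) for c in CLASSES]
        return raw[:, order]


class MLPSlideModel:
    """Reference slide classifier on the normalized reconstruction."""

    def __init__(self, seed: int = 0, epochs: int = 300,
                 learning_rate: float = 1e-3, hidden: tuple[int, ...] = (32,)):
        self.seed = seed
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.hidden = hidden
        self._clf = None

    def fit(self, reconstructions: np.ndarray, labels: Sequence[str]) -> "MLPSlideModel":
        import warnings

        from sklearn.exceptions import ConvergenceWarning
        from sklearn.neural_network import MLPClassifier

        X = np.asarray(reconstructions).reshape(len(reconstructions), -1)
        self._clf = MLPClassifier(hidden_layer_sizes=self.hidden,
                                  max_iter=self.epochs,
                                  learning_rate_init=self.learning_rate,
                                  random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._clf.fit(X, np.asarray(labels))
        return self

    def predict_proba(self, reconstructions: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(reconstructions).reshape(len(reconstructions), -1)
        raw = self._clf.predict_proba(X)
        order = [list(self._clf.classes_).index(c) for c in CLASSES]
        return raw[:, order]


# ---------------------------------------------------------------------
# training procedure
# ---------------------------------------------------------------------

def balance_sample(patches: np.ndarray, labels: Sequence[str], seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Down-sample to equal per-class counts (the minority count),
    without replacement, seeded."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    missing = set(CLASSES) - set(classes)
    if missing:
        raise ValueError(f"classes absent from training pool: {sorted(missing)}")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in CLASSES:
        idx = np.flatnonzero(labels == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep_idx = np.sort(np.concatenate(keep))
    return patches[keep_idx], labels[keep_idx]


def noise_removal_keep_indices(losses: np.ndarray, q: float) -> np.ndarray:
    """Indices kept after dropping the top-q fraction by training loss."""
    n = len(losses)
    n_drop = int(np.floor(q * n + 1e-9))
    if n_drop == 0:
        return np.arange(n)
    order = np.argsort(losses, kind="stable")  # ascending; worst last
    return np.sort(order[: n - n_drop])


def train_patch_classifier(patches: np.ndarray, labels: Sequence[str],
                           config: TrainConfig = TrainConfig(),
                           model: MLPPatchModel | None = None) -> MLPPatchModel:
    """Train the patch classifier with balancing and noise removal.

    With ``q = config.noise_removal_fraction > 0``, the model is first
    fit for ``warmup_epochs``, per-patch cross-entropy losses are
    computed, the top-q fraction of noisiest patches is removed, and
    training restarts from scratch on the remainder.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if set(CLASSES) - set(classes) or counts.min() < 3:
        raise ValueError("need at least 3 patches of each class M, D, N")
    if config.balance:
        patches, labels = balance_sample(patches, labels, seed=config.seed)
    model = model or MLPPatchModel(seed=config.seed, epochs=config.epochs,
                                   learning_rate=config.learning_rate)
    q = config.noise_removal_fraction
    if q > 0:
        model.fit(patches, labels, max_iter=config.warmup_epochs)
        probs = model.predict_proba(patches)
        true_idx = np.array([CLASSES.index(c) for c in labels])
        losses = -np.log(np.clip(probs[np.arange(len(labels)), true_idx],
                                 1e-12, None))
        keep = noise_removal_keep_indices(losses, q)
        patches, labels = patches[keep], labels[keep]
    model.fit(patches, labels)
    model.train_size_ = len(labels)
    return model


def train_slide_classifier(reconstructions: Sequence[np.ndarray],
                           labels: Sequence[str],
                           config: TrainConfig = TrainConfig(),
                           target: tuple[int, int] = (64, 64)) -> MLPSlideModel:
    """Train the slide-level classifier on normalized reconstructions."""
    labels = np.asarray(labels)
    if set(CLASSES) - set(np.unique(labels)):
        raise ValueError("every class M, D, N must appear among training slides")
    X = np.stack([normalize_reconstruction(r, target) for r in reconstructions])
    model = MLPSlideModel(seed=config.seed, learning_rate=config.learning_rate)
    model.fit(X, labels)
    model.target_ = target
    return model


# ---------------------------------------------------------------------
# prediction pipeline
# ---------------------------------------------------------------------

def predict_patches(model: PatchModel, patch_db: PatchDB, raster: SlideRaster,
                    include_background: bool = False) -> list[PatchPrediction]:
    """Score every (tissue) patch of a tiled slide; results stored in the DB."""
    indices = (patch_db.df.patch_index.to_numpy() if include_background
               else patch_db.tissue_indices())
    if len(indices) == 0:
        return []
    patches = np.stack([patch_db.read_patch(raster, int(i)) for i in indices])
    probs = model.predict_proba(patches)
    preds = [PatchPrediction(int(i), tuple(float(v) for v in p))
             for i, p in zip(indices, probs)]
    patch_db.store_predictions(preds)
    return preds


def build_reconstruction(predictions: Sequence[PatchPrediction],
                         patch_db: PatchDB) -> ReconstructedSlide:
    """Place each patch's confidence vector at its grid cell.

    Pure placement: any permutation of the prediction list yields the
    identical array.  Background / unclassified cells stay zero.
    """
    grid = np.zeros((patch_db.n_rows, patch_db.n_cols, 3))
    for p in predictions:
        col, row = patch_db.location_of(p.patch_index)
        grid[row, col] = p.probs
    return ReconstructedSlide(slide_id=patch_db.slide_id, grid=grid)


def normalize_reconstruction(rs: ReconstructedSlide | np.ndarray,
                             target: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Center and zero-pad a reconstruction to a fixed target shape.

    Grids larger than the target along an axis are first area-averaged
    down by the smallest integer block factor that fits (a 128x128 grid
    becomes 64x64 with each cell the mean of a 2x2 source block).
    """
    grid = rs.grid if isinstance(rs, ReconstructedSlide) else np.asarray(rs)
    th, tw = target
    h, w = grid.shape[:2]
    fy = math.ceil(h / th)
    fx = math.ceil(w / tw)
    if fy > 1 or fx > 1:
        from skimage.measure import block_reduce

        grid = block_reduce(grid, block_size=(fy, fx, 1), func=np.mean)
        h, w = grid.shape[:2]
    out = np.zeros((th, tw, 3), dtype=grid.dtype)
    y0 = (th - h) // 2
    x0 = (tw - w) // 2
    out[y0:y0 + h, x0:x0 + w] = grid
    return out


@dataclass
class OrganModels:
    """A patch/slide model pair for one organ route."""

    patch_model: PatchModel
    slide_model: MLPSlideModel
    organ: str
    target: tuple[int, int] = (64, 64)


def predict_slide(models: dict[str, OrganModels], raster: SlideRaster,
                  organ: str, patch_size: int = 256,
                  tissue_params: TissueParams | None = None
                  ) -> tuple[SlidePrediction, PatchDB]:
    """Run the full tile -> patch-predict -> reconstruct -> classify chain.

    A slide without any tissue patch cannot be reconstructed; it falls
    back to class N with a ``no_tissue`` flag rather than failing, since
    an empty scan carries no evidence of a lesion.
    """
    if organ not in models:
        raise KeyError(f"no model available for organ {organ!r}")
    om = models[organ]
    db = tile_slide(raster, patch_size, tissue_params)
    preds = predict_patches(om.patch_model, db, raster)
    if not preds:
        sp = SlidePrediction(raster.slide_id, "N", (0.0, 0.0, 1.0),
                             model_id=organ, flags=("no_tissue",))
        db.slide_class = sp.final_class
        return sp, db
    rs = build_reconstruction(preds, db)
    X = normalize_reconstruction(rs, om.target)[None]
    probs = om.slide_model.predict_proba(X)[0]
    sp = SlidePrediction(raster.slide_id, CLASSES[int(np.argmax(probs))],
                         tuple(float(v) for v in probs), model_id=organ)
    db.slide_class = sp.final_class
    return sp, db


# ---------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------

HEAT_COLORS = {"M": (255, 0, 0), "D": (0, 0, 255)}  # N / background: no heat


def render_heatmap(predictions: Sequence[PatchPrediction], patch_db: PatchDB,
                   scale: float = 0.125, opacity: float = 0.5) -> np.ndarray:
    """RGBA heatmap overlay at a thumbnail scale.

    Each classified patch paints one rectangle of ``patch_size * scale``
    pixels: red where the argmax class is M, blue where it is D, and
    fully transparent for N and background, so negative slides show no
    heat at all.  The overlay composes over a slide thumbnail of the
    same scale and can simply be toggled on/off.
    """
    rect = max(1, round(patch_db.patch_size * scale))
    H, W = patch_db.n_rows * rect, patch_db.n_cols * rect
    overlay = np.zeros((H, W, 4), dtype=np.uint8)
    alpha = int(round(opacity * 255))
    for p in predictions:
        color = HEAT_COLORS.get(p.argmax_class)
        if color is None:
            continue
        col, row = patch_db.location_of(p.patch_index)
        overlay[row * rect:(row + 1) * rect, col * rect:(col + 1) * rect] = \
            (*color, alpha)
    return overlay


def compose_heatmap(thumbnail: np.ndarray, overlay: np.ndarray,
                    mask_on: bool = True) -> np.ndarray:
    """Alpha-compose the heatmap over a thumbnail (mask off = plain image)."""
    thumb = np.asarray(thumbnail, dtype=np.float64)
    if not mask_on:
        return thumb.astype(np.uint8)
    H = min(thumb.shape[0], overlay.shape[0])
    W = min(thumb.shape[1], overlay.shape[1])
    out = thumb.copy()
    a = overlay[:H, :W, 3:4].astype(np.float64) / 255.0
    out[:H, :W] = (1 - a) * thumb[:H, :W] + a * overlay[:H, :W, :3]
    return np.clip(out, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_models(models: dict[str, OrganModels], path: str | Path) -> None:
    """Persist organ model pairs as one joblib archive."""
    import joblib

    joblib.dump(models, path)


def load_models(path: str | Path) -> dict[str, OrganModels]:
    import joblib

    return joblib.load(path)
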