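"""End-to-end training/evaluation helpers over a synthetic corpus.

One organ route gets one patch classifier and one slide classifier, kept
strictly separate from the other route.  The patch classifier is trained
on a balanced set of standalone rendered patches (the same texture
recipes the slide generator paints), the slide classifier on the
reconstructions produced by running the trained patch classifier over the
corpus' training slides — i.e. the slide model learns from the patch
model's actual output distribution, not from idealized inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (CLASSES, OrganModels, TrainConfig, build_reconstruction,
                       predict_patches, train_patch_classifier,
                       train_slide_classifier)
from .slide_io import open_slide
from .synthetic import sample_patches
from .tiling import tile_slide


def train_models_on_corpus(
    corpus_dir: str | Path,
    manifest: pd.DataFrame | None = None,
    seed: int = 0,
    n_patches_per_class: int = 667,
    target: tuple[int, int] = (64, 64),
    organs: Sequence[str] = ("gastric", "colorectal"),
    config: TrainConfig | None = None,
) -> dict[str, OrganModels]:
    """Train a patch+slide model pair per organ from a written corpus.

    If the manifest carries a ``split`` column only ``train`` rows feed
    the slide classifier; otherwise all slides do.
    """
    corpus_dir = Path(corpus_dir)
    if manifest is None:
        manifest = pd.read_csv(corpus_dir / "manifest.csv")
    rows = manifest[manifest.split == "train"] if "split" in manifest else manifest

    models: dict[str, OrganModels] = {}
    for i, organ in enumerate(organs):
        cfg = config or TrainConfig(seed=seed + i)
        patches, labels = sample_patches(n_patches_per_class, seed=seed + 1000 + i)
        patch_model = train_patch_classifier(patches, labels, cfg)

        organ_rows = rows[rows.organ == organ]
        if organ_rows.empty:
            continue
        recons, slide_labels = [], []
        for row in organ_rows.itertuples():
            raster = open_slide(row.path, row.slide_id)
            db = tile_slide(raster)
            preds = predict_patches(patch_model, db, raster)
            recons.append(build_reconstruction(preds, db).grid)
            slide_labels.append(row.slide_class)
        slide_model = train_slide_classifier(recons, slide_labels, cfg, target)
        models[organ] = OrganModels(patch_model, slide_model, organ, target)
    return models


def patch_holdout_accuracy(models: dict[str, OrganModels], seed: int,
                           n_eval_per_class: int = 200) -> float:
    """Accuracy of the patch classifiers on fresh held-out rendered patches,
    averaged over organ routes."""
    accs = []
    for i, (organ, om) in enumerate(sorted(models.items())):
        patches, labels = sample_patches(n_eval_per_class, seed=seed + 5000 + i)
        probs = om.patch_model.predict_proba(patches)
        pred = np.array([CLASSES[k] for k in probs.argmax(axis=1)])
        accs.append(float(np.mean(pred == labels)))
    return float(np.mean(accs))


def predict_manifest_slides(models: dict[str, OrganModels],
                            manifest: pd.DataFrame) -> pd.DataFrame:
    """Slide-level predictions for every manifest row, routed by organ."""
    from .classify import predict_slide

    out = []
    for row in manifest.itertuples():
        raster = open_slide(row.path, row.slide_id)
        pred, _db = predict_slide(models, raster, row.organ)
        out.append(dict(slide_id=row.slide_id, organ=row.organ,
                        true_class=row.slide_class,
                        pred_class=pred.final_class))
    return pd.DataFrame(out)


def slide_accuracy(pred_df: pd.DataFrame) -> float:
    return float(np.mean(pred_df.pred_class == pred_df.true_class))


# ---------------------------------------------------------------------
# error-injection drill
# ---------------------------------------------------------------------

#: negative wording used when a report "misses" a lesion in the drill
_NEGATIVE_TEXT = "Hyperplastic polyp"
_SPURIOUS_LINE = "Tubular adenoma, low grade dysplasia"


def build_error_drill(corpus_dir: str | Path, manifest: pd.DataFrame,
                      batch_dir: str | Path, n_slides: int = 60,
                      seed: int = 0):
    """Assemble a daily QC batch with five injected report errors.

    From ``n_slides`` corpus slides, three error mechanisms are planted
    into otherwise-correct records: two false-negative reports (a lesion
    slide filed with negative wording), one false-positive data-entry
    error (a spurious dysplasia line appended to a negative report), and
    one switched pair (the reports of a lesion slide and a negative slide
    exchanged) — five affected slides in total.  Slides are linked into
    ``batch_dir``; returns ``(records, error_slide_ids)``.
    """
    import shutil

    from .dx_rules import read_records

    corpus_dir, batch_dir = Path(corpus_dir), Path(batch_dir)
    batch_dir.mkdir(parents=True, exist_ok=True)
    rows = manifest.sort_values("slide_id").head(n_slides)
    for row in rows.itertuples():
        dst = batch_dir / f"{row.slide_id}.png"
        if not dst.exists():
            try:
                dst.symlink_to(Path(row.path).resolve())
            except OSError:
                shutil.copy(row.path, dst)

    accessions = set(rows.accession)
    records = [r for r in read_records(corpus_dir / "records.jsonl")
               if r.accession in accessions]
    by_acc = {r.accession: r for r in records}

    singles = rows.groupby("accession").filter(lambda g: len(g) == 1)
    rng = np.random.default_rng(seed)

    def pick(classes: set[str], exclude: set[str]) -> str:
        pool = sorted(a for a in singles[singles.slide_class.isin(classes)]
                      .accession.unique() if a not in exclude)
        if not pool:
            raise ValueError("drill corpus lacks a singleton specimen of "
                             f"class {sorted(classes)}")
        return str(pool[rng.integers(len(pool))])

    used: set[str] = set()
    error_accessions: list[str] = []
    for _ in range(2):  # false-negative report text on a lesion slide
        acc = pick({"M", "D"}, used)
        used.add(acc)
        by_acc[acc].diagnosis_text = _NEGATIVE_TEXT
        by_acc[acc].classified()
        error_accessions.append(acc)
    acc = pick({"N"}, used)  # data-entry error on a negative slide
    used.add(acc)
    by_acc[acc].diagnosis_text += "\n" + _SPURIOUS_LINE
    by_acc[acc].classified()
    error_accessions.append(acc)
    a_lesion = pick({"M", "D"}, used)  # switched pair
    used.add(a_lesion)
    a_neg = pick({"N"}, used)
    used.add(a_neg)
    ra, rb = by_acc[a_lesion], by_acc[a_neg]
    ra.diagnosis_text, rb.diagnosis_text = rb.diagnosis_text, ra.diagnosis_text
    ra.classified()
    rb.classified()
    error_accessions += [a_lesion, a_neg]

    error_slide_ids = sorted(rows[rows.accession.isin(error_accessions)]
                             .slide_id)
    return records, error_slide_ids
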