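"""Concordance/discordance QC engine.

The daily QC loop compares, slide by slide, the class derived from the
pathologist's free-text diagnosis (via the keyword rule engine) with the
class predicted by the image model, and builds a review worklist with
discordant cases first so potential human errors — above all false
negatives — surface within a day instead of at the next monthly random
review.

Comparison is per-slide on purpose: aggregating serial slides of one
specimen before comparing can cancel a switching error (two slides whose
reports were exchanged aggregate to the same class on both sides), so
specimen-level aggregates are reported alongside but never suppress a
slide-level discordance.

Exclusions: slides whose diagnosis class is U (neuroendocrine lesions,
outside the ternary image model), scan failures, unroutable headings and
slides without a matching report are all carried as explicit statuses and
excluded from the accuracy metrics, with their counts reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import OrganModels, SlidePrediction, predict_slide, render_heatmap
from .dx_rules import (CLASS_PRIORITY, DxRecord, KeywordTable, aggregate_classes,
                       classify_dx, route_organ)
from .slide_io import SlideRaster, SlideReadError, open_slide

TERNARY = ("M", "D", "N")

STATUSES = ("concordant", "discordant", "scan_failed", "unrouted",
            "excluded_U", "no_report")

#: discordance severity by the unordered class pair
SEVERITY = {frozenset({"M", "N"}): "severe",
            frozenset({"M", "D"}): "moderate",
            frozenset({"D", "N"}): "mild"}

_SEVERITY_RANK = {"severe": 0, "moderate": 1, "mild": 2}


@dataclass
class ConcordanceRecord:
    slide_id: str
    accession: str
    block_id: str = ""
    dx_class: str | None = None
    ai_class: str | None = None
    status: str = "concordant"
    severity: str | None = None
    reviewer_verdict: str | None = None  # dx_correct | ai_correct | both_wrong | unresolved
    feedback: str = ""
    timestamp: str = ""


def compare(dx_class: str, ai_class_or_failure: str | None) -> str:
    """Status of one slide: dx class vs AI class (or a failure signal).

    Failure signals take precedence; a class-U diagnosis is excluded from
    the ternary comparison; otherwise the status is decided purely by
    (in)equality of the two classes.
    """
    if dx_class not in ("M", "D", "N", "U"):
        raise ValueError(f"dx_class must be one of M,D,N,U, got {dx_class!r}")
    if ai_class_or_failure in ("scan_failed", None):
        return "scan_failed"
    if ai_class_or_failure == "unrouted":
        return "unrouted"
    if dx_class == "U":
        return "excluded_U"
    if ai_class_or_failure not in TERNARY:
        raise ValueError(f"unknown AI class {ai_class_or_failure!r}")
    return "concordant" if dx_class == ai_class_or_failure else "discordant"


def severity_of(dx_class: str | None, ai_class: str | None) -> str | None:
    if dx_class is None or ai_class is None or dx_class == ai_class:
        return None
    return SEVERITY.get(frozenset({dx_class, ai_class}))


def make_record(slide_id: str, accession: str, dx_class: str,
                ai_class_or_failure: str | None, block_id: str = "") -> ConcordanceRecord:
    status = compare(dx_class, ai_class_or_failure)
    ai_class = ai_class_or_failure if ai_class_or_failure in TERNARY else None
    if status in ("scan_failed", "unrouted"):
        ai_class = None  # failed/unrouted slides carry no AI class
    return ConcordanceRecord(
        slide_id=slide_id, accession=accession, block_id=block_id,
        dx_class=dx_class, ai_class=ai_class, status=status,
        severity=severity_of(dx_class, ai_class) if status == "discordant" else None,
    )


def build_worklist(records: Sequence[ConcordanceRecord]) -> list[ConcordanceRecord]:
    """Review-priority ordering.

    Discordant cases first (severe before moderate before mild, then by
    diagnosis severity M > D > N), then unrouted, no-report and
    scan-failed slides, and concordant cases last.  The sort is stable,
    so ties keep their input (accession) order.
    """
    group_rank = {"discordant": 0, "unrouted": 1, "no_report": 2,
                  "scan_failed": 3, "excluded_U": 4, "concordant": 5}

    def key(r: ConcordanceRecord):
        sev = _SEVERITY_RANK.get(r.severity or "", 9)
        dx_rank = -CLASS_PRIORITY.get(r.dx_class or "N", 0)
        return (group_rank.get(r.status, 9), sev, dx_rank)

    return sorted(records, key=key)


@dataclass
class QCMetrics:
    confusion: pd.DataFrame  # rows: dx class, cols: AI class, over M/D/N
    ternary_accuracy: float
    npv: float
    binary_accuracy: float
    binary_sensitivity: float
    binary_specificity: float
    n_included: int
    excluded_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "ternary_accuracy": self.ternary_accuracy,
            "npv": self.npv,
            "binary_accuracy": self.binary_accuracy,
            "binary_sensitivity": self.binary_sensitivity,
            "binary_specificity": self.binary_specificity,
            "n_included": self.n_included,
            "excluded_counts": self.excluded_counts,
        }


def compute_metrics(records: Sequence[ConcordanceRecord]) -> QCMetrics:
    """Confusion matrix and rates over the included (M/D/N vs M/D/N) slides.

    * ternary accuracy: trace / total
    * NPV: #(dx=N and AI=N) / #(AI=N) — the fraction of AI-negative
      slides that are truly negative by diagnosis
    * binary metrics collapse {D, N} to non-M, with M as the positive
      class (suspicious for malignancy vs no possibility of malignancy)
    """
    included = [r for r in records if r.status in ("concordant", "discordant")]
    if not included:
        raise ValueError("no included records: metrics are undefined")
    conf = pd.DataFrame(0, index=list(TERNARY), columns=list(TERNARY))
    for r in included:
        conf.loc[r.dx_class, r.ai_class] += 1
    total = int(conf.to_numpy().sum())
    acc = float(np.trace(conf.to_numpy())) / total
    ai_n = int(conf["N"].sum())
    npv = float(conf.loc["N", "N"]) / ai_n if ai_n else float("nan")
    dx_m = np.array([r.dx_class == "M" for r in included])
    ai_m = np.array([r.ai_class == "M" for r in included])
    bin_acc = float(np.mean(dx_m == ai_m))
    sens = float(np.mean(ai_m[dx_m])) if dx_m.any() else float("nan")
    spec = float(np.mean(~ai_m[~dx_m])) if (~dx_m).any() else float("nan")
    excluded: dict[str, int] = {}
    for r in records:
        if r.status not in ("concordant", "discordant"):
            excluded[r.status] = excluded.get(r.status, 0) + 1
    return QCMetrics(confusion=conf, ternary_accuracy=acc, npv=npv,
                     binary_accuracy=bin_acc, binary_sensitivity=sens,
                     binary_specificity=spec, n_included=total,
                     excluded_counts=excluded)


# ---------------------------------------------------------------------
# reference error-case fixture
# ---------------------------------------------------------------------

#: Seven reference error cases of the kinds a daily QC loop must catch:
#: five false negatives (missed lesion or omitted text), one false-positive
#: data-entry error, and one switched specimen pair (two slides whose
#: reports were exchanged).  Each entry is (case id, [(dx_class, ai_class)
#: per slide]).  They serve as a self-check of the per-slide comparator:
#: every case must surface as discordant.
REFERENCE_ERROR_CASES: list[tuple[str, list[tuple[str, str]]]] = [
    ("case1_fn_missed_cancer", [("D", "M")]),
    ("case2_fn_missed_cancer", [("N", "M")]),
    ("case3_fn_missed_adenoma", [("N", "D")]),
    ("case4_fn_difficult_dx", [("N", "D")]),
    ("case5_fn_omitted_text", [("N", "D")]),
    ("case6_fp_entry_error", [("D", "N")]),
    ("case7_switched_pair", [("D", "N"), ("N", "D")]),
]


def reference_case_records() -> list[ConcordanceRecord]:
    records = []
    for case_id, pairs in REFERENCE_ERROR_CASES:
        for i, (dx, ai) in enumerate(pairs):
            records.append(make_record(f"{case_id}_{i:02d}", case_id, dx, ai))
    return records


def count_discordant_reference_cases() -> int:
    """Number of reference cases with >= 1 discordant slide (expected: all 7)."""
    by_case: dict[str, bool] = {}
    for r in reference_case_records():
        by_case[r.accession] = by_case.get(r.accession, False) or \
            r.status == "discordant"
    return sum(by_case.values())


# ---------------------------------------------------------------------
# daily run
# ---------------------------------------------------------------------

Predictor = Callable[[SlideRaster, str], SlidePrediction]
"""A predictor maps (raster, organ) to a SlidePrediction."""


class ModelPredictor:
    """Default predictor backed by trained organ model pairs."""

    def __init__(self, models: dict[str, OrganModels], patch_size: int = 256,
                 heatmap_dir: str | Path | None = None):
        self.models = models
        self.patch_size = patch_size
        self.heatmap_dir = Path(heatmap_dir) if heatmap_dir else None

    def __call__(self, raster: SlideRaster, organ: str) -> SlidePrediction:
        pred, db = predict_slide(self.models, raster, organ, self.patch_size)
        if self.heatmap_dir is not None:
            from PIL import Image

            self.heatmap_dir.mkdir(parents=True, exist_ok=True)
            preds = [p for p in _db_predictions(db)]
            overlay = render_heatmap(preds, db)
            Image.fromarray(overlay, "RGBA").save(
                self.heatmap_dir / f"{raster.slide_id}.png")
        return pred


class GroundTruthPredictor:
    """Oracle predictor that answers with the planted synthetic truth.

    Replaces the image models in end-to-end drills so that the QC logic
    can be exercised independently of classifier accuracy: the "AI"
    class of a slide is its synthetic ground-truth class, read from the
    generator's JSON files by slide id.
    """

    def __init__(self, gt_dir: str | Path):
        self.gt_dir = Path(gt_dir)

    def __call__(self, raster: SlideRaster, organ: str) -> SlidePrediction:
        from .synthetic import GroundTruth

        gt = GroundTruth.from_json(self.gt_dir / f"{raster.slide_id}.json")
        probs = tuple(1.0 if c == gt.slide_class else 0.0 for c in ("M", "D", "N"))
        return SlidePrediction(raster.slide_id, gt.slide_class, probs,
                               model_id=organ)


def _db_predictions(db):
    from .classify import PatchPrediction

    sub = db.df.dropna(subset=["p_M"]) if "p_M" in db.df.columns else db.df.iloc[:0]
    return [PatchPrediction(int(r.patch_index), (r.p_M, r.p_D, r.p_N))
            for r in sub.itertuples()]


@dataclass
class QCReport:
    records: list[ConcordanceRecord]
    worklist: list[ConcordanceRecord]
    metrics: QCMetrics | None
    specimen_aggregates: pd.DataFrame

    @property
    def n_severe(self) -> int:
        return sum(1 for r in self.records if r.severity == "severe")

    def to_json(self, path: str | Path) -> None:
        data = {
            "records": [asdict(r) for r in self.records],
            "worklist": [r.slide_id for r in self.worklist],
            "metrics": self.metrics.to_dict() if self.metrics else None,
            "specimen_aggregates": self.specimen_aggregates.to_dict("records"),
        }
        Path(path).write_text(json.dumps(data, indent=2))

    def worklist_csv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(r) for r in self.worklist]).to_csv(path, index=False)


def run_daily_qc(
    slide_dir: str | Path,
    dx_records: Sequence[DxRecord],
    predictor: Predictor,
    rules: KeywordTable | None = None,
    max_retries: int = 3,
    out_dir: str | Path | None = None,
) -> QCReport:
    """Process one day's batch of scanned slides against their reports.

    Slide files are matched to diagnosis records by accession — the part
    of the file name before the first underscore (one report covers all
    serial slides of a specimen).  Each matched slide is routed by its
    heading, predicted (with up to ``max_retries`` read attempts before
    declaring a scan failure), compared per-slide, and folded into the
    worklist; specimen-level aggregated classes are reported alongside.
    """
    slide_dir = Path(slide_dir)
    by_accession = {r.accession: r for r in dx_records}
    records: list[ConcordanceRecord] = []
    slide_rows: list[dict] = []

    paths = sorted(p for p in slide_dir.iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff"})
    for path in paths:
        slide_id = path.stem
        accession = slide_id.split("_")[0]
        dx_rec = by_accession.get(accession)
        if dx_rec is None:
            records.append(ConcordanceRecord(
                slide_id=slide_id, accession=accession, status="no_report"))
            continue
        dx_class = dx_rec.dx_class or classify_dx(dx_rec.diagnosis_text, rules)
        organ = route_organ(dx_rec.heading)
        if organ == "unrouted":
            records.append(make_record(slide_id, accession, dx_class,
                                       "unrouted", dx_rec.block_id))
            continue
        pred = None
        for _ in range(max_retries):
            try:
                raster = open_slide(path, slide_id)
                pred = predictor(raster, organ)
                break
            except SlideReadError:
                continue
        ai = pred.final_class if pred is not None else "scan_failed"
        records.append(make_record(slide_id, accession, dx_class, ai,
                                   dx_rec.block_id))
        slide_rows.append(dict(slide_id=slide_id, block_id=dx_rec.block_id,
                               dx_class=dx_class, ai_class=ai))

    # specimen-level aggregation (reported, never suppressing slide status)
    agg_rows = []
    if slide_rows:
        df = pd.DataFrame(slide_rows)
        for block_id, grp in df.groupby("block_id", sort=True):
            ai = [c for c in grp.ai_class if c in TERNARY]
            agg_rows.append(dict(
                block_id=block_id,
                n_slides=len(grp),
                dx_final=aggregate_classes(list(grp.dx_class)),
                ai_final=aggregate_classes(ai) if ai else None,
            ))
    aggregates = pd.DataFrame(agg_rows)

    included = [r for r in records if r.status in ("concordant", "discordant")]
    metrics = compute_metrics(records) if included else None
    report = QCReport(records=records, worklist=build_worklist(records),
                      metrics=metrics, specimen_aggregates=aggregates)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "qc_report.json")
        report.worklist_csv(out_dir / "worklist.csv")
    return report
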