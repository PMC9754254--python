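# biopsyqc

AI-assisted **daily quality control for gastrointestinal endoscopic biopsy
histopathology**. The package implements a complete post-analytic QC loop:
every signed-out slide is classified by an image model into three classes —
**M** (malignancy / high-grade dysplasia cannot be ruled out), **D**
(low-grade dysplasia), **N** (negative for dysplasia) — the pathologist's
free-text diagnosis is classified into {M, D, N, U} by a keyword rule
engine, and the two classes are compared slide by slide. Discordant cases
are listed first for review, so human errors (above all false negatives:
a missed lesion, an omitted diagnosis line, a switched specimen pair)
surface within a day instead of at the next monthly random review.

It is aimed at pathology-informatics developers who want a desk-scale,
fully testable reference implementation of such a QC pipeline: every stage
runs on synthetic slides generated by the package itself, with no clinical
data required.

## What is inside

- **Patch pipeline** (`tiling`, `classify`): a slide is cut into an indexed
  grid of 256×256 patches (`patch_index = grid_row · n_cols + grid_col`,
  edge tiles padded white); each tissue patch gets a class-probability
  vector `(p_M, p_D, p_N)`; the vectors are placed back on the grid to form
  a small rectangular *reconstructed slide*; a second classifier maps the
  centered, zero-padded 64×64 reconstruction to the slide-level class.
  Patch-level results render as a heatmap overlay (M red, D blue, N no
  heat). Models are pluggable; the bundled reference models are small
  scikit-learn MLPs over fixed texture features, trainable in minutes on
  one CPU.
- **Text rules** (`dx_rules`): keyword classification of diagnoses with
  priority M > U > D > N, a sessile-serrated carve-out to N, a
  case-sensitive "NET" rule, organ routing (gastric vs colorectal) from
  specimen headings, and serial-slide aggregation by worst class.
- **QC engine** (`qc`): per-slide concordance comparison with explicit
  statuses (scan failure, unroutable heading, class-U exclusion, missing
  report), a severity-ordered review worklist, and metrics — the 3×3
  confusion matrix, ternary accuracy, NPV = #(dx=N ∧ AI=N)/#(AI=N), and
  binary M vs non-M accuracy/sensitivity/specificity.
- **Synthetic generator** (`synthetic`): deterministic slides with
  procedural class textures, planted lesion polygons, routine artifacts
  (blur, folds, stain shift, air bubbles), diagnosis records including
  injected error styles, multi-slide specimens, and specimen-level
  80/10/10 splitting.

## Worked example

```python
from biopsyqc.synthetic import generate_corpus, split_corpus
from biopsyqc.pipeline import (train_models_on_corpus, patch_holdout_accuracy,
                               predict_manifest_slides, slide_accuracy)

man = generate_corpus(210, seed=11, out_dir="corpus", serial_rate=0.2)
man = split_corpus(man, (0.72, 0.0, 0.28), seed=11)
models = train_models_on_corpus("corpus", man, seed=2, n_patches_per_class=667)

print("patch accuracy:", patch_holdout_accuracy(models, seed=77))
test = man[man.split == "test"]
pred = predict_manifest_slides(models, test)
print("slide accuracy:", slide_accuracy(pred), "on", len(pred), "slides")
```

prints (one run on this corpus):

```
patch accuracy: 0.9833333333333334
slide accuracy: 1.0 on 67 slides
```

i.e. the patch classifier recovers 98.3% of held-out patch labels and the
slide classifier recovers the planted class of all 67 held-out slides.
Classifying a report and aggregating serial slides:

```python
from biopsyqc.dx_rules import classify_dx, aggregate_classes
classify_dx("Tubulovillous adenoma, low to focal high grade dysplasia")  # 'M'
classify_dx("Sessile serrated adenoma/polyp")                            # 'N'
aggregate_classes(["D", "D", "M", "N"])                                  # 'M'
```

The first diagnosis contains low-grade wording but the "high" keyword
forces class M; the serrated polyp contains "adenoma" yet the carve-out
keeps it N; a specimen whose serial slides read D, D, M, N reports the
most serious class.

A CLI mirrors the library (`biopsyqc synth-corpus / train / predict /
classify-dx / qc-run`); `qc-run` exits non-zero when severe (M↔N)
discordances are present.

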