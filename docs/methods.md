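# Methods

## Problem setting

Gastrointestinal endoscopic biopsies are read under the microscope and
signed out; quality control then happens after the fact, classically as a
monthly random review of a small sample of slides. The system implemented
here double-checks *every* slide daily: slides are scanned, classified by
an image model into M / D / N (malignant incl. high-grade dysplasia /
low-grade dysplasia / negative), the free-text report is classified into
M / D / N / U by keyword rules, and disagreements are queued for review
first. The design goal is not diagnostic accuracy superior to the
pathologist but fast detection of *human* errors — missed lesions, omitted
or mistyped diagnosis lines, switched specimens — with a high negative
predictive value so that concordant-negative slides need no further check.

## Image pipeline

**Tiling.** A slide of W×H pixels becomes a ceil(W/256) × ceil(H/256) grid
of half-open, non-overlapping 256×256 tiles; edge tiles are padded white
rather than dropped, so a lesion touching the slide border stays visible.
Tiles, their grid locations and pixel origins are a bijection
(`patch_index = row · n_cols + col`, `x0 = col · 256`) persisted in a
per-slide patch database (CSV) that later also stores the patch-level and
slide-level classification — three layers of information in one table.

**Tissue detection.** A patch is tissue when more than 5% of its pixels
have Rec.601 luma below 230/255. Both numbers are configurable and the
detector can be switched off (every patch classified). Background patches
are skipped by default; their reconstruction cells stay zero.

**Patch classifier.** Pluggable: anything with `fit` / `predict_proba`
over (n, 256, 256, 3) arrays. The bundled reference model extracts a
76-dimensional feature vector per patch — RGB channel means and standard
deviations, dark-pixel fractions at four luma thresholds (nuclear-density
proxies), mean and deviation of the gradient magnitude (chromatin
speckle / edge energy), and an 8×8 block-pooled intensity map — and fits
`StandardScaler + MLPClassifier(hidden=(64,))`. The feature design is what
makes the model light enough to train in minutes on a CPU; a
convolutional network can be dropped in behind the same interface for
clinical-scale images.

**Training conditioning.** Two steps precede fitting: class balancing
(down-sample every class to the minority count, seeded, without
replacement) and loss-based noise removal — fit for `warmup_epochs`
(default 15), compute per-patch cross-entropy, drop the top *q* fraction
(default q = 0.02, allowed range [0, 0.1]), and refit from scratch on the
remainder. The removal schedule is a single round; *q* = 0 disables it.

**Reconstruction and slide classifier.** Each patch's probability vector
is placed at its grid cell, giving an n_rows × n_cols × 3 array;
probabilities are carried through bit-identically (no renormalization),
and placement is order-invariant by construction. Because the slide model
needs a fixed-size input, the grid is centered and zero-padded to 64×64
(grids larger than the target are first area-averaged down by integer
block factors). The zero vector marks background unambiguously: no
probability vector sums to 0. The slide classifier (reference:
`MLPClassifier(hidden=(32,))` on the flattened normalized grid) is trained
on reconstructions produced by the *trained* patch model over the training
slides, so it sees the patch model's real output distribution. Separate
patch+slide pairs are trained per organ route (gastric, colorectal) and a
slide is only ever scored by the model its heading routes to.

**Ties and degenerate inputs.** Probability vectors are ordered (M, D, N),
so an argmax tie breaks toward the clinically more serious class. A slide
with no tissue patches falls back to class N with a `no_tissue` flag. An
unreadable file raises a scan-failure signal; the daily runner retries up
to 3 times before recording `scan_failed`.

**Heatmap.** Per-patch rectangles at a thumbnail scale (default 1/8 of
full resolution; each rectangle is `256 · scale` pixels): red for argmax
M, blue for D, fully transparent for N and background, with configurable
opacity; the RGBA overlay composes over (or toggles off) the thumbnail.

## Text rules

Classification is by ordered keyword phrase lists — M: carcinoma, high,
grade undetermined, grade uncertain, favor neoplastic, sarcoma, lymphoma,
malignant, malignancy, cancer; U: neuroendocrine, carcinoid, NET; D:
dysplasia, adenoma, low, indefinite for dysplasia, undetermined
significance — evaluated M, then U, then the sessile-serrated carve-out
(sessile serrated adenoma/polyp | adenoma | lesion → N), then D; no hit
defaults to N. The table ships as code defaults and loads from YAML so an
institution can extend it.

Matching operates on alphanumeric tokens after collapsing whitespace and
punctuation, case-insensitively. A keyword token may carry the
derivational suffixes "-s" or "-tous" ("carcinomas", "carcinomatous"),
and keywords of ≥ 6 characters also match as the tail of a compound token
("adenocarcinoma", "leiomyosarcoma"). Grading words stay exact: "high"
never fires inside "higher", "low" never inside "yellow". "NET" matches
only as a standalone all-uppercase token. Whether bare "high" should
require a following "grade" is debatable (reports almost always write
"high grade …"); the table keeps the literal keyword "high", and the YAML
config is the place to tighten it.

Serial slides from one paraffin block aggregate by the total order
N < D < U < M — the most serious class wins, never the most frequent —
which makes aggregation commutative, associative and idempotent.

Routing matches heading lines against organ keyword lists (gastric:
stomach, esophagogastric/gastroesophageal junction; colorectal: terminal
ileum, ileocecal valve, cecum, colon, large intestine, rectosigmoid
junction, colon and rectum, rectum). A line matching both lists, lines
matching different organs, or no match at all yield `unrouted`: no image
model runs, and the slide is queued for manual attention instead.

## QC engine

Comparison is **per slide**. The switched-pair error is the reason:
exchange the reports of a D slide and an N slide and both specimens still
aggregate to the same class set, so a specimen-level comparison would see
concordance while both slides are individually wrong. Specimen-level
aggregates are computed and reported, but never suppress a slide-level
discordance.

Statuses: `scan_failed` and `unrouted` take precedence (no AI class
exists); a class-U diagnosis is `excluded_U` (the ternary image model does
not cover neuroendocrine lesions); otherwise equality decides
concordant/discordant. Discordance severity is mapped as M↔N = severe,
M↔D = moderate, D↔N = mild — a package convention, since severity grading
has no universal definition. The worklist orders discordant first (severe
before moderate before mild, then by diagnosis class M > D > N), then
unrouted / missing-report / scan-failed, then concordant; the sort is
stable so ties keep accession order. Reviewer verdict fields
(`dx_correct` / `ai_correct` / `both_wrong` / `unresolved`) support a
false-positive/false-negative export for later retraining; no automatic
retraining loop is included.

Metrics are computed over included records only: ternary accuracy
(confusion-matrix trace / total), NPV = #(dx=N ∧ AI=N) / #(AI=N), and
binary M-vs-non-M accuracy, sensitivity and specificity; exclusion counts
are reported so that included + excluded always equals the number of
input records.

A seven-case reference fixture encodes the per-slide (dx, AI) class pairs
of the error types the system exists to catch — five false negatives, one
false-positive entry error, one switched pair — and the comparator must
flag every case discordant; the switched pair also documents why per-slide
comparison is non-negotiable.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not histology itself. A slide is a white canvas with 3 elliptical tissue
fragments; class textures are procedural (noise + stamped ellipses), with
parameters chosen to make the three classes separable by nuclear density,
color and texture energy: N — light pink stroma, sparse round nuclei,
ring/gland motifs; D — darker stroma, dense elongated dark-blue nuclei;
M — crowded variable-size dark-purple blobs with high-frequency speckle.
Lesions are planted as discs clipped to the tissue geometry; ground-truth
patch labels are *derived from the planted polygons* by the 25%-overlap
rule (a tile is lesion-labeled when ≥ 25% of its area intersects a lesion
polygon; tissue tiles otherwise N; tiles with ≤ 5% tissue are background).
Discs are added, largest-tissue-coverage tiles first with corrective
passes, until the labeled fraction reaches the requested
`lesion_fraction` (default 0.5); across seeds the achieved fraction lands
within ±0.1 of the request.

Artifacts — locally blurred regions, dark fold streaks, stain shifts,
air-bubble discs, each at a default rate of 0.05 expected instances per
grid tile — perturb pixels only and never alter ground-truth labels: the
pipeline is meant to train and predict *through* routine artifacts, not to
re-prepare slides.

Standalone training patches are rendered with the same texture recipes but
realistic *composition*: a lesion patch carries a lesion disc covering
U(0.35, 1) of its area over negative mucosa, and 30% of patches of every
class sit at a tissue edge with white glass beyond. This matters: a tile
cut from a slide is almost never texture-pure, and a model trained on pure
textures misreads a half-covered malignant tile as the intermediate-density
class. Matching the composition distribution is what lifts on-slide patch
accuracy to the level measured on held-out patches.

Diagnosis records use typical wording pools per organ and class, plus
injected error styles: `ambiguous` (hedged wording, same class),
`entry_error` (a spurious "Tubular adenoma, low grade dysplasia" line
appended to a negative report), and a switched pair (two slides' report
texts exchanged). Corpora assign class and organ mixes by largest
remainder at the specimen level; a configurable fraction of specimens
(default 0.2) carries a second serial section sharing the block id and
report text. Splitting operates on blocks, never slides, so serial
sections cannot leak across train/val/test.

Default study scale (chosen once as a desk-scale stand-in for a clinical
corpus): slides of 1280×1024 px (a 5×4 tile grid), 210 specimens split
72/0/28 at block level (~185 training and ~67 held-out slides), patch
models trained on 2,001 rendered patches per organ, and a 60-slide daily
drill batch with 5 injected error slides.

### What the synthetic data does *not* show

Passing on synthetic slides demonstrates that the plumbing — tiling,
probability bookkeeping, reconstruction, routing, comparison, worklists —
is correct and that the learning procedure recovers planted structure. It
says nothing about performance on real H&E tissue: procedural textures are
far more separable than gastritis vs low-grade dysplasia, slides here are
megapixel not gigapixel, there is no staining variation between
laboratories, no pyramid/MIRAX handling, and texture classes are spatially
homogeneous. Clinical accuracy claims require clinical corpora and a
clinical-scale convolutional backbone.

## Numerical and design choices

- Coordinates are 0-based, origin top-left, tiles half-open; traversal
  order never affects results (records sorted by index, reconstruction a
  pure placement).
- Determinism: every stochastic step (generator, balancing, MLP
  initialization) is seeded; identical seeds give bit-identical slides,
  models and predictions on the same machine.
- Probability vectors sum to 1 within 1e-6 (softmax output is used as-is);
  reconstruction cells are exact copies.
- The 25% boundary-labeling rule and the 64×64 normalization target are
  package conventions where no field standard exists; both are parameters.
- The noise-removal step is a deliberately simple single-round top-q
  trim — a placeholder for more elaborate noisy-label schemes.
- Class U has no image model: a U diagnosis excludes the slide from
  comparison rather than forcing a meaningless ternary match.

## Known limitations

- No OpenSlide dependency: PNG/TIFF only out of the box; gigapixel
  pyramidal formats need a user-supplied `SlideRaster` adapter reading
  level 0.
- The reference MLPs are not transferable to real histology; they are the
  test vehicle for the pipeline contracts.
- Severity taxonomy (M↔N severe, M↔D moderate, D↔N mild) is a convention.
- The daily runner ingests a directory snapshot; a production system would
  watch the file system and talk to the laboratory information system.
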