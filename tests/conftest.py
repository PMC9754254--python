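"""Shared fixtures.

The end-to-end fixtures build one synthetic study corpus per session:
210 specimens (serial-section rate 0.2, ~250 slides), specimen-level
split into ~72% training and ~28% held-out slides, and one trained
patch+slide model pair per organ (each patch model fit on 2,001 rendered
patches).  Building them takes several minutes of CPU; every test that
needs trained models shares them.
"""

import pytest

CORPUS_SEED = 11
TRAIN_SEED = 2
N_SPECIMENS = 210
N_PATCHES_PER_CLASS = 667


@pytest.fixture(scope="session")
def study_corpus(tmp_path_factory):
    """Written synthetic corpus with a train/test split at block level."""
    from biopsyqc.synthetic import generate_corpus, split_corpus

    out = tmp_path_factory.mktemp("study_corpus")
    manifest = generate_corpus(N_SPECIMENS, seed=CORPUS_SEED, out_dir=out,
                               serial_rate=0.2)
    manifest = split_corpus(manifest, (0.72, 0.0, 0.28), seed=CORPUS_SEED)
    return out, manifest


@pytest.fixture(scope="session")
def trained_models(study_corpus):
    """Patch + slide model pairs per organ, trained on the training split."""
    from biopsyqc.pipeline import train_models_on_corpus

    corpus_dir, manifest = study_corpus
    return train_models_on_corpus(corpus_dir, manifest, seed=TRAIN_SEED,
                                  n_patches_per_class=N_PATCHES_PER_CLASS)
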