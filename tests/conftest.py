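import numpy as np
import pytest

from sctqa.cascade import TrainConfig, train_cascade
from sctqa.labeling import build_corpus
from sctqa.phantom import PhantomConfig, make_dataset, uniform_mae_sampler

#: desk-scale training recipe for the tiny backbone: higher learning rate
#: and no weight penalties, which the small net needs to converge within a
#: short epoch budget
DESK_RECIPE = dict(
    learning_rate=3e-3,
    l1_weight=0.0,
    l2_weight=0.0,
    batch_size=16,
    max_translation_px=2,
    backbone="tiny",
)


@pytest.fixture(scope="session")
def tiny_cascade():
    """A quickly trained cascade on a small phantom cohort.

    Good enough for structural/routing/persistence checks and coarse
    low-vs-high discrimination; not a converged model.
    """
    pconf = PhantomConfig(shape=(32, 32, 16), modality_style="CBCT")
    pairs, manifest = make_dataset(8, pconf, uniform_mae_sampler(0, 100), seed=11)
    corpus = build_corpus(pairs)
    cfg = TrainConfig(max_epochs=100, seed=3, min_regression_samples=3, **DESK_RECIPE)
    model = train_cascade(corpus, cfg)
    return {"model": model, "pairs": pairs, "corpus": corpus, "cfg": cfg,
            "manifest": manifest, "phantom_config": pconf}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
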