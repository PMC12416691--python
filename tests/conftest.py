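import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phantomqc import learned, rules, synth
from phantomqc.layout import DEFAULT_LAYOUT

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: cell size matching the default 512-pixel canvas
CANVAS = 512
_side = int(0.52 * CANVAS)
CELL = (_side - _side % 4) // 4

TRAIN_PHANTOMS = 100
TRAIN_EPOCHS = 12
TRAIN_SEEDS = (0, 1, 2)


def nominal_spec(**kw) -> synth.PhantomSpec:
    """Fully-visible phantom under mild nominal conditions."""
    defaults = dict(
        lesions=synth.nominal_lesions(DEFAULT_LAYOUT, CELL),
        blur_sigma=0.5,
        noise_sigma=0.005,
        seed=5,
    )
    defaults.update(kw)
    return synth.PhantomSpec(**defaults)


def tile_dataset(n_phantoms: int, seed: int, config=None):
    """Standardized tiles + grades from sampled phantoms (exact-crop
    path; the localization pipeline is exercised separately)."""
    rng = np.random.default_rng(seed)
    config = config or synth.SamplingConfig.easy()
    X, y = [], []
    for _ in range(n_phantoms):
        spec = synth.sample_spec(rng, config)
        tiles, truth = synth.render_subimages(spec)
        X.extend(t.pixels for t in tiles)
        y.extend(truth.scores)
    return np.stack(X), y


@pytest.fixture(scope="session")
def rule_scorer():
    return rules.RuleBasedScorer()


@pytest.fixture(scope="session")
def nominal_render():
    return synth.render_phantom(nominal_spec())


@pytest.fixture(scope="session")
def nominal_tiles():
    tiles, truth = synth.render_subimages(nominal_spec(noise_sigma=0.003))
    return tiles, truth


@pytest.fixture(scope="session")
def trained_models():
    """One classifier per seed, each with its own held-out tile set.

    Trained on low-noise synthetic tiles; shared by the learned-module
    tests and the desk-scale accuracy checks so training cost is paid
    once per seed.
    """
    models = []
    for s in TRAIN_SEEDS:
        X, y = tile_dataset(TRAIN_PHANTOMS, 100 + s)
        clf = learned.DualOutputClassifier(
            epochs=TRAIN_EPOCHS, random_state=s
        ).fit(X, y)
        Xte, yte = tile_dataset(30, 900 + s)
        models.append((clf, Xte, yte))
    return models


@pytest.fixture(scope="session")
def trained_clf(trained_models):
    return trained_models[0][0]
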