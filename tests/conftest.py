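import numpy as np
import pytest

from softspot.images import LabeledImage, SceneConfig, generate_dataset


def make_labeled(pixels, label=0, fruit_id="f0", camera_id="A"):
    """LabeledImage from a raw array, for tests that bypass rendering."""
    pixels = np.asarray(pixels, dtype=float)
    return LabeledImage(pixels, label, np.zeros(pixels.shape[:2], bool),
                        camera_id, fruit_id)


@pytest.fixture(scope="session")
def separable_scene():
    """Scene with strong, large, apically planted blemishes: the classes are
    separable by design, so a small CNN can be trained quickly and reliably."""
    return SceneConfig(image_side=64, blemish_amplitude=0.3,
                       blemish_radius_range=(6, 9),
                       blemish_placement=((1.0, 0.75, 1.0),), seed=7)


@pytest.fixture(scope="session")
def separable_data(separable_scene):
    return generate_dataset(separable_scene, 30, 30, "A", seed=7)


@pytest.fixture(scope="session")
def trained_model(separable_data):
    """A small CNN trained once on the separable scene; reused broadly.
    Training is fully deterministic given the seeds, so the resulting model
    is identical on every run."""
    from softspot import classifier as clf

    tr, va = clf.split_train_val(separable_data, seed=3)
    spec = clf.ModelSpec(input_side=64, block_widths=(8, 16, 32))
    model, curves = clf.train_classifier(
        tr, va, spec, clf.TrainConfig(epochs=40, seed=3))
    return model, tr, va
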