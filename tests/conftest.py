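import numpy as np
import pytest

from mitoseg import pipeline, synthetic, unet


@pytest.fixture(scope="session")
def fragmented_pair():
    """A small fragmented-phenotype image with exact ground truth."""
    spec = synthetic.SynthSpec(height=96, width=96, phenotype="fragmented",
                               n_objects=10, seed=7)
    return synthetic.generate_image(spec)


def make_training_tiles(n_images: int = 12, side: int = 64, seed0: int = 100):
    """Fragmented-phenotype tiles with weight maps, ready for training."""
    tiles = []
    for s in range(n_images):
        spec = synthetic.SynthSpec(height=side, width=side, phenotype="fragmented",
                                   n_objects=8, seed=seed0 + s)
        pair = synthetic.generate_image(spec)
        wm = pipeline.compute_weight_map(pair.mask.astype(np.uint8))
        tiles.append((unet.normalize_intensity(pair.raw), pair.mask, wm.weights))
    return tiles


@pytest.fixture(scope="session")
def trained_tiny_model():
    """A depth-2, 8-filter model trained briefly on easy synthetic blobs.

    Shared across tests that need a model which has actually learned
    something; training is seeded so the fixture is reproducible.
    """
    tiles = make_training_tiles()
    train_t, val_t = pipeline.train_val_split(tiles, pipeline.SplitSpec(seed=0))
    cfg = unet.ModelConfig(depth=2, base_filters=8, input_side=64, epochs=30,
                           batch_size=4, learning_rate=1e-3, seed=0)
    model = unet.build_model(cfg)
    model, history = unet.train(model, train_t, val_t, cfg)
    return model, history
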