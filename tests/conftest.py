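import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Eight 160px phantoms (classes cycled) with letterboxed training targets."""
    from fracdet.data import preprocess
    from fracdet.phantom import PhantomConfig, render_phantom

    cfg = PhantomConfig(image_size=160)
    gen = np.random.default_rng(7)
    items, raw = [], []
    for i in range(8):
        cls = i % 3
        img, lab, _ = render_phantom(cfg, cls, gen)
        chw, _ = preprocess(img, 160)
        box = np.array([lab.to_xyxy(160, 160)])
        items.append((chw, (np.array([cls]), box)))
        raw.append((img, [lab]))
    return items, raw
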