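import numpy as np
import pytest

import contrp

#: short seven-period protocol route used across tests (seconds)
SHORT_ROUTE = (
    ("rest", 30.0), ("city", 30.0), ("highway", 20.0), ("city", 30.0),
    ("highway", 20.0), ("city", 30.0), ("rest", 30.0),
)

#: small architecture whose feature path still exercises all five blocks
TINY_ARCH = contrp.ArchConfig(block_filters=(2, 3, 4, 5, 6))


@pytest.fixture(scope="session")
def short_sim_config():
    return contrp.SimConfig(seed=11, route=SHORT_ROUTE)


@pytest.fixture(scope="session")
def short_recording(short_sim_config):
    return contrp.generate_recording(short_sim_config, "drive99")


@pytest.fixture(scope="session")
def short_dataset(short_sim_config):
    return contrp.make_dataset(3, short_sim_config)


def make_image_samples(n_per_class, side=36, n_recordings=3, seed=0,
                       contrast=2.0):
    """Trivially separable RP-image triples: stressed images carry a large
    mean offset over the relaxed ones, mimicking amplitude-separated Cont-RPs."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(2 * n_per_class):
        label = i % 2
        base = 0.1 + contrast * label
        imgs = [np.abs(base + 0.05 * rng.standard_normal((side, side)))
                for _ in range(3)]
        imgs = [(im + im.T) / 2 for im in imgs]
        samples.append(contrp.SampleTriple(imgs[0], imgs[1], imgs[2], label,
                                           f"rec{(i // 2) % n_recordings}", float(i)))
    return samples
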