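import numpy as np
import pytest

from microcrack3d import CrackSpec, LacunaSpec, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_phantom():
    """A quiet 128^3 phantom with a few cracks and lacunae (shared)."""
    cfg = PhantomConfig(
        shape=(128, 128, 128),
        bvtv=0.20,
        cracks=CrackSpec(
            count=4,
            length_um=(50.0, 90.0),
            width_um=(25.0, 60.0),
            thickness_um=(1.4, 4.2),
            type_weights={"linear": 0.7, "twisted": 0.3},
        ),
        lacunae=LacunaSpec(count=10),
        noise_sigma=0.0,
        ring_amplitude=0.0,
        seed=11,
    )
    vol, truth = generate_phantom(cfg)
    return cfg, vol, truth
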