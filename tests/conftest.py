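import numpy as np
import pytest

import ctradial as ct


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, unblurred scene with one green territory at f=0.6 along
    an in-plane axis; rendering is deterministic, so session scope is safe."""
    params = ct.SceneParams(
        psf_sigma=(0.0, 0.0, 0.0),
        noise_model="none",
        background_level=0.0,
        territories=(
            ct.TerritorySpec(
                channel="green",
                fractional_radial_position=0.6,
                direction=(0.0, 1.0, 0.0),
            ),
        ),
        seed=1,
    )
    scene, truth = ct.render_scene(params)
    return params, scene, truth


@pytest.fixture(scope="session")
def default_scene():
    """Scene at default blur/noise with a green and a red territory."""
    params = ct.SceneParams(
        territories=(
            ct.TerritorySpec(channel="green", fractional_radial_position=0.6),
            ct.TerritorySpec(channel="red", fractional_radial_position=0.3),
        ),
        seed=7,
    )
    scene, truth = ct.render_scene(params)
    return params, scene, truth


@pytest.fixture(scope="session")
def expression_table():
    return ct.simulate_expression(ct.ExpressionSimParams(seed=3))


@pytest.fixture()
def toy_table():
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "chromosome": ["chrA"] * 3 + ["chrB"] * 3,
            "fpkm_glass": [0.5, 1.0, 2.0, 5.0, 8.0, 0.2],
            "fpkm_2kPa": [0.5, 4.0, 2.0, 5.0, 1.0, 0.2],
            "log2fc_2kPa": [0.0, 2.0, -1.9, -2.0, -3.0, 0.1],
        }
    )
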