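import numpy as np
import pytest

from paddytiller.synthetic import SceneSpec, generate_scene


def tiny_plot_spec(seed: int) -> SceneSpec:
    """A 64×64 two-hill plot: desk-scale scenes for network tests."""
    return SceneSpec(
        seed=seed,
        plot_rows=1,
        plot_cols=2,
        plot_width_cm=9.6,
        plot_height_cm=9.6,
        tiller_range=(2, 8),
        area_per_tiller=30.0,
        leaf_length_range=(4, 10),
        leaf_width_range=(2, 3),
        n_water_patches=1,
        n_speculars=1,
    )


@pytest.fixture(scope="session")
def tiny_scenes():
    """Five deterministic 64×64 scenes with ground truth."""
    return [generate_scene(tiny_plot_spec(i)) for i in range(5)]


@pytest.fixture(scope="session")
def default_scene():
    """One full-size (600×800) breeding-plot scene."""
    return generate_scene(SceneSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
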