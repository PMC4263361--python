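import numpy as np
import pytest

from colonymorph import synthetic


@pytest.fixture
def disc_mask():
    """Rasterized disc of radius 100 px as a ColonyMask."""
    from skimage import draw

    from colonymorph.masks import ColonyMask

    grid = np.zeros((240, 240), dtype=bool)
    rr, cc = draw.disk((120, 120), 100)
    grid[rr, cc] = True
    return ColonyMask(grid)


def spoked_scene(spoke_count: int, seed: int, noise_sd: float = 6.0,
                 amplitude: float = 0.2) -> synthetic.SceneSpec:
    """A colony with a known number of radial spokes on a standard plate."""
    spokes = (
        synthetic.SpokeSpec(spoke_count=spoke_count, spoke_amplitude=amplitude,
                            radial_band=(25.0, 105.0))
        if spoke_count
        else synthetic.SpokeSpec()
    )
    return synthetic.SceneSpec(
        shape=(360, 360),
        plate_radius=165.0,
        petals=synthetic.PetalSpec(base_radius=110.0),
        spokes=spokes,
        noise_sd=noise_sd,
        seed=seed,
    )
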