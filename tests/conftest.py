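import numpy as np
import pytest

from kinquant import OpticsModel, VoxelGrid, render_focus


@pytest.fixture
def default_optics() -> OpticsModel:
    return OpticsModel()


@pytest.fixture
def quiet_optics() -> OpticsModel:
    """Camera model with all noise sources disabled."""
    return OpticsModel(photon_noise=False, read_noise_sd=0.0)


def make_focus_grid(shape=(17, 48, 48), center=None, photons=5000.0,
                    sigma_xy=0.12, sigma_z=0.35, background=0.0) -> VoxelGrid:
    """Noiseless grid with a single rendered focus."""
    grid = VoxelGrid(np.full(shape, float(background)))
    if center is None:
        center = tuple(s // 2 for s in shape)
    render_focus(grid, center, photons, sigma_xy, sigma_z)
    return grid


@pytest.fixture
def focus_grid() -> VoxelGrid:
    return make_focus_grid()
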