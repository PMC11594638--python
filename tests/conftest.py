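import warnings

import numpy as np
import pytest

from pvsmap.image import ImageVolume
from pvsmap.phantom import (
    PhantomSpec,
    generate_atlas,
    generate_lesion_masks,
    generate_pvs_tubes,
    render_sequences,
)
from pvsmap.vesselness import FrangiParams, multiscale_max


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One noiseless 64^3 phantom with supra-voxel tubes, plus its vesselness
    maps — shared across tests because the Frangi pass is the slow part."""
    spec = PhantomSpec(
        noise_sigma=0.0,
        tube_radius_mm_range=(1.0, 1.5),
        pvs_density_per_region={"wm": 14.0, "bg": 4.0, "bs": 2.0},
        seed=11,
    )
    atlas = generate_atlas(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = generate_pvs_tubes(spec, atlas)
    wmh, lacunes = generate_lesion_masks(spec, atlas)
    t2, flair = render_sequences(spec, atlas, truth, wmh, lacunes)
    v_t2 = multiscale_max(t2, FrangiParams())
    v_flair = multiscale_max(flair, FrangiParams(polarity="dark"))
    return dict(
        spec=spec, atlas=atlas, truth=truth, wmh=wmh, lacunes=lacunes,
        t2=t2, flair=flair, v_t2=v_t2, v_flair=v_flair,
    )


def make_tube_volume(n=33, radius_mm=1.5, voxel_mm=0.9, intensity=100.0, axis=2):
    """Solid bright cylinder through the grid center along the given axis."""
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2
    perp = [a for a in range(3) if a != axis]
    r2 = sum(((idx[a] - c) * voxel_mm) ** 2 for a in perp)
    data = (r2 <= radius_mm**2).astype(float) * intensity
    return ImageVolume(data, (voxel_mm,) * 3)


@pytest.fixture
def tube_volume():
    return make_tube_volume()
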