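import warnings

import numpy as np
import pytest

from mammocalc.synthetic import PhantomSpec, Speck, make_phantom
from mammocalc.types import BreastMask, CandidateSpot, MammogramImage

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def speck_phantom():
    """Small phantom with 10 isolated bright specks and a faint noise floor."""
    spec = PhantomSpec(
        shape_px=(512, 384),
        poisson_scale=0.0,
        gaussian_sd=1.0,
        texture_amplitude=0.0,
        specks=[
            Speck(center_mm=(8 + 3 * (i // 5), 1.5 + 2 * (i % 5)), diameter_mm=0.4, amplitude=150)
            for i in range(10)
        ],
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at default film-noise levels with one 4-speck cluster."""
    centers = [(12.0, 6.0), (13.5, 7.0), (11.0, 7.5), (12.5, 5.0)]
    spec = PhantomSpec(
        shape_px=(512, 384),
        specks=[Speck(center_mm=c, diameter_mm=0.35, amplitude=140) for c in centers],
        seed=11,
    )
    return make_phantom(spec)


def make_spot(row, col, area=4, ecc=0.2, coords=None):
    coords = coords if coords is not None else np.array([[int(row), int(col)]])
    return CandidateSpot(
        centroid_rc=(float(row), float(col)),
        area_px=area,
        eccentricity=ecc,
        major_axis_px=2.0,
        minor_axis_px=1.5,
        mean_response=0.5,
        blobness=0.8,
        coords=np.asarray(coords),
    )


@pytest.fixture
def full_mask():
    return BreastMask(np.ones((128, 128), dtype=bool))


@pytest.fixture
def flat_image():
    return MammogramImage(np.full((128, 128), 50.0), spacing_mm=0.05)
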