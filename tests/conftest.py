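"""Shared fixtures: small phantoms sized for fast desk-scale testing."""

import numpy as np
import pytest
from scipy import ndimage

import wbatlas as w


@pytest.fixture(scope="session")
def small_acq():
    """Noisy 3-station acquisition on a small grid."""
    return w.AcquisitionSpec(
        stations=3, slices_per_station=16, overlap_slices=2, noise_sigma=2.0
    )


@pytest.fixture(scope="session")
def clean_acq():
    """Noiseless unit-gain acquisition for forward/inverse checks."""
    return w.AcquisitionSpec(
        stations=2,
        slices_per_station=12,
        overlap_slices=2,
        noise_sigma=0.0,
        station_gain=1.0,
    )


@pytest.fixture(scope="session")
def clean_subject(clean_acq):
    return w.make_subject(acq=clean_acq, shape_xy=(24, 18), seed=1, wf_noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_subject(small_acq):
    return w.make_subject(acq=small_acq, shape_xy=(32, 24), seed=5)


def make_textured_phantom(shape=(40, 40, 40), spacing=(3.0, 3.0, 3.0), seed=3):
    """Ellipsoid body with smooth random texture and one bright inclusion.

    Texture makes the deformation observable everywhere inside the body,
    so field-recovery benchmarks are well-posed.
    """
    x, y, z = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    cx, cy, cz = [(n - 1) / 2 for n in shape]
    body = ((x - cx) / 14.0) ** 2 + ((y - cy) / 12.0) ** 2 + ((z - cz) / 16.0) ** 2 <= 1
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.normal(0, 1, shape), 2.0)
    tex = 40.0 * tex / tex.std()
    img = body * (100.0 + tex)
    img += (((x - 15) / 4.0) ** 2 + ((y - cy) / 4.0) ** 2 + ((z - 16) / 5.0) ** 2 <= 1) * 150
    img = ndimage.gaussian_filter(img, 1.0)
    return w.Volume(values=img, spacing=spacing), body
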