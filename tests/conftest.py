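"""Shared fixtures: one reduced-scale instrument simulated once per session."""

import numpy as np
import pytest

from flfm import (CalibrationResult, PhantomSpec, Volume, compute_psf,
                  desk_scale_config, forward_project, make_phantom)
from flfm.optics import psf_views


@pytest.fixture(scope="session")
def cfg():
    return desk_scale_config()


@pytest.fixture(scope="session")
def psf(cfg):
    return compute_psf(cfg)


@pytest.fixture(scope="session")
def cal(cfg):
    return CalibrationResult.from_config(cfg)


@pytest.fixture(scope="session")
def cal64(cfg):
    """Smaller 64 px view windows used by the training-scale tests."""
    return CalibrationResult.from_config(cfg, view_size=(64, 64))


@pytest.fixture(scope="session")
def kernels(psf, cal):
    return psf_views(psf, cal)


@pytest.fixture(scope="session")
def voxel_nm(cfg):
    return (cfg.depth_step_um * 1e3, cfg.lateral_sampling_nm,
            cfg.lateral_sampling_nm)


@pytest.fixture(scope="session")
def bead_volume(cfg, voxel_nm):
    """Three well-separated sub-diffraction beads on the native grid."""
    spec = PhantomSpec(kind="beads", count=3, shape=(41, 64, 64),
                       voxel_size_nm=voxel_nm, bead_diameter_nm=260.0,
                       bead_min_separation_nm=3000.0, seed=0)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def bead_lf(bead_volume, psf):
    return forward_project(bead_volume, psf)


@pytest.fixture(scope="session")
def tube_lf(cfg, psf, cal, voxel_nm):
    """Panel of the three clean views of a hollow-tube phantom, used as
    the reference image for noise fitting."""
    from flfm import LFImage, extract_views
    spec = PhantomSpec(kind="hollow_tubes", count=3, shape=(41, 64, 64),
                       voxel_size_nm=voxel_nm, seed=4)
    vol = make_phantom(spec)
    views = extract_views(forward_project(vol, psf), cal)
    return LFImage(np.hstack(list(views.data)))


def true_bead_centers(volume: Volume) -> np.ndarray:
    from scipy import ndimage
    lab, n = ndimage.label(volume.data > 0.5 * volume.data.max())
    return np.asarray(ndimage.center_of_mass(volume.data, lab,
                                             range(1, n + 1)))
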