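import numpy as np
import pytest

from phagenuc.segment import CellROI, long_axis
from phagenuc.synth import CellSpec, OpticsModel, SceneSpec, render_scene

PX_NM = 65.0  # default pixel size used throughout the fixtures


@pytest.fixture
def single_cell_scene():
    """Factory for one-cell scenes: (image, truth, spec)."""

    def _make(
        phenotype="uniform",
        contrast=None,
        infected=True,
        psf_px=2.0,
        noise=False,
        seed=0,
        shape=(60, 80),
        center=(30.0, 40.0),
        **cell_kw,
    ):
        if contrast is None:
            contrast = {"imported": 3.0, "excluded": 0.2, "uniform": 1.0}[phenotype]
        optics = OpticsModel(psf_sigma_nm=PX_NM * psf_px, noise=noise)
        cell = CellSpec(
            center=center,
            phenotype=phenotype,
            gfp_contrast=contrast,
            infected=infected,
            **cell_kw,
        )
        spec = SceneSpec(image_shape=shape, cells=[cell], optics=optics, seed=seed)
        image, truth = render_scene(spec)
        return image, truth, spec

    return _make


@pytest.fixture
def roi_from_truth():
    """Build a CellROI (with fitted axis) from rendered ground truth."""

    def _make(truth, cell_id=1, infected=True):
        mask = truth.mask(cell_id)
        rows, cols = np.nonzero(mask)
        roi = CellROI(
            cell_id=cell_id,
            mask=mask,
            centroid=(float(rows.mean()), float(cols.mean())),
            infected=infected,
        )
        long_axis(roi)
        return roi

    return _make


def rect_mask(shape, r0, r1, c0, c1):
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask
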