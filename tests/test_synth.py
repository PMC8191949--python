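"""Scene generator: geometry, noise model, determinism, population mixes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagenuc.errors import ConfigError, GeometryError, OverlapError
from phagenuc.synth import (
    CellSpec,
    OpticsModel,
    SceneSpec,
    make_population,
    read_scene,
    read_truth,
    render_scene,
    rle_decode,
    rle_encode,
    write_scene,
)


def test_noiseless_sharp_uniform_cell_is_flat(single_cell_scene):
    """psf=0, no noise, uniform cell: GFP constant on the mask, offset outside."""
    image, truth, spec = single_cell_scene(phenotype="uniform", psf_px=0.0, infected=False)
    offset = spec.optics.camera_offset
    mask = truth.mask(1)
    on = image[0][mask]
    assert np.allclose(on, on[0]) and on[0] > offset
    assert np.allclose(image[0][~mask], offset)


def test_render_is_deterministic():
    spec = make_population(6, {"imported": 0.5, "excluded": 0.5}, seed=7)
    img_a, truth_a = render_scene(spec)
    img_b, truth_b = render_scene(spec)
    assert np.array_equal(img_a, img_b)
    assert np.array_equal(truth_a.label_image, truth_b.label_image)


def test_excluded_contrast_recovered_within_psf_bleed(single_cell_scene):
    """Rendered nucleus/cytoplasm GFP ratio ~ gfp_contrast; bleed bounded.

    The emitter disk has a hard edge, so Gaussian blur mixes the classes in
    a ring of width ~2 sigma; the tolerance is that ring's area fraction
    (computed from the rendered ground truth) times the density step.
    """
    contrast = 0.1
    for psf_px in (0.0, 0.5, 1.0):
        image, truth, spec = single_cell_scene(
            phenotype="excluded", contrast=contrast, psf_px=psf_px
        )
        gfp = image[0] - spec.optics.camera_offset
        nuc = truth.nucleus_mask(1)
        cyto = truth.mask(1) & ~nuc
        ratio = gfp[nuc].mean() / gfp[cyto].mean()
        if psf_px == 0.0:
            assert ratio == pytest.approx(contrast, rel=1e-9)
        else:
            rows, cols = np.nonzero(nuc)
            radius = np.sqrt(nuc.sum() / np.pi)
            ring_frac = min(1.0, 2.0 * np.pi * radius * 2.0 * psf_px / nuc.sum())
            tol = (1.0 - contrast) * ring_frac * 0.5
            assert abs(ratio - contrast) <= tol


def test_interior_contrast_nearly_exact_after_blur(single_cell_scene):
    """Away from the disk edge the contrast survives a 1 px PSF almost exactly."""
    from scipy import ndimage as ndi

    image, truth, spec = single_cell_scene(phenotype="imported", contrast=3.0, psf_px=1.0)
    gfp = image[0] - spec.optics.camera_offset
    nuc_in = ndi.binary_erosion(truth.nucleus_mask(1), iterations=3)
    cyto = ndi.binary_erosion(truth.mask(1), iterations=3) & ~ndi.binary_dilation(
        truth.nucleus_mask(1), iterations=3
    )
    assert gfp[nuc_in].mean() / gfp[cyto].mean() == pytest.approx(3.0, rel=0.05)


def test_poisson_photon_statistics():
    """With read noise off, per-pixel variance over repeated renders ~ mean."""
    optics = OpticsModel(read_noise_sd=0.0, camera_offset=0.0, psf_sigma_nm=0.0)
    cell = CellSpec(center=(16.0, 24.0), length_um=2.0, infected=False)
    samples = []
    for seed in range(600):
        spec = SceneSpec(image_shape=(32, 48), cells=[cell], optics=optics, seed=seed)
        image, _ = render_scene(spec)
        samples.append(float(image[0][16, 24]))  # a cytoplasm pixel
    samples = np.array(samples)
    assert samples.var() == pytest.approx(samples.mean(), rel=0.10)


def test_photon_scale_linearity():
    """Doubling photon_scale doubles the background-subtracted cell mean."""
    means = []
    for scale in (400.0, 800.0):
        optics = OpticsModel(photon_scale=scale)
        cell = CellSpec(center=(30.0, 40.0))
        image, truth = render_scene(
            SceneSpec(image_shape=(60, 80), cells=[cell], optics=optics, seed=11)
        )
        means.append(image[0][truth.mask(1)].mean() - optics.camera_offset)
    assert means[1] / means[0] == pytest.approx(2.0, rel=0.02)


def test_membrane_channel_is_cell_outline(single_cell_scene):
    image, truth, spec = single_cell_scene(psf_px=0.0, infected=False)
    from scipy import ndimage as ndi

    mask = truth.mask(1)
    outline = mask & ~ndi.binary_erosion(mask)
    mem = image[2] - spec.optics.camera_offset
    assert (mem[outline] > 0).all()
    assert np.allclose(mem[ndi.binary_erosion(mask, iterations=2)], 0.0)


def test_uninfected_cell_has_no_nucleus_in_any_channel(single_cell_scene):
    image, truth, spec = single_cell_scene(
        phenotype="uniform", infected=False, psf_px=0.0
    )
    assert not truth.nucleus_mask(1).any()
    for ch in range(2):  # GFP and DAPI flat inside the cell
        vals = image[ch][truth.mask(1)]
        assert np.allclose(vals, vals[0])


def test_overlapping_cells_raise():
    cells = [CellSpec(center=(30.0, 40.0)), CellSpec(center=(32.0, 42.0))]
    spec = SceneSpec(image_shape=(60, 80), cells=cells, optics=OpticsModel(noise=False))
    with pytest.raises(OverlapError):
        render_scene(spec)


def test_out_of_bounds_cell_raises():
    spec = SceneSpec(
        image_shape=(40, 40),
        cells=[CellSpec(center=(5.0, 20.0))],
        optics=OpticsModel(noise=False),
    )
    with pytest.raises(GeometryError):
        render_scene(spec)


def test_cellspec_invariants():
    with pytest.raises(ConfigError):
        CellSpec(center=(0, 0), length_um=0.5, width_um=1.0)  # not a rod
    with pytest.raises(ConfigError):
        CellSpec(center=(0, 0), nucleus_radius_frac=0.0)
    with pytest.raises(ConfigError):
        CellSpec(center=(0, 0), nucleus_axial_pos=1.5)


def test_every_labeled_pixel_belongs_to_one_cell():
    spec = make_population(12, {"uniform": 1.0}, seed=3)
    _, truth = render_scene(spec)
    per_cell = sum(int(truth.mask(c.cell_id).sum()) for c in truth.cells)
    assert per_cell == int((truth.label_image > 0).sum())
    assert sorted(np.unique(truth.label_image)) == list(range(0, 13))


class TestMakePopulation:
    def test_degenerate_mix_all_excluded(self):
        spec = make_population(10, {"excluded": 1.0}, seed=1)
        assert [c.phenotype for c in spec.cells] == ["excluded"] * 10

    def test_mix_counts_recorded_and_reproducible(self):
        """A 115-cell 50/50 two-population mixture, as for a mixed mutant."""
        spec_a = make_population(115, {"imported": 0.5, "excluded": 0.5}, seed=9)
        spec_b = make_population(115, {"imported": 0.5, "excluded": 0.5}, seed=9)
        counts = {ph: sum(c.phenotype == ph for c in spec_a.cells) for ph in ("imported", "excluded")}
        assert counts["imported"] + counts["excluded"] == 115
        assert abs(counts["imported"] - 57.5) <= 0.5  # largest-remainder split
        assert [c.phenotype for c in spec_a.cells] == [c.phenotype for c in spec_b.cells]
        _, truth = render_scene(spec_a)
        assert truth.phenotype_counts == counts

    def test_bad_fractions_raise(self):
        with pytest.raises(ConfigError):
            make_population(5, {"imported": 0.5, "excluded": 0.6}, seed=0)
        with pytest.raises(ConfigError):
            make_population(5, {"sideways": 1.0}, seed=0)
        with pytest.raises(ConfigError):
            make_population(0, {"imported": 1.0}, seed=0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=0, max_size=64), st.integers(1, 8))
def test_rle_roundtrip(bits, width):
    rows = max(1, (len(bits) + width - 1) // width)
    mask = np.zeros(rows * width, dtype=bool)
    mask[: len(bits)] = bits
    mask = mask.reshape(rows, width)
    assert np.array_equal(rle_decode(rle_encode(mask), mask.shape), mask)


def test_scene_yaml_roundtrip(tmp_path):
    spec = make_population(4, {"imported": 1.0}, seed=2)
    path = tmp_path / "scene.yaml"
    spec.to_yaml(path)
    back = SceneSpec.from_yaml(path)
    assert back == spec


def test_scene_tiff_and_truth_roundtrip(tmp_path, single_cell_scene):
    image, truth, _ = single_cell_scene(phenotype="excluded", noise=True)
    tiff, sidecar = write_scene(tmp_path, "s", image.astype(np.uint16), truth)
    assert np.array_equal(read_scene(tiff), image.astype(np.uint16))
    back = read_truth(sidecar)
    assert np.array_equal(back.label_image, truth.label_image)
    assert np.array_equal(back.nucleus_label, truth.nucleus_label)
    assert back.cells[0].phenotype == truth.cells[0].phenotype
    assert back.cells[0].axis_p0 == pytest.approx(truth.cells[0].axis_p0)
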