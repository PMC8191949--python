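"""Axial profiles: extraction, normalization, classification, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagenuc.errors import (
    EmptyPopulationError,
    EnsembleError,
    NormalizationError,
    ProfileError,
)
from phagenuc.pipeline import RunConfig, analyze_image, build_scene
from phagenuc.profiles import (
    AxialProfile,
    PhenotypeCall,
    average_profiles,
    classify_localization,
    extract_profile,
    normalize_profile,
    orient_profiles,
    population_fractions,
)
from phagenuc.segment import CellROI


def _line_roi(shape, p0, p1):
    mask = np.ones(shape, dtype=bool)
    return CellROI(
        cell_id=1,
        mask=mask,
        centroid=((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2),
        axis_p0=p0,
        axis_p1=p1,
        length_px=float(np.hypot(p1[0] - p0[0], p1[1] - p0[1])),
    )


def _profile(values, cell_id=1):
    values = np.asarray(values, dtype=float)
    return AxialProfile(
        cell_id=cell_id,
        positions=np.linspace(0, 1, values.size),
        values_raw=values,
    )


class TestExtract:
    def test_constant_image(self):
        roi = _line_roi((20, 20), (10.0, 2.0), (10.0, 17.0))
        p = extract_profile(np.full((20, 20), 100.0), roi, n_points=11)
        assert np.allclose(p.values_raw, 100.0)
        assert p.positions[0] == 0.0 and p.positions[-1] == 1.0
        assert np.all(np.diff(p.positions) > 0)

    def test_ramp_image_bilinear(self):
        """I(col) = col sampled on a horizontal axis gives 0, 1, ..., 10."""
        img = np.tile(np.arange(20.0), (20, 1))
        roi = _line_roi((20, 20), (5.0, 0.0), (5.0, 10.0))
        p = extract_profile(img, roi, n_points=11)
        assert np.allclose(p.values_raw, np.arange(11.0))

    def test_line_width_averages_perpendicular(self):
        img = np.tile(np.arange(20.0)[:, None], (1, 20))  # ramp along rows
        roi = _line_roi((20, 20), (10.0, 2.0), (10.0, 17.0))
        p = extract_profile(img, roi, n_points=5, line_width=3)
        # offsets -1, 0, +1 rows average back to the center row value
        assert np.allclose(p.values_raw, 10.0)

    def test_short_axis_raises(self):
        roi = _line_roi((20, 20), (10.0, 9.0), (10.0, 10.0))
        with pytest.raises(ProfileError):
            extract_profile(np.zeros((20, 20)), roi)

    def test_imported_cell_peaks_centrally(self, single_cell_scene, roi_from_truth):
        image, truth, _ = single_cell_scene(phenotype="imported", contrast=3.0)
        roi = roi_from_truth(truth)
        p = extract_profile(image[0], roi, pole_margin_px=roi.width_estimate() / 2)
        peak = p.positions[int(np.argmax(p.values_raw))]
        assert abs(peak - 0.5) <= 0.1


class TestNormalize:
    def test_constant_profile_normalizes_to_one(self):
        p = normalize_profile(_profile([7.0] * 11))
        assert np.allclose(p.values_norm, 1.0)

    def test_single_point_anchor_division(self):
        p = normalize_profile(_profile([100, 150, 200, 150, 100]), anchor_frac=0.01)
        assert p.anchor == 100.0
        assert np.allclose(p.values_norm, [1.0, 1.5, 2.0, 1.5, 1.0])

    def test_anchor_window_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        p = normalize_profile(_profile(rng.uniform(50, 150, 101)), anchor_frac=0.05)
        m = int(np.ceil(0.05 * 101))
        assert p.values_norm[:m].mean() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p.values_norm * p.anchor, p.values_raw)

    def test_nonpositive_anchor_raises(self):
        with pytest.raises(NormalizationError):
            normalize_profile(_profile([0.0] * 11))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1000.0))
    def test_gain_invariance(self, gain):
        base = np.array([100, 150, 200, 150, 100, 90, 110], dtype=float)
        p1 = normalize_profile(_profile(base))
        p2 = normalize_profile(_profile(base * gain))
        assert np.allclose(p1.values_norm, p2.values_norm)
        c1 = classify_localization(p1)
        c2 = classify_localization(p2)
        assert c1.score == pytest.approx(c2.score) and c1.call == c2.call


class TestClassify:
    def test_flat_profile_is_mixed(self):
        call = classify_localization(normalize_profile(_profile([1.0] * 101)))
        assert call.score == pytest.approx(1.0)
        assert call.call == "mixed_ambiguous"

    @pytest.mark.parametrize(
        "phenotype, contrast, expected",
        [("imported", 3.0, "imported"), ("excluded", 0.2, "excluded")],
    )
    def test_noiseless_cells_called_correctly(
        self, single_cell_scene, roi_from_truth, phenotype, contrast, expected
    ):
        image, truth, _ = single_cell_scene(phenotype=phenotype, contrast=contrast)
        roi = roi_from_truth(truth)
        p = extract_profile(image[0], roi, pole_margin_px=roi.width_estimate() / 2)
        call = classify_localization(normalize_profile(p))
        assert call.call == expected

    def test_reversal_invariance(self):
        values = np.array([90, 100, 130, 180, 150, 120, 95, 100, 105], dtype=float)
        fwd = classify_localization(normalize_profile(_profile(values)))
        rev = classify_localization(normalize_profile(_profile(values[::-1])))
        assert fwd.score == pytest.approx(rev.score)
        assert fwd.call == rev.call


class TestOrient:
    def test_monotone_profile_reversed_when_enabled(self):
        p = normalize_profile(_profile(np.arange(1.0, 12.0)))
        before = p.values_raw.copy()
        orient_profiles([p], brighter_end_first=True)
        assert np.allclose(p.values_raw, before[::-1])

    def test_symmetric_profile_unchanged(self):
        vals = np.array([1, 2, 3, 2, 1], dtype=float)
        p = normalize_profile(_profile(vals))
        orient_profiles([p], brighter_end_first=True)
        assert np.allclose(p.values_raw, vals)

    def test_disabled_by_default(self):
        p = normalize_profile(_profile(np.arange(1.0, 12.0)))
        before = p.values_raw.copy()
        orient_profiles([p])
        assert np.allclose(p.values_raw, before)


class TestAverage:
    def test_single_member(self):
        p = normalize_profile(_profile([100, 120, 140, 120, 100]))
        ens = average_profiles([p])
        assert np.allclose(ens.mean, p.values_norm)
        assert np.allclose(ens.sd, 0.0)
        assert ens.n == 1

    def test_symmetric_pair_averages_to_baseline(self):
        a = _profile([1.0, 2.0, 1.0])
        b = _profile([1.0, 0.0, 1.0])
        for p in (a, b):
            p.values_norm = p.values_raw.copy()
        ens = average_profiles([a, b])
        assert np.allclose(ens.mean, 1.0)

    def test_mismatched_lengths_raise(self):
        a = normalize_profile(_profile([1.0] * 5))
        b = normalize_profile(_profile([1.0] * 7))
        with pytest.raises(EnsembleError):
            average_profiles([a, b])

    def test_balanced_mixture_centers_near_baseline(self):
        """50/50 imported/excluded at matched |log contrast|: central mean ~ 1."""
        config = RunConfig(
            seed=21,
            n_cells=60,
            phenotype_mix={"imported": 0.5, "excluded": 0.5},
            contrasts={"imported": 1.25, "excluded": 0.8},
        )
        image, _ = build_scene(config)
        res = analyze_image(image, config)
        ens = average_profiles(res["profiles"])
        center = np.abs(ens.positions - 0.5) <= 0.1
        sem = ens.sd[center].mean() / np.sqrt(ens.n)
        assert abs(ens.mean[center].mean() - 1.0) <= 2 * sem + 0.02


class TestFractions:
    def _calls(self, spec_counts):
        calls = []
        i = 0
        for name, k in spec_counts.items():
            for _ in range(k):
                i += 1
                calls.append(PhenotypeCall(cell_id=i, score=1.0, call=name, t_hi=1.2, t_lo=0.8))
        return calls

    def test_all_excluded(self):
        out = population_fractions(self._calls({"excluded": 177}))
        assert out == {"n": 177, "imported": 0.0, "excluded": 1.0, "mixed_ambiguous": 0.0}

    def test_all_imported(self):
        out = population_fractions(self._calls({"imported": 111}))
        assert out["imported"] == 1.0 and out["n"] == 111

    def test_even_split(self):
        out = population_fractions(self._calls({"imported": 1, "excluded": 1}))
        assert out["imported"] == 0.5 and out["excluded"] == 0.5
        assert out["imported"] + out["excluded"] + out["mixed_ambiguous"] == 1.0

    def test_empty_raises(self):
        with pytest.raises(EmptyPopulationError):
            population_fractions([])
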