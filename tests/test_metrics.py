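"""Placental metric suite: volume, histogram shape, morphology, thickness."""

import numpy as np
import pytest
from scipy import stats

from placenta_t2star import EchoTrain, PlacentaMask
from placenta_t2star.metrics import (
    compute_all,
    compute_volume,
    histogram_stats,
    max_thickness,
    morphological_map,
    non_uniformity,
)
from placenta_t2star.relaxometry import T2StarMap

from conftest import brute_force_distance_map


def t2map_from(values: np.ndarray, dims=(2.5, 2.5, 2.5)) -> T2StarMap:
    values = np.asarray(values, float)
    valid = np.isfinite(values)
    return T2StarMap(
        t2star_ms=values,
        s0=np.where(valid, 1000.0, np.nan),
        fit_quality=np.where(valid, 1.0, np.nan),
        valid=valid,
        non_decaying=np.zeros_like(valid),
        voxel_dims_mm=dims,
        echo_train=EchoTrain("custom", (10.0, 20.0)),
    )


def box_mask(shape, box, dims=(2.5, 2.5, 2.5)) -> PlacentaMask:
    data = np.zeros(shape)
    data[box] = 1
    return PlacentaMask(data, dims)


class TestVolume:
    def test_thousand_voxels_at_2p5mm(self):
        mask = box_mask((12, 12, 12), (slice(1, 11), slice(1, 11), slice(1, 11)))
        assert mask.n_voxels == 1000
        assert compute_volume(mask) == pytest.approx(15.625)

    def test_single_voxel_at_3mm(self):
        mask = box_mask((5, 5, 5), (2, 2, 2), dims=(3.0, 3.0, 3.0))
        assert compute_volume(mask) == pytest.approx(0.027)

    def test_volume_is_exact_count_times_voxel(self, rng):
        data = (rng.random((10, 10, 10)) > 0.6).astype(int)
        data[0, 0, 0] = 1
        mask = PlacentaMask(data, (3.1, 3.1, 3.1))
        assert compute_volume(mask) == mask.n_voxels * 3.1**3 / 1000.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_volume(PlacentaMask(np.zeros((4, 4, 4)), (1, 1, 1)))


class TestHistogramStats:
    def test_constant_sample_degenerate_convention(self):
        vals = np.full((4, 4, 4), 110.0)
        mask = box_mask((4, 4, 4), (slice(None),) * 3)
        mean, skew, kurt, n, degenerate = histogram_stats(t2map_from(vals), mask)
        assert mean == 110.0
        assert skew == 0.0 and kurt == 0.0
        assert degenerate

    def test_symmetric_distribution_zero_skew(self):
        lo = np.linspace(100.0, 145.0, 32)
        vals = np.concatenate([lo, (300.0 - lo)])  # mirror about 150
        arr = np.full((4, 4, 4), np.nan)
        arr.ravel()[: vals.size] = vals
        mask = box_mask((4, 4, 4), (slice(None),) * 3)
        mean, skew, _, n, _ = histogram_stats(t2map_from(arr), mask)
        assert mean == pytest.approx(150.0)
        assert skew == pytest.approx(0.0, abs=1e-9)
        assert n == 64

    def test_normal_sample_has_zero_excess_kurtosis(self, rng):
        """10,000 normal draws: excess kurtosis within 0.1 of the
        normal's value (0), skewness near 0."""
        draws = 200.0 + rng.standard_normal(10_000)
        arr = draws.reshape(25, 25, 16)
        mask = box_mask(arr.shape, (slice(None),) * 3)
        mean, skew, kurt, _, degenerate = histogram_stats(t2map_from(arr), mask)
        assert not degenerate
        assert mean == pytest.approx(200.0, abs=0.05)
        assert abs(kurt) < 0.1
        assert abs(skew) < 0.1

    def test_invalid_voxels_excluded_and_counted(self):
        arr = np.full((3, 3, 3), 100.0)
        arr[0, 0, :] = np.nan  # failed fits
        mask = box_mask((3, 3, 3), (slice(None),) * 3)
        *_, n, _ = histogram_stats(t2map_from(arr), mask)
        assert n == 24

    def test_too_few_valid_voxels_errors(self):
        arr = np.full((2, 2, 2), np.nan)
        arr[0, 0, 0] = 100.0
        mask = box_mask((2, 2, 2), (slice(None),) * 3)
        with pytest.raises(ValueError, match="valid voxels"):
            histogram_stats(t2map_from(arr), mask)


class TestMorphologicalMap:
    def test_isolated_voxel_one_spacing_from_background(self):
        mask = box_mask((5, 5, 5), (2, 2, 2), dims=(3.0, 3.0, 3.0))
        morph = morphological_map(mask)
        assert morph.distance_mm[2, 2, 2] == pytest.approx(3.0)
        assert np.isnan(morph.distance_mm[0, 0, 0])

    def test_slab_interior_maximum(self):
        """A laterally extended 7-voxel slab at 2.5 mm: the deepest voxel
        is 4 voxel steps (10 mm) from background; matches brute force."""
        shape = (24, 24, 11)
        mask = box_mask(shape, (slice(None), slice(None), slice(2, 9)))
        morph = morphological_map(mask)
        oracle = brute_force_distance_map(mask.data, mask.voxel_dims_mm)
        assert np.nanmax(morph.distance_mm) == pytest.approx(10.0)
        np.testing.assert_allclose(
            np.nan_to_num(morph.distance_mm), np.nan_to_num(oracle), atol=1e-9
        )

    def test_random_masks_equal_brute_force_oracle(self, rng):
        for _ in range(8):
            data = rng.random((16, 16, 16)) > 0.7
            data[2, 2, 2] = True
            mask = PlacentaMask(data.astype(int), (3.1, 2.5, 3.0))
            morph = morphological_map(mask)
            oracle = brute_force_distance_map(data, (3.1, 2.5, 3.0))
            np.testing.assert_allclose(
                np.nan_to_num(morph.distance_mm), np.nan_to_num(oracle), atol=1e-9
            )

    def test_distances_at_least_minimum_spacing(self, rng):
        data = rng.random((12, 12, 12)) > 0.5
        data[5, 5, 5] = True
        mask = PlacentaMask(data.astype(int), (2.0, 2.5, 3.0))
        vals = morphological_map(mask).values()
        assert np.all(vals >= 2.0 - 1e-12)

    def test_translation_invariance(self):
        a = box_mask((20, 20, 20), (slice(2, 8), slice(3, 9), slice(4, 8)))
        b = box_mask((20, 20, 20), (slice(9, 15), slice(8, 14), slice(10, 14)))
        ma, mb = morphological_map(a), morphological_map(b)
        assert np.nanmax(ma.distance_mm) == np.nanmax(mb.distance_mm)
        assert non_uniformity(ma) == pytest.approx(non_uniformity(mb))
        assert max_thickness(ma) == max_thickness(mb)


class TestNonUniformityAndThickness:
    def test_single_voxel(self):
        morph = morphological_map(box_mask((5, 5, 5), (2, 2, 2), dims=(3.0,) * 3))
        assert non_uniformity(morph) == pytest.approx(3.0)  # mean 3, SD 0
        assert max_thickness(morph) == pytest.approx(6.0)

    def test_slab_values_match_oracle_map(self):
        shape = (24, 24, 11)
        mask = box_mask(shape, (slice(None), slice(None), slice(2, 9)))
        oracle = brute_force_distance_map(mask.data, mask.voxel_dims_mm)
        vals = oracle[np.isfinite(oracle)]
        morph = morphological_map(mask)
        assert non_uniformity(morph) == pytest.approx(vals.mean() + vals.std(), abs=1e-9)
        assert max_thickness(morph) == pytest.approx(20.0)

    def test_sd_convention_switch(self):
        """Sample vs population SD differ by sqrt(n/(n-1)) on the spread
        term only."""
        mask = box_mask((10, 10, 8), (slice(1, 9), slice(1, 9), slice(1, 7)))
        morph = morphological_map(mask)
        vals = morph.values()
        n = vals.size
        pop, samp = non_uniformity(morph, ddof=0), non_uniformity(morph, ddof=1)
        expected = vals.mean() + vals.std(ddof=0) * np.sqrt(n / (n - 1))
        assert samp == pytest.approx(expected)
        assert samp > pop

    def test_ball_thickness_close_to_diameter(self):
        """Digital ball of radius 8 voxels at 1 mm iso: thickness within 2
        voxels of 16 mm, agreeing with the brute-force oracle."""
        r, n = 8, 21
        c = n // 2
        x, y, z = np.ogrid[:n, :n, :n]
        ball = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r**2
        mask = PlacentaMask(ball.astype(int), (1.0, 1.0, 1.0))
        thick = max_thickness(morphological_map(mask))
        oracle = brute_force_distance_map(ball, (1.0, 1.0, 1.0))
        assert thick == pytest.approx(2.0 * np.nanmax(oracle), abs=1e-9)
        assert abs(thick - 16.0) <= 2.0


class TestComputeAll:
    def test_aggregates_consistently(self, rng):
        shape = (12, 12, 10)
        mask = box_mask(shape, (slice(2, 10), slice(2, 10), slice(2, 8)))
        vals = np.full(shape, np.nan)
        vals[mask.data] = rng.normal(150.0, 20.0, mask.n_voxels)
        t2map = t2map_from(vals)
        m = compute_all(t2map, mask)
        assert m.n_voxels == mask.n_voxels
        assert m.volume_ml == compute_volume(mask)
        assert m.max_thickness_mm == max_thickness(morphological_map(mask))
        assert m.n_valid_fit_voxels == mask.n_voxels
        assert m.mean_t2star_ms == pytest.approx(vals[mask.data].mean())

    def test_failed_fits_kept_for_morphology(self):
        shape = (8, 8, 8)
        mask = box_mask(shape, (slice(1, 7), slice(1, 7), slice(1, 7)))
        vals = np.full(shape, 120.0)
        vals[1, 1, :] = np.nan  # fit failures inside the mask
        m = compute_all(t2map_from(vals), mask)
        assert m.n_valid_fit_voxels < m.n_voxels
        assert m.volume_ml == compute_volume(mask)  # mask-derived, unchanged
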