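import numpy as np
import pytest

from seedbed3d import (
    FilterSpec,
    binarize_blocks,
    build_seedbed,
    label_blocks,
    log_filter,
    measure_blocks,
    size_distribution,
)
from seedbed3d.blocks import BlockRecord, blocks_to_frame
from seedbed3d.errors import EmptyInputError, InputError, ParameterError
from seedbed3d.surface import decompose_surface

from conftest import make_field


def block(label, area, d=None, length=10.0, width=5.0, height=4.0):
    d = d if d is not None else 2 * np.sqrt(area / np.pi)
    return BlockRecord(
        label=label, area=area, length=length, width=width, height=height,
        equivalent_diameter=d, centroid=(0.0, 0.0),
    )


class TestLogFilter:
    def test_constant_field_zero_response(self):
        resp = log_filter(make_field(np.full((64, 64), 9.0)), 0.05)
        assert np.allclose(resp, 0.0, atol=1e-9)

    def test_gaussian_bump_peaks_at_center(self):
        yy, xx = np.indices((101, 101))
        sigma = 101 * 0.05
        z = 10 * np.exp(-((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * sigma**2))
        resp = log_filter(make_field(z), 0.05)
        assert np.unravel_index(np.argmax(resp), resp.shape) == (50, 50)

    def test_interior_feature_integrates_to_zero(self):
        z = np.zeros((201, 201))
        z[95:106, 95:106] = 12.0
        resp = log_filter(make_field(z), 0.02)  # sigma ~ 4 px, far from borders
        assert abs(resp.sum()) < 1e-9 * np.abs(resp).sum()

    def test_rejects_bad_sigma(self):
        with pytest.raises(ParameterError):
            log_filter(make_field(np.zeros((8, 8))), -0.1)


class TestBinarize:
    def test_zero_residual_fixed_threshold(self):
        mask = binarize_blocks(
            make_field(np.zeros((32, 32))),
            FilterSpec(threshold_method="fixed", threshold_value=2.0),
        )
        assert not mask.any()

    def test_plateaus_recovered_exactly(self):
        z = np.zeros((40, 40))
        z[5:10, 5:10] = 20.0
        z[25:35, 25:30] = 20.0
        mask = binarize_blocks(
            make_field(z), FilterSpec(threshold_method="fixed", threshold_value=2.0)
        )
        assert np.array_equal(mask, z > 2.0)

    def test_otsu_recovers_synthetic_clod_footprint(self):
        """Otsu finds the clods conservatively: near-perfect precision,
        most of the >1 mm footprint recovered."""
        scene = build_seedbed(6, seed=5, n_clods=60)
        residual = decompose_surface(scene.true_heightfield).block
        mask = binarize_blocks(residual, FilterSpec(threshold_method="otsu"))
        truth = scene.true_heightfield.z > 1.0
        assert (mask & truth).sum() / mask.sum() >= 0.95  # precision
        assert (mask & truth).sum() / (mask | truth).sum() >= 0.65  # IoU

    def test_triangle_recovers_footprint_on_clean_residual(self):
        """The triangle rule recovers >=80% of the true footprint on a
        noise-free residual, including thin clod rims."""
        scene = build_seedbed(6, seed=5, n_clods=60)
        residual = decompose_surface(scene.true_heightfield).block
        mask = binarize_blocks(residual, FilterSpec(threshold_method="triangle"))
        truth = scene.true_heightfield.z > 1.0
        assert (mask & truth).sum() / (mask | truth).sum() >= 0.8

    def test_empty_residual_rejected(self):
        empty = make_field(np.zeros((8, 8)), valid=np.zeros((8, 8), bool))
        with pytest.raises(EmptyInputError):
            binarize_blocks(empty, FilterSpec(threshold_method="fixed", threshold_value=1.0))


class TestLabeling:
    def test_empty_mask(self):
        labels, n = label_blocks(np.zeros((16, 16), bool))
        assert n == 0 and not labels.any()

    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), bool)
        mask[2:7, 2:7] = True
        mask[12:17, 12:17] = True
        _, n = label_blocks(mask)
        assert n == 2

    def test_diagonal_touch_is_one_block(self):
        mask = np.zeros((20, 20), bool)
        mask[2:7, 2:7] = True
        mask[7:12, 7:12] = True  # touches only at the (6,6)/(7,7) corner
        _, n = label_blocks(mask)
        assert n == 1

    def test_min_area_speckle_filter(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 5] = True  # single-cell speckle
        mask[10:14, 10:14] = True
        labels, n = label_blocks(mask, min_area_cells=4)
        assert n == 1
        assert labels[5, 5] == 0

    def test_labels_partition_the_filtered_mask(self, rng):
        mask = rng.random((60, 60)) > 0.6
        labels, n = label_blocks(mask, min_area_cells=4)
        assert sorted(np.unique(labels[labels > 0])) == list(range(1, n + 1))
        counts = [(labels == k).sum() for k in range(1, n + 1)]
        assert sum(counts) == (labels > 0).sum()
        assert all(c >= 4 for c in counts)


class TestMeasure:
    def test_square_block_measurements(self):
        z = np.zeros((20, 20))
        z[5:15, 5:15] = 20.0
        residual = make_field(z, pitch=1.0)
        labels, _ = label_blocks(z > 2.0)
        (rec,) = measure_blocks(labels, residual)
        assert rec.area == pytest.approx(100.0)
        assert rec.height == pytest.approx(20.0)
        assert rec.equivalent_diameter == pytest.approx(2 * np.sqrt(100 / np.pi))
        assert rec.length >= rec.width > 0

    def test_single_cell_block(self):
        z = np.zeros((9, 9))
        z[4, 4] = 7.0
        labels, _ = label_blocks(z > 0, min_area_cells=1)
        (rec,) = measure_blocks(labels, make_field(z))
        assert rec.area == pytest.approx(1.0)
        assert rec.height == pytest.approx(7.0)

    def test_heights_bounded_by_global_max(self, rng):
        z = np.abs(rng.normal(0, 5, (50, 50)))
        labels, _ = label_blocks(z > 3.0)
        for rec in measure_blocks(labels, make_field(z)):
            assert rec.height <= z.max() + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            measure_blocks(np.zeros((5, 5), int), make_field(np.zeros((6, 6))))

    def test_synthetic_clod_diameter_recovered(self):
        from seedbed3d.simulate import Clod, _paint_caps

        z = np.zeros((300, 300))
        _paint_caps(z, [Clod(center_x=225, center_y=225, diameter=60, height=24)],
                    pitch=1.5, cap_aspect=0.4)
        residual = decompose_surface(make_field(z, pitch=1.5)).block
        mask = binarize_blocks(
            residual, FilterSpec(threshold_method="fixed", threshold_value=1.0)
        )
        labels, n = label_blocks(mask)
        assert n == 1
        (rec,) = measure_blocks(labels, residual)
        assert rec.equivalent_diameter == pytest.approx(60.0, rel=0.15)


class TestSizeDistribution:
    def test_known_diameters(self):
        blocks = [block(i + 1, np.pi * (d / 2) ** 2, d=d) for i, d in enumerate((3, 10, 60))]
        dist = size_distribution(blocks)
        assert dist.fractions == pytest.approx([1 / 3, 1 / 3, 0, 1 / 3, 0, 0])
        assert dist.fractions.sum() == pytest.approx(1.0)

    def test_boundary_diameter_goes_to_upper_class(self):
        dist = size_distribution([block(1, np.pi * 2.5**2, d=5.0)])
        assert dist.fractions[1] == 1.0  # 5 mm lands in 5-15

    def test_empty_inventory_flagged(self):
        dist = size_distribution([])
        assert dist.is_empty
        assert dist.fractions.sum() == 0.0

    def test_frame_export_columns(self):
        df = blocks_to_frame([block(1, 100.0)])
        assert list(df.columns) == [
            "label", "area_mm2", "length_mm", "width_mm", "height_mm",
            "equiv_diameter_mm", "centroid_x_mm", "centroid_y_mm",
        ]
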