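"""LCN segmentation and morphometry against phantom ground truth."""

import math

import numpy as np
import pytest

from bonemorph.core import ImageStack
from bonemorph.lcn import (
    SegmentationConfig,
    acellular_area,
    compute_lcn_metrics,
    count_canaliculi,
    count_canaliculi_all,
    lacuna_surface_area,
    local_threshold,
    segment_lacunae,
)
from bonemorph.synthetic import LCNPhantomParams, generate_lcn_stack

from conftest import match_to_truth


class TestLocalThreshold:
    def test_constant_stack_all_background(self, phantom_cfg):
        stack = ImageStack(np.full((24, 48, 48), 80.0), (0.48, 0.24, 0.24))
        assert not local_threshold(stack, phantom_cfg).any()

    def test_phantom_objects_fully_detected(self, clean_phantom, phantom_cfg):
        params, stack, _ = clean_phantom
        objects = stack.data == params.foreground_intensity
        binary = local_threshold(stack, phantom_cfg)
        assert binary[objects].all()

    def test_inverted_contrast_not_silently_segmented(self, clean_phantom, phantom_cfg):
        """Dark-on-bright input yields no foreground on the objects; the
        bright-objects convention is a documented contract, not a switch."""
        params, stack, _ = clean_phantom
        inverted = ImageStack(255.0 - stack.data, stack.spacing)
        binary = local_threshold(inverted, phantom_cfg)
        objects = stack.data == params.foreground_intensity
        assert not binary[objects].any()

    def test_window_larger_than_axis_names_axis(self):
        stack = ImageStack(np.zeros((4, 40, 40)), (0.48, 0.24, 0.24))
        cfg = SegmentationConfig(local_threshold_window=10.0)
        with pytest.raises(ValueError, match="axis 0"):
            local_threshold(stack, cfg)


class TestSegmentLacunae:
    def test_empty_stack_empty_result(self, phantom_cfg):
        records, labels = segment_lacunae(
            np.zeros((8, 16, 16), bool), (0.48, 0.24, 0.24), phantom_cfg
        )
        assert records == []
        assert labels.max() == 0

    def test_phantom_counts_and_volumes(self, clean_phantom, segmented_phantom):
        _, _, truth = clean_phantom
        _, records, _, _ = segmented_phantom
        assert len(records) == truth.n_interior
        for rec in records:
            ref = match_to_truth(rec, truth)
            assert rec.volume == pytest.approx(ref.voxel_volume, rel=0.05)

    def test_border_lacuna_removed(self, phantom_cfg):
        """Translating one lacuna onto a face reduces the count by one."""
        base = [((8.0, 8.0, 8.0), (2.0, 2.0, 2.0)), ((8.0, 8.0, 24.0), (2.0, 2.0, 2.0))]
        p = LCNPhantomParams(
            stack_shape=(36, 140, 140), n_lacunae=2, canaliculi_per_lacuna=0,
            allow_border=True,
        )

        def count(lacunae):
            stack, _ = generate_lcn_stack(p, lacunae=lacunae)
            binary = local_threshold(stack, phantom_cfg)
            recs, _ = segment_lacunae(binary, stack.spacing, phantom_cfg)
            return len(recs)

        assert count(base) == 2
        shifted = [(( -1.0, 8.0, 8.0), (2.0, 2.0, 2.0)), base[1]]
        assert count(shifted) == 1

    def test_volume_filter_monotone(self, clean_phantom, segmented_phantom):
        _, stack, _ = clean_phantom
        binary, _, _, _ = segmented_phantom
        retained = []
        for lo, hi in [(10.0, 500.0), (25.0, 120.0), (40.0, 80.0)]:
            cfg = SegmentationConfig(
                min_lacuna_volume=lo, max_lacuna_volume=hi, opening_radius=0.8
            )
            recs, _ = segment_lacunae(binary, stack.spacing, cfg)
            retained.append(len(recs))
        assert retained[0] >= retained[1] >= retained[2]


class TestSurfaceArea:
    def test_single_voxel_face_area(self):
        labels = np.zeros((5, 5, 5), int)
        labels[2, 2, 2] = 1
        a, c = 0.25, 0.5  # in-plane and axial spacing
        got = lacuna_surface_area(labels, 1, (c, a, a))
        assert got == pytest.approx(4 * a * c + 2 * a * a)

    def test_sphere_matches_analytic(self):
        r, sp = 5.0, 0.25
        n = int(2 * r / sp) + 9
        coords = (np.indices((n, n, n)) - n // 2) * sp
        labels = (np.sum(coords**2, axis=0) <= r**2).astype(int)
        got = lacuna_surface_area(labels, 1, (sp, sp, sp))
        assert got == pytest.approx(4 * math.pi * r**2, rel=0.10)

    def test_ellipsoid_matches_thomsen(self):
        a, b, c = 3.0, 4.0, 5.0
        sp = 0.25
        n = 48
        z, y, x = (np.indices((n, n, n)) - n // 2) * sp
        labels = ((z / a) ** 2 + (y / b) ** 2 + (x / c) ** 2 <= 1).astype(int)
        p = 1.6075
        thomsen = 4 * math.pi * (
            ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3
        ) ** (1 / p)
        got = lacuna_surface_area(labels, 1, (sp, sp, sp))
        assert got == pytest.approx(thomsen, rel=0.10)

    def test_missing_label_raises(self):
        with pytest.raises(ValueError, match="label 3"):
            lacuna_surface_area(np.zeros((4, 4, 4), int), 3, (1, 1, 1))


class TestCountCanaliculi:
    def test_phantom_counts_exact(self, clean_phantom, segmented_phantom):
        _, _, truth = clean_phantom
        _, records, _, counts = segmented_phantom
        for rec in records:
            ref = match_to_truth(rec, truth)
            assert counts[rec.label] == ref.canaliculi_count

    def test_isolated_lacuna_zero(self, phantom_cfg):
        p = LCNPhantomParams(
            stack_shape=(24, 64, 64), n_lacunae=1, canaliculi_per_lacuna=0
        )
        stack, _ = generate_lcn_stack(p)
        binary = local_threshold(stack, phantom_cfg)
        recs, labels = segment_lacunae(binary, stack.spacing, phantom_cfg)
        assert count_canaliculi(binary, labels, recs[0].label, phantom_cfg) == 0

    def test_missing_label_raises(self, phantom_cfg):
        with pytest.raises(ValueError, match="label 9"):
            count_canaliculi(
                np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), int), 9, phantom_cfg
            )

    def test_shared_tube_counted_for_both(self, phantom_cfg):
        """A tube spanning two lacunae contributes one count to each."""
        sp = (0.48, 0.24, 0.24)
        shape = (36, 120, 120)
        zz, yy, xx = [g * s for g, s in zip(np.indices(shape), sp)]
        c1, c2 = np.array([8.0, 14.0, 8.0]), np.array([8.0, 14.0, 20.0])
        binary = np.zeros(shape, bool)
        for c in (c1, c2):
            binary |= (
                ((zz - c[0]) / 2.0) ** 2
                + ((yy - c[1]) / 2.0) ** 2
                + ((xx - c[2]) / 2.0) ** 2
            ) <= 1
        # straight tube along x joining the two ellipsoids
        tube = (
            (np.abs(zz - 8.0) <= 0.3)
            & (np.abs(yy - 14.0) <= 0.3)
            & (xx > 8.0)
            & (xx < 20.0)
        )
        binary |= tube
        recs, labels = segment_lacunae(binary, sp, phantom_cfg)
        assert len(recs) == 2
        counts = count_canaliculi_all(binary, labels, phantom_cfg)
        assert counts[recs[0].label] == 1
        assert counts[recs[1].label] == 1


class TestMetrics:
    def _rec(self, vol=50.0, cn=5, sa=60.0):
        from bonemorph.core import LacunaRecord

        return LacunaRecord(1, vol, sa, (0, 0, 0), cn)

    def test_density_arithmetic(self):
        recs = [self._rec() for _ in range(10)]
        m = compute_lcn_metrics(recs, physical_volume_um3=1e6)  # 0.001 mm^3
        assert m.lac_density == pytest.approx(10_000.0)

    def test_known_truth_recovered(self, clean_phantom, segmented_phantom):
        _, stack, truth = clean_phantom
        _, records, _, counts = segmented_phantom
        for r in records:
            r.canaliculi_count = counts[r.label]
        m = compute_lcn_metrics(records, stack.physical_volume)
        assert m.lac_density == pytest.approx(truth.lac_density, rel=1e-12)
        assert m.mean_canaliculi_per_lacuna == pytest.approx(
            truth.mean_canaliculi_per_lacuna
        )
        assert m.mean_lac_volume == pytest.approx(truth.mean_lac_volume, rel=0.05)
        assert m.canalicular_density > 0

    def test_empty_scan_density_zero_means_undefined(self):
        m = compute_lcn_metrics([], physical_volume_um3=1e6)
        assert m.lac_density == 0.0
        assert math.isnan(m.mean_lac_volume)
        assert math.isnan(m.mean_canaliculi_per_lacuna)
        assert math.isnan(m.canalicular_density)

    def test_pooled_density_is_volume_weighted_mean(self):
        r1 = [self._rec() for _ in range(4)]
        r2 = [self._rec() for _ in range(10)]
        v1, v2 = 2e5, 6e5
        m1 = compute_lcn_metrics(r1, v1)
        m2 = compute_lcn_metrics(r2, v2)
        pooled = compute_lcn_metrics(r1 + r2, v1 + v2)
        expected = (m1.lac_density * v1 + m2.lac_density * v2) / (v1 + v2)
        assert pooled.lac_density == pytest.approx(expected)


class TestAcellularArea:
    def _stack(self, mip):
        return ImageStack(np.asarray(mip, float)[None], (0.48, 0.24, 0.24))

    def test_uniform_bright_zero_percent(self):
        cfg = SegmentationConfig(mip_global_threshold=100.0)
        assert acellular_area(self._stack(np.full((50, 50), 200.0)), cfg) == 0.0

    def test_fully_dark_hundred_percent(self):
        cfg = SegmentationConfig(mip_global_threshold=100.0)
        assert acellular_area(self._stack(np.zeros((50, 50))), cfg) == 100.0

    def test_dark_square_fraction(self):
        img = np.full((100, 100), 200.0)
        img[:20, :50] = 10.0  # 10% of pixels
        for thr in (100.0, "otsu"):
            cfg = SegmentationConfig(mip_global_threshold=thr)
            assert acellular_area(self._stack(img), cfg) == pytest.approx(10.0)

    def test_exclusion_mask_removes_region(self):
        img = np.full((100, 100), 200.0)
        img[:20, :50] = 10.0
        excl = np.zeros((100, 100), bool)
        excl[:20, :50] = True  # mask out the dark patch entirely
        cfg = SegmentationConfig(mip_global_threshold=100.0)
        assert acellular_area(self._stack(img), cfg, exclusion_mask=excl) == 0.0
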