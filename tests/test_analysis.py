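import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import auxindisk as ad
from auxindisk.analysis import (angular_cv, circular_histogram,
                                compare_ensembles, extract_auxin_maxima,
                                summarize_run)
from auxindisk._arrays import compile_arrays


def paint_patches(disk, angles_deg, r_frac=0.5, sigma=3.0, amplitude=10.0):
    """Paint Gaussian auxin bumps at the given polar positions (middle ring)."""
    arrays = compile_arrays(disk)
    cents = arrays.centroids()
    areas = arrays.areas()
    tissue_c = (cents * areas[:, None]).sum(axis=0) / areas.sum()
    R = np.hypot(*(cents - tissue_c).T).max()
    for i, cid in enumerate(arrays.cids):
        c = cents[i] - tissue_c
        val = 0.0
        for ang in angles_deg:
            target = R * r_frac * np.array([math.cos(math.radians(ang)),
                                            math.sin(math.radians(ang))])
            d = np.hypot(*(c - target))
            val += amplitude * math.exp(-d * d / (2 * sigma * sigma))
        disk.cells[cid].aux = val
    return disk


class TestExtractMaxima:
    def test_uniform_field_has_no_ring_maxima(self, disk):
        """A uniform field is one big component centred at r = 0, which the
        middle-ring filter discards."""
        for c in disk.cells.values():
            c.aux = 1.0
        assert extract_auxin_maxima(disk) == []

    def test_zero_field_empty(self, disk):
        assert extract_auxin_maxima(disk) == []

    def test_single_patch(self, disk):
        paint_patches(disk, [70.0])
        maxima = extract_auxin_maxima(disk)
        assert len(maxima) == 1
        assert maxima[0].angle == pytest.approx(70.0, abs=8.0)
        assert maxima[0].peak_aux > 5.0

    def test_two_opposite_patches(self, disk):
        """Antipodal patches give two maxima ~180 deg apart (the finite cell
        size of the 73-cell disk limits angular accuracy to a few degrees)."""
        paint_patches(disk, [20.0, 200.0])
        maxima = extract_auxin_maxima(disk)
        assert len(maxima) == 2
        gap = abs(maxima[0].angle - maxima[1].angle)
        assert gap == pytest.approx(180.0, abs=7.0)

    def test_count_stable_across_thresholds(self, disk):
        """Well-separated bumps are counted correctly for a range of
        threshold fractions."""
        paint_patches(disk, [0.0, 120.0, 240.0])
        for frac in (0.3, 0.5, 0.7):
            assert len(extract_auxin_maxima(disk, threshold_frac=frac)) == 3

    def test_rotation_rotates_angles(self, disk):
        paint_patches(disk, [10.0, 130.0, 250.0])
        rot = disk.transform(rotation_deg=40.0)
        a0 = sorted(m.angle for m in extract_auxin_maxima(disk))
        a1 = sorted((m.angle - 40.0) % 360 for m in extract_auxin_maxima(rot))
        np.testing.assert_allclose(a1, a0, atol=1e-6)


class TestAngularCV:
    def test_even_spacing_is_zero(self):
        assert angular_cv([0, 90, 180, 270]) == pytest.approx(0.0, abs=1e-12)

    def test_uneven_spacing(self):
        """Gaps (45, 135, 90, 90): sample SD sqrt(1350), mean 90."""
        assert angular_cv([0, 45, 180, 270]) == pytest.approx(
            math.sqrt(1350) / 90, abs=1e-9)

    def test_undefined_for_single_angle(self):
        assert math.isnan(angular_cv([10.0]))

    def test_rotation_and_relabel_invariant(self):
        angles = [5, 77, 200, 301]
        shifted = [(a + 123.4) % 360 for a in angles]
        assert angular_cv(shifted) == pytest.approx(angular_cv(angles))
        assert angular_cv(angles[::-1]) == pytest.approx(angular_cv(angles))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 359.999), min_size=2, max_size=12))
    def test_gaps_always_partition_the_circle(self, angles):
        s = np.sort(np.asarray(angles) % 360.0)
        gaps = np.diff(np.concatenate([s, [s[0] + 360.0]]))
        assert gaps.sum() == pytest.approx(360.0)
        cv = angular_cv(angles)
        assert cv >= 0 or math.isnan(cv)


class TestCircularHistogram:
    def test_single_point_binning(self):
        """Intensity 7 at 46.2 deg lands in fine bin 46 and coarse bin 11."""
        pos = (math.cos(math.radians(46.2)), math.sin(math.radians(46.2)))
        h = circular_histogram([(pos, 7.0)], center=(0, 0))
        assert h.fine_bins[46] == 7.0
        assert h.fine_bins.sum() == 7.0
        assert h.coarse_bins[11] == 7.0

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        pts = [((rng.normal(), rng.normal()), rng.random()) for _ in range(200)]
        h = circular_histogram(pts, center=(0, 0))
        total = sum(w for _, w in pts)
        assert h.total == pytest.approx(total)
        assert h.fine_bins.sum() == pytest.approx(total)
        assert h.coarse_bins.sum() == pytest.approx(total)

    def test_coarse_is_exact_4fold_aggregation(self):
        rng = np.random.default_rng(1)
        pts = [((rng.normal(), rng.normal()), 1.0) for _ in range(100)]
        h = circular_histogram(pts, center=(0, 0))
        np.testing.assert_allclose(h.coarse_bins,
                                   h.fine_bins.reshape(90, 4).sum(axis=1))

    def test_four_degree_rotation_shifts_coarse_bins(self):
        angles = np.arange(0, 360, 8) + 2.0  # bin centres, away from edges
        pts = [((math.cos(math.radians(a)), math.sin(math.radians(a))), i + 1.0)
               for i, a in enumerate(angles)]
        h0 = circular_histogram(pts, center=(0, 0))
        rot = [((math.cos(math.radians(a + 4)), math.sin(math.radians(a + 4))), i + 1.0)
               for i, a in enumerate(angles)]
        h1 = circular_histogram(rot, center=(0, 0))
        np.testing.assert_allclose(h1.coarse_bins, np.roll(h0.coarse_bins, 1))

    def test_center_point_warns_into_bin_zero(self):
        with pytest.warns(UserWarning):
            h = circular_histogram([((0.0, 0.0), 3.0)], center=(0, 0))
        assert h.fine_bins[0] == 3.0
        assert h.total == 3.0

    def test_alignment_offset(self):
        pos = (math.cos(math.radians(49.0)), math.sin(math.radians(49.0)))
        h = circular_histogram([(pos, 1.0)], center=(0, 0),
                               alignment_offset=45.0)
        assert h.fine_bins[4] == 1.0


class TestSummarize:
    def test_summary_values(self, disk):
        paint_patches(disk, [0.0, 90.0, 180.0, 270.0])

        class FakeTraj:
            snapshots = [(100, disk)]
            config = None

        s = summarize_run(FakeTraj())
        assert s.maxima_count == 4
        assert 3.0 < s.mean_max_aux <= 10.0
        assert s.angular_cv == pytest.approx(0.0, abs=0.15)

    def test_no_maxima_flagged(self, disk):
        class FakeTraj:
            snapshots = [(50, disk)]
            config = None

        s = summarize_run(FakeTraj())
        assert s.maxima_count == 0
        assert math.isnan(s.mean_max_aux)
        assert math.isnan(s.angular_cv)


class TestCompareEnsembles:
    def _table(self, groups):
        rows = []
        for name, vals in groups.items():
            rows += [{"genotype": name, "maxima_count": v} for v in vals]
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(4, 1, 40)
        t = self._table({"a": vals, "b": vals})
        rep = compare_ensembles(t, "maxima_count", "genotype")
        assert not any(c["significant"] for c in rep["mean_comparisons"])

    def test_mean_shift_detected(self):
        rng = np.random.default_rng(1)
        t = self._table({"a": rng.normal(0, 1, 50), "b": rng.normal(5, 1, 50)})
        rep = compare_ensembles(t, "maxima_count", "genotype")
        assert rep["mean_comparisons"][0]["significant"]

    def test_variance_difference_detected(self):
        rng = np.random.default_rng(2)
        t = self._table({"a": rng.normal(0, 0.5, 60), "b": rng.normal(0, 4, 60)})
        rep = compare_ensembles(t, "maxima_count", "genotype")
        vc = rep["variance_comparisons"][0]
        assert vc["p"] < 0.01
        assert vc["direction"] == "<"

    def test_group_count(self):
        rng = np.random.default_rng(3)
        t = self._table({k: rng.normal(0, 1, 5) for k in "abcd"})
        rep = compare_ensembles(t, "maxima_count", "genotype")
        assert len(rep["groups"]) == 4

    def test_degenerate_groups_flagged(self):
        t = self._table({"a": [4] * 5, "b": [4] * 5})
        rep = compare_ensembles(t, "maxima_count", "genotype")
        assert rep["degenerate"]
        assert rep["mean_comparisons"] == []
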