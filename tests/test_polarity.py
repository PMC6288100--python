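import numpy as np
import pytest

from conftest import random_ratio_map
from oracles import bin_percentages_loop, student_p_value, welch_p_value
from shearfret import (
    DegenerateGeometryError,
    RatioMap,
    ValidationError,
    bin_along_flow,
    normalize_profiles,
    polarity_test,
    updown_summary,
)

FLOW = (0.0, 1.0)


def rect_map(h=20, w=40, value=1.0):
    valid = np.zeros((h + 4, w + 4), dtype=bool)
    valid[2 : 2 + h, 2 : 2 + w] = True
    return RatioMap(ratio=np.where(valid, value, 0.0), valid=valid)


class TestBinAlongFlow:
    def test_uniform_rectangle_gives_equal_bins(self):
        # 50 pixel columns into 50 bins, flow parallel to a side: one column
        # per bin, each exactly 2% of the cell total
        prof = bin_along_flow(rect_map(w=50), FLOW, n_bins=50)
        np.testing.assert_allclose(prof.percentages, 2.0, atol=1e-9)

    def test_monotone_field_gives_monotone_profile(self):
        # one pixel column per bin so the discretization cannot mask the trend
        rm = rect_map(w=50)
        cols = np.arange(rm.ratio.shape[1], dtype=float)
        ramp = 1.0 + (cols - 2) / 49.0  # 1 upstream edge -> 2 downstream edge
        rm.ratio = np.where(rm.valid, ramp[None, :], 0.0)
        prof = bin_along_flow(rm, FLOW, n_bins=50)
        assert np.all(np.diff(prof.percentages) < 0)  # bin 1 (downstream) largest

    @pytest.mark.parametrize("flow", [(0.0, 1.0), (1.0, 0.0),
                                      (np.sqrt(0.5), np.sqrt(0.5)),
                                      (-np.sqrt(0.5), np.sqrt(0.5))])
    def test_matches_per_pixel_loop(self, rng, flow):
        for _ in range(5):
            rm = random_ratio_map(rng, dyadic=False)
            got = bin_along_flow(rm, flow, n_bins=17)
            ref = bin_percentages_loop(rm.ratio, rm.valid, flow, 17)
            np.testing.assert_allclose(got.percentages, ref, rtol=0, atol=1e-9)

    def test_flip_reverses_exactly(self, rng):
        for _ in range(10):
            rm = random_ratio_map(rng)
            a = bin_along_flow(rm, FLOW, n_bins=50)
            b = bin_along_flow(rm, (0.0, -1.0), n_bins=50)
            assert np.array_equal(a.percentages, b.percentages[::-1])

    def test_joint_rotation_invariance_exact(self, rng):
        rm = random_ratio_map(rng)
        base = bin_along_flow(rm, FLOW, n_bins=50)
        d = FLOW
        ratio, valid = rm.ratio, rm.valid
        for _ in range(3):
            ratio = np.rot90(ratio).copy()
            valid = np.rot90(valid).copy()
            d = (-d[1], d[0])  # np.rot90 rotates counterclockwise
            rot = bin_along_flow(RatioMap(ratio=ratio, valid=valid), d, n_bins=50)
            assert np.array_equal(base.percentages, rot.percentages)

    def test_percentages_conserved(self, rng):
        for _ in range(20):
            rm = random_ratio_map(rng, dyadic=False)
            prof = bin_along_flow(rm, (0.6, 0.8), n_bins=50)
            assert prof.percentages.sum() == pytest.approx(100.0, abs=1e-6)

    def test_boundary_pixel_split_between_bins(self):
        # 3 columns, 2 bins: the middle column sits exactly on the interior
        # edge and must contribute half its weight to each bin
        valid = np.zeros((1, 3), dtype=bool)
        valid[0, :] = True
        rm = RatioMap(ratio=np.ones((1, 3)), valid=valid)
        prof = bin_along_flow(rm, FLOW, n_bins=2)
        np.testing.assert_allclose(prof.percentages, [50.0, 50.0], atol=1e-12)

    def test_degenerate_extent_rejected(self):
        valid = np.zeros((10, 10), dtype=bool)
        valid[:, 4] = True  # single column, no extent along the column axis
        rm = RatioMap(ratio=np.where(valid, 1.0, 0.0), valid=valid)
        with pytest.raises(DegenerateGeometryError):
            bin_along_flow(rm, FLOW, n_bins=50)

    def test_fixed_edges_clip_outside_pixels(self):
        rm = rect_map(w=30)
        free = bin_along_flow(rm, FLOW, n_bins=10)
        fixed = bin_along_flow(rm, FLOW, n_bins=10,
                               edges=(float(free.bin_edges[-1]) - 5.0,
                                      float(free.bin_edges[0]) + 5.0))
        assert fixed.percentages.sum() == pytest.approx(100.0, abs=1e-6)


def profiles_from_matrix(mat):
    """Build raw profiles (frames = columns) from an (n_bins, T) matrix."""
    from shearfret import SpatialProfile

    n, t = mat.shape
    edges = np.arange(n + 1, dtype=float)[::-1]
    return [SpatialProfile(percentages=mat[:, i].copy(), bin_edges=edges, frame_index=i)
            for i in range(t)]


class TestNormalizeProfiles:
    def test_constant_profiles_normalize_to_one(self):
        mat = np.tile(np.linspace(1, 3, 10)[:, None], (1, 6))
        out = normalize_profiles(profiles_from_matrix(mat), stimulus_onset_frame=3)
        for p in out:
            np.testing.assert_allclose(p.normalized_percentages, 1.0, atol=1e-12)

    def test_single_bin_doubling(self):
        mat = np.ones((10, 6))
        mat[4, 3:] = 2.0
        out = normalize_profiles(profiles_from_matrix(mat), stimulus_onset_frame=3)
        assert out[5].normalized_percentages[4] == pytest.approx(2.0)
        others = np.delete(out[5].normalized_percentages, 4)
        np.testing.assert_allclose(others, 1.0, atol=1e-12)

    def test_zero_prestimulus_bin_flagged_invalid(self):
        mat = np.ones((10, 6))
        mat[7, :3] = 0.0
        out = normalize_profiles(profiles_from_matrix(mat), stimulus_onset_frame=3)
        assert not out[0].valid[7]
        assert np.isnan(out[0].normalized_percentages[7])

    def test_requires_pre_stimulus_frame(self):
        with pytest.raises(ValidationError):
            normalize_profiles(profiles_from_matrix(np.ones((5, 3))), 0)


class TestUpdownSummary:
    def normalized(self, values, valid=None):
        from shearfret import SpatialProfile

        values = np.asarray(values, dtype=float)
        return SpatialProfile(
            percentages=values.copy(),
            bin_edges=np.arange(len(values) + 1, dtype=float)[::-1],
            normalized_percentages=values,
            valid=np.ones(len(values), dtype=bool) if valid is None else valid,
        )

    def test_flat_profile(self):
        down, up = updown_summary(self.normalized(np.ones(50)))
        assert (down, up) == (1.0, 1.0)

    def test_arithmetic(self):
        vals = np.ones(50)
        vals[:5] = [1, 2, 3, 4, 5]
        vals[45:] = 2.0
        down, up = updown_summary(self.normalized(vals))
        assert down == pytest.approx(3.0)
        assert up == pytest.approx(2.0)

    def test_matches_slice_mean(self, rng):
        vals = rng.uniform(0.5, 2.0, 50)
        down, up = updown_summary(self.normalized(vals))
        assert down == pytest.approx(vals[:5].mean())
        assert up == pytest.approx(vals[45:].mean())

    def test_invalid_bins_skipped(self):
        vals = np.ones(50)
        vals[:5] = [10, 2, 2, 2, 2]
        valid = np.ones(50, dtype=bool)
        valid[0] = False  # the extreme bin is unusable
        down, _ = updown_summary(self.normalized(vals, valid))
        assert down == pytest.approx(2.0)

    def test_all_edge_bins_invalid_rejected(self):
        valid = np.ones(50, dtype=bool)
        valid[:5] = False
        with pytest.raises(ValidationError):
            updown_summary(self.normalized(np.ones(50), valid))


class TestPolarityTest:
    def test_identical_groups_not_polar(self):
        res = polarity_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0 and not res.polar

    def test_strong_difference_detected(self):
        res = polarity_test([1.00, 1.02, 0.98], [2.00, 2.02, 1.98])
        assert res.p_value < 0.001
        assert res.polar
        assert res.down_mean == pytest.approx(2.0)
        assert res.up_mean == pytest.approx(1.0)

    @pytest.mark.parametrize("variant,oracle",
                             [("welch", welch_p_value), ("student", student_p_value)])
    def test_p_matches_t_distribution_oracle(self, rng, variant, oracle):
        for _ in range(20):
            a = rng.normal(1.0, 0.1, rng.integers(3, 12))
            b = rng.normal(1.05, 0.2, rng.integers(3, 12))
            res = polarity_test(a, b, variant=variant)
            assert res.p_value == pytest.approx(oracle(a, b), abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            polarity_test([1.0], [1.0, 2.0])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            polarity_test([1, 2, 3], [1, 2, 3], variant="bootstrap")
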