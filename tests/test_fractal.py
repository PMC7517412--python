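import math

import numpy as np
import pytest

from fdnet.exceptions import DomainError, ValidationError
from fdnet.fractal import (
    BoxCountCurve,
    VoxelMask,
    aggregate_lobe_fd,
    box_counts,
    default_sizes,
    estimate_fd,
    fd_of_mask,
    fd_per_roi,
)
from fdnet.synthetic import CANTOR_DUST_FD, MENGER_FD, PhantomSpec, make_phantom

from conftest import cohort_from_fd


def brute_force_box_count(occ: np.ndarray, r: int) -> int:
    """Triple-loop oracle: grid anchored at the bounding-box origin."""
    idx = np.nonzero(occ)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) for a in idx]
    boxes = set()
    for x, y, z in zip(*idx):
        boxes.add(((x - lo[0]) // r, (y - lo[1]) // r, (z - lo[2]) // r))
    return len(boxes)


class TestBoxCounts:
    def test_full_cube(self):
        mask = VoxelMask(np.ones((4, 4, 4), dtype=bool))
        curve = box_counts(mask, [1, 2, 4])
        assert curve.counts.tolist() == [64, 8, 1]

    def test_single_voxel(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 3, 1] = True
        curve = box_counts(VoxelMask(occ), [1, 2, 4])
        assert curve.counts.tolist() == [1, 1, 1]

    def test_menger_level2(self):
        sponge = make_phantom(PhantomSpec("menger_sponge", 2))
        curve = box_counts(sponge, [1, 3, 9])
        assert curve.counts.tolist() == [400, 20, 1]

    def test_oversized_box_counts_one(self):
        mask = VoxelMask(np.ones((4, 4, 4), dtype=bool))
        assert box_counts(mask, [16]).counts.tolist() == [1]

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            box_counts(VoxelMask(np.zeros((3, 3, 3), dtype=bool)), [1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(3, 17, size=3)
        occ = rng.random(shape) < 0.3
        if not occ.any():
            occ[0, 0, 0] = True
        sizes = [1, 2, 3, 4, 5, 7]
        curve = box_counts(VoxelMask(occ), sizes)
        expected = [brute_force_box_count(occ, r) for r in sizes]
        assert curve.counts.tolist() == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_counts_non_increasing(self, seed):
        rng = np.random.default_rng(100 + seed)
        occ = rng.random((12, 9, 14)) < 0.2
        if not occ.any():
            occ[0, 0, 0] = True
        curve = box_counts(VoxelMask(occ), [1, 2, 3, 4, 6, 8, 16])
        assert (np.diff(curve.counts) <= 0).all()

    def test_translation_invariance_after_cropping(self):
        rng = np.random.default_rng(5)
        occ = rng.random((8, 8, 8)) < 0.4
        big = np.zeros((32, 32, 32), dtype=bool)
        big[13:21, 2:10, 17:25] = occ
        sizes = [1, 2, 4, 8]
        a = box_counts(VoxelMask(occ), sizes).counts
        b = box_counts(VoxelMask(big), sizes).counts
        assert a.tolist() == b.tolist()


class TestDefaultSizes:
    def test_dyadic_cube(self):
        mask = VoxelMask(np.ones((64, 64, 64), dtype=bool))
        assert default_sizes(mask, base=2) == [1, 2, 4, 8, 16, 32, 64]

    def test_triadic_sponge(self):
        sponge = make_phantom(PhantomSpec("menger_sponge", 2))
        assert default_sizes(sponge, base=3) == [1, 3, 9]

    def test_tiny_mask_rejected(self):
        mask = VoxelMask(np.ones((2, 2, 2), dtype=bool))
        with pytest.raises(DomainError):
            default_sizes(mask, base=3)


class TestEstimateFd:
    def test_exact_cube_power_law(self):
        est = estimate_fd(BoxCountCurve([1, 2, 4], [64, 8, 1]))
        assert est.fd == pytest.approx(3.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_is_zero_dimensional(self):
        est = estimate_fd(BoxCountCurve([1, 2, 4], [1, 1, 1]))
        assert est.fd == 0.0

    def test_menger_closed_form(self):
        est = estimate_fd(BoxCountCurve([1, 3, 9], [400, 20, 1]))
        assert est.fd == pytest.approx(math.log(20) / math.log(3), abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(DomainError):
            estimate_fd(BoxCountCurve([2], [5]))

    def test_increasing_counts_rejected(self):
        with pytest.raises(ValidationError):
            BoxCountCurve([1, 2], [3, 5])


class TestAnalyticPhantoms:
    @pytest.mark.parametrize(
        "spec,base,expected",
        [
            (PhantomSpec("cube", 32), 2, 3.0),
            (PhantomSpec("slab", 32), 2, 2.0),
            (PhantomSpec("line", 32), 2, 1.0),
            (PhantomSpec("menger_sponge", 3), 3, MENGER_FD),
            (PhantomSpec("cantor_dust", 3), 3, CANTOR_DUST_FD),
        ],
    )
    def test_dimension_recovery(self, spec, base, expected):
        est = fd_of_mask(make_phantom(spec), base=base)
        assert est.fd == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_dimension_bounds_on_random_masks(self, seed):
        rng = np.random.default_rng(200 + seed)
        occ = rng.random((16, 16, 16)) < rng.uniform(0.05, 0.9)
        if not occ.any():
            occ[0, 0, 0] = True
        mask = VoxelMask(occ)
        try:
            est = fd_of_mask(mask)
        except DomainError:
            return
        assert -0.1 <= est.fd <= 3.1


class TestFdPerRoi:
    def test_filled_block_and_missing_roi(self, atlas):
        labels = np.zeros((40, 24, 24), dtype=int)
        labels[0:16, 0:16, 0:16] = 5
        fd = fd_per_roi(labels, atlas)
        assert fd[5 - 1] == pytest.approx(3.0, abs=0.05)
        assert np.isnan(fd[7 - 1])

    def test_sponge_region_triadic(self, atlas):
        sponge = make_phantom(PhantomSpec("menger_sponge", 2)).occupancy
        labels = np.zeros((12, 12, 12), dtype=int)
        labels[:9, :9, :9][sponge] = 61
        fd = fd_per_roi(labels, atlas, base=3)
        assert fd[61 - 1] == pytest.approx(MENGER_FD, abs=0.05)

    def test_bad_label_code_rejected(self, atlas):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, 0] = 99
        with pytest.raises(ValidationError):
            fd_per_roi(labels, atlas)

    def test_min_voxels_marks_missing(self, atlas):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[0, 0, :4] = 3  # 4 voxels < default min of 8
        fd = fd_per_roi(labels, atlas)
        assert np.isnan(fd[3 - 1])


class TestAggregateLobeFd:
    def test_constant_cohort(self, atlas):
        fd = np.full((5, 68), 2.2)
        table = aggregate_lobe_fd(cohort_from_fd(fd), atlas)
        assert np.allclose(table["mean"], 2.2)
        assert np.allclose(table["sd"], 0.0)

    def test_sampling_recovery(self, atlas):
        rng = np.random.default_rng(9)
        n = 400
        fd = 2.24 + 0.10 * rng.standard_normal((n, 68))
        table = aggregate_lobe_fd(cohort_from_fd(fd), atlas)
        frontal = table[(table.lobe == "frontal") & (table.hemisphere == "both")]
        se = 0.10 / math.sqrt(n * 28)
        assert abs(frontal["mean"].iloc[0] - 2.24) < 2 * se * 3  # generous 2-SE-ish band

    def test_single_subject_uses_roi_spread(self, atlas):
        rng = np.random.default_rng(11)
        fd = (2.2 + 0.1 * rng.standard_normal(68))[None, :]
        table = aggregate_lobe_fd(cohort_from_fd(fd), atlas)
        row = table[(table.lobe == "frontal") & (table.hemisphere == "both")]
        expected_sd = np.std(fd[0, :28], ddof=1)
        assert row["sd"].iloc[0] == pytest.approx(expected_sd)
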