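"""Domain types and elementary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from normconn import (AcquisitionMatrix, BinaryMask, Connectome, GridMismatchError,
                      InvalidInputError, StatMap, VoxelGrid, bh_fdr, fisher_z,
                      one_sample_t, pearson_r)

from conftest import make_acquisition


# ---------------------------------------------------------------------------
# VoxelGrid / BinaryMask
# ---------------------------------------------------------------------------

class TestVoxelGrid:
    def test_equality_within_affine_tolerance(self, tiny_grid):
        jitter = tiny_grid.affine.copy()
        jitter[0, 3] += 5e-5
        assert tiny_grid == VoxelGrid(tiny_grid.dims, jitter)
        far = tiny_grid.affine.copy()
        far[0, 3] += 1.0
        assert tiny_grid != VoxelGrid(tiny_grid.dims, far)
        assert tiny_grid != VoxelGrid((4, 3, 3), tiny_grid.affine)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(InvalidInputError):
            VoxelGrid((0, 3, 2), np.eye(4))
        with pytest.raises(InvalidInputError):
            VoxelGrid((2, 2, 2), np.zeros((4, 4)))

    def test_flat_index_is_x_fastest(self, tiny_grid):
        # x-fastest: stepping x by 1 changes the flat index by 1,
        # stepping y by 1 changes it by nx, stepping z by nx*ny
        assert tiny_grid.flat_index(1, 0, 0) == 1
        assert tiny_grid.flat_index(0, 1, 0) == 4
        assert tiny_grid.flat_index(0, 0, 1) == 12
        flat = tiny_grid.flat_index(3, 2, 1)
        assert tuple(int(v) for v in tiny_grid.unravel(flat)) == (3, 2, 1)

    def test_dense_roundtrip_uses_fortran_order(self, tiny_grid):
        mask = BinaryMask(tiny_grid, [1, 4, 12])
        dense = mask.to_dense()
        assert dense[1, 0, 0] == 1 and dense[0, 1, 0] == 1 and dense[0, 0, 1] == 1
        assert BinaryMask.from_dense(tiny_grid, dense) == mask


class TestBinaryMask:
    def test_out_of_range_member_rejected(self, tiny_grid):
        with pytest.raises(InvalidInputError):
            BinaryMask(tiny_grid, [tiny_grid.voxel_count])

    def test_set_operations(self, tiny_grid):
        a = BinaryMask(tiny_grid, [0, 1, 2, 3])
        b = BinaryMask(tiny_grid, [2, 3, 4])
        assert list(a.intersection(b).members) == [2, 3]
        assert list(a.union(b).members) == [0, 1, 2, 3, 4]
        assert a.cardinality == 4

    def test_grid_mismatch_is_hard_error(self, tiny_grid):
        other = VoxelGrid(tiny_grid.dims, np.diag([3.0, 3.0, 3.0, 1.0]))
        with pytest.raises(GridMismatchError):
            BinaryMask(tiny_grid, [0]).intersection(BinaryMask(other, [0]))


class TestAcquisitionMatrix:
    def test_invalid_rows_excluded_at_construction(self, tiny_grid):
        data = np.random.default_rng(0).standard_normal((4, 10))
        data[1] = 7.0          # constant -> zero variance
        data[2, 3] = np.nan    # non-finite
        acq = AcquisitionMatrix("a", tiny_grid, [0, 1, 2, 3], data)
        assert list(acq.voxel_indices) == [0, 3]
        assert acq.data.shape == (2, 10)

    def test_too_few_volumes_rejected(self, tiny_grid):
        with pytest.raises(InvalidInputError):
            AcquisitionMatrix("a", tiny_grid, [0], np.ones((1, 2)))

    def test_unsorted_indices_rejected(self, tiny_grid, rng):
        with pytest.raises(InvalidInputError):
            AcquisitionMatrix("a", tiny_grid, [3, 1], rng.standard_normal((2, 5)))


class TestConnectome:
    def test_duplicate_ids_rejected(self, tiny_grid, rng):
        acqs = [make_acquisition(tiny_grid, "same", rng) for _ in range(2)]
        with pytest.raises(InvalidInputError, match="duplicate"):
            Connectome(tiny_grid, acqs)

    def test_empty_rejected(self, tiny_grid):
        with pytest.raises(InvalidInputError):
            Connectome(tiny_grid, [])


class TestStatMap:
    def test_no_data_voxels_have_zero_n(self, tiny_grid):
        values = np.full(tiny_grid.voxel_count, np.nan)
        values[0] = 0.5
        n = np.zeros(tiny_grid.voxel_count, dtype=int)
        n[0] = 3
        sm = StatMap(tiny_grid, values, "mean_r", n)
        assert sm.defined.sum() == 1
        bad_n = n.copy()
        bad_n[1] = 2  # claims contributions at a NaN voxel
        with pytest.raises(InvalidInputError):
            StatMap(tiny_grid, values, "mean_r", bad_n)

    def test_mean_r_range_enforced(self, tiny_grid):
        values = np.full(tiny_grid.voxel_count, np.nan)
        values[0] = 1.5
        n = np.zeros(tiny_grid.voxel_count, dtype=int)
        n[0] = 2
        with pytest.raises(InvalidInputError):
            StatMap(tiny_grid, values, "mean_r", n)

    def test_restrict_only_removes_voxels(self, tiny_grid, rng):
        values = rng.uniform(-1, 1, tiny_grid.voxel_count)
        n = np.full(tiny_grid.voxel_count, 5)
        sm = StatMap(tiny_grid, values, "mean_r", n)
        keep = BinaryMask(tiny_grid, [0, 5, 7])
        out = sm.restrict(keep)
        assert np.array_equal(np.flatnonzero(out.defined), keep.members)
        assert np.array_equal(out.values[keep.members], values[keep.members])


# ---------------------------------------------------------------------------
# pearson_r
# ---------------------------------------------------------------------------

class TestPearsonR:
    def test_self_correlation_is_one(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_evaluated_example(self):
        # direct covariance/variance evaluation: cov-sum 4, var-sums 5 and 5
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-15)

    @pytest.mark.parametrize("x,y", [
        ([1, 2], [3, 4]),            # too short
        ([1, 1, 1], [1, 2, 3]),      # zero variance
        ([1, 2, 3], [1, 2, 3, 4]),   # length mismatch
    ])
    def test_invalid_inputs(self, x, y):
        with pytest.raises(InvalidInputError):
            pearson_r(x, y)

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=30, derandomize=True)
    def test_symmetry_and_positive_affine_invariance(self, seed, scale, shift):
        g = np.random.default_rng(seed)
        x, y = g.standard_normal(12), g.standard_normal(12)
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson_r(scale * x + shift, y) == pytest.approx(r, abs=1e-9)


# ---------------------------------------------------------------------------
# fisher_z
# ---------------------------------------------------------------------------

class TestFisherZ:
    def test_odd_function(self):
        assert fisher_z(0.0) == 0.0
        for r in (0.1, 0.37, 0.9):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-15)

    def test_reference_value(self):
        # high-precision arctanh(0.5) = ln(3)/2
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-15)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(InvalidInputError):
            fisher_z(r)


# ---------------------------------------------------------------------------
# one_sample_t
# ---------------------------------------------------------------------------

class TestOneSampleT:
    def test_symmetric_values_give_zero_t(self):
        t, df, p = one_sample_t([-0.4, 0.4])
        assert t == pytest.approx(0.0, abs=1e-15)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(InvalidInputError):
            one_sample_t([1.0, 1.0, 1.0])
        with pytest.raises(InvalidInputError):
            one_sample_t([1.0])

    def test_textbook_formula_example(self):
        # frozen from mean/(sd/sqrt(n)) and the Student-t two-sided tail
        t, df, p = one_sample_t([0.1, 0.3, 0.2, 0.4])
        assert t == pytest.approx(3.8729833462074175, abs=1e-12)
        assert df == 3
        assert p == pytest.approx(0.03046629166217096, abs=1e-12)

    def test_null_calibration_at_extreme_tail(self):
        # |t| should exceed the two-sided 0.001 critical value ~0.1% of the time
        g = np.random.default_rng(7)
        n, reps = 10, 20000
        crit = stats.t.ppf(1 - 0.0005, n - 1)
        hits = sum(abs(one_sample_t(g.standard_normal(n))[0]) > crit
                   for _ in range(reps))
        # binomial 99.9% envelope around 0.001 * reps = 20
        assert 5 <= hits <= 40


# ---------------------------------------------------------------------------
# bh_fdr
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_null_extremes(self):
        assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()
        assert bh_fdr([0.01], 0.05).all()
        assert bh_fdr([], 0.05).size == 0

    def test_step_up_example(self):
        # exhaustive step-up by hand: thresholds k*q/m = .0125 .025 .0375 .05;
        # p(1)=.01 and p(2)=.02 pass, p(3)=.20 and p(4)=.90 do not
        reject = bh_fdr([0.01, 0.02, 0.20, 0.90], 0.05)
        assert list(reject) == [True, True, False, False]

    def test_invalid_pvalues(self):
        with pytest.raises(InvalidInputError):
            bh_fdr([0.5, 1.2], 0.05)
        with pytest.raises(InvalidInputError):
            bh_fdr([0.5], 0.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
           st.floats(0.01, 0.3))
    @settings(max_examples=50, derandomize=True)
    def test_rejections_are_monotone_in_p(self, pvals, q):
        reject = bh_fdr(pvals, q)
        if reject.any():
            pmax = max(p for p, rej in zip(pvals, reject) if rej)
            assert all(rej for p, rej in zip(pvals, reject) if p <= pmax)

    def test_false_rejection_proportion_under_null(self):
        # over replicates of uniform p-values, the realized false-rejection
        # proportion at q=0.05 stays at or below 0.05 (up to MC error)
        g = np.random.default_rng(11)
        fdp = []
        for _ in range(200):
            reject = bh_fdr(g.uniform(size=10_000), 0.05)
            fdp.append(reject.sum() / max(reject.sum(), 1))
        assert np.mean(fdp) <= 0.05 + 2 * np.std(fdp) / np.sqrt(len(fdp)) + 0.01
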