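"""Permutation null, p-values, FDR thresholding, cluster extraction."""

import numpy as np
import pytest

from dualale.ale_maps import KernelSpec, LikelihoodMap
from dualale.inference import (
    NullDistribution,
    extract_clusters,
    fdr_threshold,
    p_map,
    permute_null,
    uniformity_pit,
)
from dualale.study_io import Direction, FocusCoordinate, Space, StudyRecord, score_quality

from conftest import full_mask_grid

RED = Direction.REDUCTION


def make_null(values, n_masked):
    vals = np.sort(np.asarray(values, dtype=np.float32))
    assert len(vals) % n_masked == 0
    return NullDistribution(values=vals, n_permutations=len(vals) // n_masked,
                            n_masked=n_masked, seed=0)


def jmap(grid, values):
    return LikelihoodMap(grid, np.asarray(values, dtype=float), "joint", RED)


def two_focus_studies(grid, n_per_cond=2, n_foci=2, seed=0):
    rng = np.random.default_rng(seed)
    masked = grid.masked_indices()
    out = []
    for cond in ("A", "B"):
        for i in range(n_per_cond):
            picks = masked[rng.integers(0, len(masked), size=n_foci)]
            foci = tuple(
                FocusCoordinate(
                    *(ijk * grid.voxel_size + grid.affine[:3, 3]),
                    space=Space.MNI, direction=RED,
                )
                for ijk in picks
            )
            out.append(StudyRecord(f"{cond}{i}", cond, 10, 10,
                                   quality=score_quality([1] * 12), foci=foci))
    return out


class TestPMap:
    def test_hand_counted_example(self):
        grid = full_mask_grid(1, 2.0)  # single voxel
        null = make_null([0.1, 0.2, 0.3], n_masked=1)
        p = p_map(jmap(grid, [[[0.25]]]), null)
        assert p[0, 0, 0] == pytest.approx((1 + 1) / (1 + 3))

    def test_value_above_all_null_gets_minimum_p(self):
        grid = full_mask_grid(1, 2.0)
        null = make_null([0.1, 0.2, 0.3], n_masked=1)
        p = p_map(jmap(grid, [[[9.0]]]), null)
        assert p[0, 0, 0] == pytest.approx(1 / 4)

    def test_zero_joint_gets_p_one(self):
        grid = full_mask_grid(1, 2.0)
        null = make_null([0.0, 0.2, 0.3], n_masked=1)
        p = p_map(jmap(grid, [[[0.0]]]), null)
        assert p[0, 0, 0] == pytest.approx(1.0)

    def test_p_is_monotone_nonincreasing_in_joint_value(self):
        grid = full_mask_grid(4, 2.0)
        rng = np.random.default_rng(1)
        null = make_null(rng.uniform(0, 1, 64 * 5), n_masked=64)
        j = rng.uniform(0, 1, grid.shape)
        p = p_map(jmap(grid, j), null)
        order = np.argsort(j.ravel())
        assert np.all(np.diff(p.ravel()[order]) <= 1e-12)


class TestFDR:
    def test_manual_step_up_worked_example(self):
        grid = full_mask_grid(4, 2.0)
        p = np.ones(grid.shape)
        p[0, 0, 0], p[0, 0, 1], p[0, 0, 2], p[0, 0, 3] = 0.001, 0.01, 0.02, 0.9
        # restrict the mask to exactly these 4 voxels
        from dualale.stereotax import VoxelGrid

        mask = np.zeros(grid.shape, dtype=bool)
        mask[0, 0, :4] = True
        small = VoxelGrid(shape=grid.shape, affine=grid.affine,
                          voxel_size=grid.voxel_size, mask=mask)
        sig = fdr_threshold(p, small, q=0.05)
        assert sig.sum() == 3
        assert not sig[0, 0, 3]

    def test_all_ones_reject_nothing(self):
        grid = full_mask_grid(3, 2.0)
        assert fdr_threshold(np.ones(grid.shape), grid, 0.05).sum() == 0

    def test_all_minimum_reject_everything(self):
        grid = full_mask_grid(3, 2.0)
        p = np.full(grid.shape, 1e-6)
        assert fdr_threshold(p, grid, 0.05).all()

    def test_bh_between_bonferroni_and_unadjusted(self):
        grid = full_mask_grid(5, 2.0)
        rng = np.random.default_rng(23)
        p = rng.uniform(0, 0.2, grid.shape)
        q = 0.05
        m = p.size
        bh = fdr_threshold(p, grid, q)
        bonf = p <= q / m
        raw = p < q
        assert np.all(bh[bonf])       # BH rejects every Bonferroni rejection
        assert np.all(raw[bh])        # and only unadjusted-significant voxels

    def test_invalid_q_rejected(self):
        grid = full_mask_grid(2, 2.0)
        with pytest.raises(ValueError):
            fdr_threshold(np.ones(grid.shape), grid, 1.5)


class TestClusters:
    def _grid(self):
        return full_mask_grid(12, 2.0)

    def test_singleton_voxel_filtered_by_100mm3(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        sig[5, 5, 5] = True  # 8 mm3 on a 2 mm grid
        j = jmap(grid, sig.astype(float))
        assert extract_clusters(sig, j, 100.0) == []

    def test_3x3x3_block_survives_as_single_cluster(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        sig[4:7, 4:7, 4:7] = True  # 27 voxels * 8 mm3 = 216 mm3
        j = jmap(grid, sig.astype(float))
        clusters = extract_clusters(sig, j, 100.0)
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 27
        assert clusters[0].volume_mm3 == pytest.approx(216.0)

    def test_blocks_separated_by_gap_are_two_clusters(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        sig[1:4, 1:4, 1:4] = True
        sig[1:4, 1:4, 6:9] = True  # 2-voxel gap along z
        j = jmap(grid, sig.astype(float))
        assert len(extract_clusters(sig, j, 100.0)) == 2

    def test_peak_is_max_joint_voxel(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        sig[4:7, 4:7, 4:7] = True
        vals = sig.astype(float)
        vals[5, 6, 4] = 3.0
        clusters = extract_clusters(sig, jmap(grid, vals), 100.0)
        assert clusters[0].peak_ijk == (5, 6, 4)
        assert clusters[0].peak_value == 3.0

    def test_clusters_sorted_by_descending_volume(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        sig[1:3, 1:4, 1:4] = True    # 18 voxels
        sig[6:9, 6:9, 6:9] = True    # 27 voxels
        clusters = extract_clusters(sig, jmap(grid, sig.astype(float)), 100.0)
        assert [c.n_voxels for c in clusters] == [27, 18]
        assert [c.cluster_id for c in clusters] == [1, 2]

    def test_empty_significance_map_gives_empty_list(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        assert extract_clusters(sig, jmap(grid, sig.astype(float))) == []

    def test_unsupported_connectivity_rejected(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        with pytest.raises(ValueError, match="connectivity"):
            extract_clusters(sig, jmap(grid, sig.astype(float)),
                             connectivity=10)

    def test_diagonal_voxels_merge_under_18_but_not_6_connectivity(self):
        grid = self._grid()
        sig = np.zeros(grid.shape, dtype=bool)
        # two 2x2x2 blocks sharing only an edge
        sig[2:4, 2:4, 2:4] = True
        sig[4:6, 4:6, 2:4] = True
        j = jmap(grid, sig.astype(float))
        assert len(extract_clusters(sig, j, 0.0, connectivity=18)) == 1
        assert len(extract_clusters(sig, j, 0.0, connectivity=6)) == 2


class TestPermutationNull:
    def test_zero_permutations_rejected(self, grid4, kernel10):
        studies = two_focus_studies(grid4)
        with pytest.raises(ValueError):
            permute_null(studies, grid4, kernel10, RED, 0, seed=1)

    def test_same_seed_reproduces_null_exactly(self, grid4, kernel10):
        studies = two_focus_studies(grid4)
        a = permute_null(studies, grid4, kernel10, RED, 5, seed=42)
        b = permute_null(studies, grid4, kernel10, RED, 5, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_null_sample_size_is_permutations_times_masked(self, grid4, kernel10):
        studies = two_focus_studies(grid4)
        null = permute_null(studies, grid4, kernel10, RED, 3, seed=0)
        assert null.n_total == 3 * grid4.n_masked

    def test_null_values_match_map_construction_range(self, grid4, kernel10):
        studies = two_focus_studies(grid4)
        null = permute_null(studies, grid4, kernel10, RED, 2, seed=0)
        assert null.values.min() >= 0.0
        assert null.values.max() <= 2.0

    def test_pit_uniform_under_exchangeable_observation(self, grid4):
        # observed data drawn from the same spatial-randomness law as the
        # permutations: thinned randomized-PIT values must look Uniform(0,1)
        from scipy import stats

        from dualale.ale_maps import condition_mean_map, joint_map, study_map

        kernel = KernelSpec(fwhm=12.0)
        pit_all = []
        for seed in range(4):
            studies = two_focus_studies(grid4, n_per_cond=5, n_foci=2,
                                        seed=100 + seed)
            null = permute_null(studies, grid4, kernel, RED, 50,
                                seed=200 + seed)
            maps = {
                c: condition_mean_map(
                    [study_map(s, grid4, kernel, RED) for s in studies
                     if s.condition == c], c)
                for c in ("A", "B")
            }
            joint = joint_map(maps["A"], maps["B"])
            pit_all.append(uniformity_pit(joint, null, kernel,
                                          seed=300 + seed))
        pit = np.concatenate(pit_all)
        ks = stats.kstest(pit, "uniform")
        assert ks.pvalue > 0.01
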