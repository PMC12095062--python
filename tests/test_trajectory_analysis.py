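"""Trajectory statistics: alignment, RMSF, occupancy, angles, filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from rnatube.synthetic.trajectory_gen import TrajectoryConfig, generate_nanotube_trajectory
from rnatube.trajectory import (
    UnitsSpec,
    align_and_mean,
    bond_occupancy,
    compute_rmsf,
    convert_time,
    duplex_angle_beta,
    kl_quality_filter,
    layer_centroids,
)


@pytest.fixture(scope="module")
def cloud():
    rng = np.random.default_rng(0)
    return rng.normal(size=(40, 3)) * [5.0, 2.0, 1.0]


class TestAlignAndRMSF:
    def test_identical_frames_mean_equals_frame(self, cloud):
        frames = [cloud.copy() for _ in range(5)]
        mean, aligned, _, centroid_idx = align_and_mean(frames)
        assert np.allclose(mean, cloud, atol=1e-12)
        assert np.allclose(compute_rmsf(aligned, mean), 0.0, atol=1e-12)
        assert centroid_idx == 0

    def test_pure_rotations_have_zero_rmsf(self, cloud):
        rng = np.random.default_rng(3)
        frames = [cloud] + [
            Rotation.random(random_state=rng).apply(cloud) + rng.normal(size=3)
            for _ in range(6)
        ]
        mean, aligned, _, _ = align_and_mean(frames)
        assert compute_rmsf(aligned, mean).max() < 1e-9

    def test_isotropic_jitter_rmsf_matches_sigma_sqrt3(self):
        """Per-axis Gaussian jitter sigma gives RMSF = sigma * sqrt(3)
        within 5% at 1,000 frames (closed-form expectation)."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(30, 3)) * 50.0
        sigma = 0.5
        frames = [base + rng.normal(0, sigma, base.shape) for _ in range(1000)]
        mean, aligned, _, _ = align_and_mean(frames)
        rmsf = compute_rmsf(aligned, mean)
        assert np.median(rmsf) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_rmsf_invariant_under_global_rigid_motion(self, cloud):
        rng = np.random.default_rng(11)
        frames = [cloud + rng.normal(0, 0.3, cloud.shape) for _ in range(50)]
        mean, aligned, _, _ = align_and_mean(frames)
        base_rmsf = compute_rmsf(aligned, mean)
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0])
        moved = [rot.apply(f) + [10.0, -4.0, 2.5] for f in frames]
        mean2, aligned2, _, _ = align_and_mean(moved)
        assert np.allclose(compute_rmsf(aligned2, mean2), base_rmsf, atol=1e-8)

    def test_single_frame_rejected(self, cloud):
        with pytest.raises(ValueError):
            align_and_mean([cloud])
        with pytest.raises(ValueError):
            compute_rmsf(cloud[None])


class TestOccupancy:
    registry = pd.DataFrame(
        {"i": [0, 2], "j": [1, 3], "category": ["stem", "stem"], "region": ["r", "r"]}
    )

    def frames_with_distance(self, dists):
        frames = []
        for d0, d1 in dists:
            pos = np.zeros((4, 3))
            pos[1, 0] = d0
            pos[3, 0] = d1
            frames.append(pos)
        return frames

    def test_always_bonded_gives_one(self):
        frames = self.frames_with_distance([(1.0, 1.0)] * 5)
        assert bond_occupancy(frames, self.registry, "r", 2.5, positions_in_nm=True) == 1.0

    def test_never_bonded_gives_zero(self):
        frames = self.frames_with_distance([(9.0, 9.0)] * 5)
        assert bond_occupancy(frames, self.registry, "r", 2.5, positions_in_nm=True) == 0.0

    def test_three_of_four_frames_gives_075(self):
        """One pair bonded in 3 of 4 frames: occupancy 0.75 by direct
        count."""
        reg = self.registry.iloc[:1]
        frames = self.frames_with_distance([(1.0, 0), (1.0, 0), (1.0, 0), (9.0, 0)])
        assert bond_occupancy(frames, reg, "r", 2.5, positions_in_nm=True) == 0.75

    def test_frame_order_invariance_and_linearity(self):
        reg = self.registry.iloc[:1]
        dists = [(1.0, 0), (9.0, 0), (1.0, 0), (9.0, 0), (1.0, 0)]
        a = bond_occupancy(self.frames_with_distance(dists), reg, "r", 2.5, positions_in_nm=True)
        b = bond_occupancy(self.frames_with_distance(dists[::-1]), reg, "r", 2.5, positions_in_nm=True)
        assert a == b == 0.6

    def test_missing_region_raises(self):
        with pytest.raises(ValueError):
            bond_occupancy([np.zeros((4, 3))], self.registry, "nope", 2.5)


class TestDuplexAngle:
    def line(self, direction, n=10, origin=(0, 0, 0)):
        t = np.linspace(0, 1, n)[:, None]
        return np.asarray(origin) + t * np.asarray(direction, float) * 20.0

    def test_parallel_duplexes_are_zero_degrees(self):
        pos = np.vstack([self.line([1, 0, 0]), self.line([1, 0, 0], origin=(0, 5, 0))])
        beta = duplex_angle_beta(pos, np.arange(10), np.arange(10, 20))
        assert beta == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_duplexes_are_ninety_degrees(self):
        pos = np.vstack([self.line([1, 0, 0]), self.line([0, 1, 0])])
        assert duplex_angle_beta(pos, np.arange(10), np.arange(10, 20)) == pytest.approx(90.0, abs=1e-6)

    def test_45_degree_rotation_with_noise(self):
        rng = np.random.default_rng(5)
        a = self.line([1, 0, 0])
        b = self.line([np.cos(np.pi / 4), np.sin(np.pi / 4), 0])
        pos = np.vstack([a, b]) + rng.normal(0, 0.2, (20, 3))
        beta = duplex_angle_beta(pos, np.arange(10), np.arange(10, 20))
        assert beta == pytest.approx(45.0, abs=2.0)

    def test_swapped_arguments_give_the_same_angle(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(size=(20, 3)) * [10, 3, 1]
        a, b = np.arange(10), np.arange(10, 20)
        assert duplex_angle_beta(pos, a, b) == pytest.approx(
            duplex_angle_beta(pos, b, a)
        )

    def test_degenerate_duplex_rejected(self):
        pos = np.zeros((8, 3))
        with pytest.raises(ValueError):
            duplex_angle_beta(pos, np.arange(4), np.arange(4, 8))


class TestKLFilter:
    def make_run(self, occupancies, n_frames=10):
        """Synthetic run: one internal KL of 12 pairs; pair p is bonded in
        round(occ*n_frames) frames."""
        registry = pd.DataFrame(
            {
                "i": np.arange(12) * 2,
                "j": np.arange(12) * 2 + 1,
                "category": "internal_KL",
                "region": "T0/iKL0",
            }
        )
        frames = []
        for f in range(n_frames):
            pos = np.zeros((24, 3))
            for p, occ in enumerate(occupancies):
                bonded = f < round(occ * n_frames)
                pos[2 * p + 1, 0] = 1.0 if bonded else 9.0
            frames.append(pos)
        return frames, registry

    def test_fully_bonded_run_passes(self):
        frames, reg = self.make_run([1.0] * 12)
        assert kl_quality_filter([frames], reg, positions_in_nm=True) == [0]

    def test_mean_below_11_fails(self):
        # 12 pairs at 10.9/12 mean bonds
        frames, reg = self.make_run([10.9 / 12.0] * 12, n_frames=120)
        assert kl_quality_filter([frames], reg, positions_in_nm=True) == []

    def test_cohort_matches_brute_force(self):
        """Accepted runs equal a direct recomputation over a cohort with
        known per-run occupancies."""
        rng = np.random.default_rng(4)
        cohort, expected = [], []
        for run_idx in range(6):
            occs = rng.uniform(0.7, 1.0, 12)
            frames, reg = self.make_run(occs, n_frames=50)
            cohort.append(frames)
            counts = [round(o * 50) / 50.0 for o in occs]
            if sum(counts) >= 11.0:
                expected.append(run_idx)
        got = kl_quality_filter(cohort, reg, positions_in_nm=True)
        assert got == expected

    def test_registry_without_internal_kls_raises(self):
        reg = pd.DataFrame({"i": [0], "j": [1], "category": ["stem"], "region": ["r"]})
        with pytest.raises(ValueError):
            kl_quality_filter([[np.zeros((2, 3))]], reg)


class TestUnits:
    def test_timestep_and_total_time(self):
        """dt = 0.003 reduced units is 9.09 fs; 1e9 steps are 9.09 us."""
        fs, us = convert_time(UnitsSpec(dt_sim_units=0.003, steps=10**9))
        assert fs == pytest.approx(9.09, abs=0.005)
        assert us == pytest.approx(9.09, abs=0.005)

    def test_zero_steps(self):
        _, us = convert_time(UnitsSpec(steps=0))
        assert us == 0.0


class TestLayerCentroids:
    def test_straight_tube_centroids_collinear(self, small_assembly):
        cents = layer_centroids(small_assembly.positions_nm, small_assembly.layer_of_nt)
        assert np.abs(cents[:, :2]).max() < 0.2
        assert np.all(np.diff(cents[:, 2]) > 0)

    def test_matches_generator_truth(self, small_assembly):
        cfg = TrajectoryConfig(n_frames=3, bend_P_nm=1000.0, seed=5)
        _, frames, truth = generate_nanotube_trajectory(small_assembly, cfg)
        for frame, expected in zip(frames, truth["layer_centroids_nm"]):
            got = layer_centroids(frame, small_assembly.layer_of_nt)
            assert np.allclose(got, expected, atol=1e-6)

    def test_permutation_invariance(self, small_assembly):
        pos = small_assembly.positions_nm
        layer = small_assembly.layer_of_nt
        perm = np.random.default_rng(2).permutation(pos.shape[0])
        a = layer_centroids(pos, layer)
        b = layer_centroids(pos[perm], layer[perm])
        assert np.allclose(a, b, atol=1e-12)

    def test_empty_layer_raises(self):
        with pytest.raises(ValueError):
            layer_centroids(np.zeros((4, 3)), np.array([0, 0, 2, 2]))
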