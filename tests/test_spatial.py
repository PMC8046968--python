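import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from tomomorph.errors import ComputationError, PlacementError, ValidationError
from tomomorph.scene import Fibril, TomogramScene, resample_polyline
from tomomorph.spatial import (
    DistanceProfile,
    band,
    ensemble_ks_test,
    fibril_membrane_distances,
    inter_membrane_distances,
    ks_compare,
    membrane_distance_field,
    null_ensemble,
    randomize_fibrils,
    simulation_rng,
)

from .conftest import make_sphere_volume, straight_fibril


def scene_from_membrane_voxels(shape, voxels, voxel_size=1.0):
    """Scene whose membrane is an explicit voxel set (label volume left
    empty apart from the membrane voxels as single-voxel organelles)."""
    vol = np.zeros(shape, dtype=np.int32)
    pts = np.asarray(voxels, dtype=np.float64) * voxel_size
    return TomogramScene(
        label_volume=vol,
        voxel_size=voxel_size,
        membrane_points={1: pts},
        tomogram_id="explicit",
    )


class TestDistanceField:
    def test_single_voxel_corner_distance(self):
        scene = scene_from_membrane_voxels((21, 21, 21), [(10, 10, 10)])
        field = membrane_distance_field(scene)
        assert field[0, 0, 0] == pytest.approx(np.sqrt(300.0))
        assert field[10, 10, 10] == 0.0

    def test_two_planes_midplane(self):
        voxels = [(x, y, z) for x in (0, 20) for y in range(21) for z in range(21)]
        scene = scene_from_membrane_voxels((21, 21, 21), voxels)
        field = membrane_distance_field(scene)
        assert field[10, 5, 7] == pytest.approx(10.0)

    def test_matches_brute_force_on_random_voxels(self, rng):
        shape = (32, 32, 32)
        voxels = rng.integers(0, 32, size=(100, 3))
        scene = scene_from_membrane_voxels(shape, voxels, voxel_size=1.5)
        field = membrane_distance_field(scene)
        grid = np.argwhere(np.ones(shape, dtype=bool)) * 1.5
        brute = cdist(grid, np.unique(voxels, axis=0) * 1.5).min(axis=1)
        np.testing.assert_allclose(field.reshape(-1), brute, atol=1e-9)

    def test_no_membrane_raises(self):
        vol = np.zeros((8, 8, 8), dtype=np.int32)
        scene = TomogramScene(label_volume=vol, voxel_size=1.0)
        with pytest.raises(ValidationError):
            membrane_distance_field(scene)

    def test_zero_on_membrane_and_lipschitz(self):
        vol = make_sphere_volume((24, 24, 24), [(12, 12, 12)], [6.0])
        scene = TomogramScene(label_volume=vol, voxel_size=1.0)
        field = membrane_distance_field(scene)
        mask = scene.membrane_mask
        assert np.all(field[mask] == 0.0)
        for axis in range(3):
            assert np.max(np.abs(np.diff(field, axis=axis))) <= 1.0 + 1e-9


class TestFibrilMembraneDistances:
    def test_point_four_nm_away(self):
        scene = scene_from_membrane_voxels((21, 21, 21), [(10, 14, 10)])
        field = membrane_distance_field(scene)
        fib = Fibril(points=np.array([[10.0, 10.0, 10.0], [10.0, 11.0, 10.0]]))
        sample = fibril_membrane_distances([fib], field, scene)
        assert sample.values[0] == pytest.approx(4.0, abs=1e-9)

    def test_chord_through_spherical_shell(self):
        vs = 2.0
        vol = make_sphere_volume(
            (64, 64, 64), [(63.0, 63.0, 63.0)], [50.0], voxel_size=vs
        )
        scene = TomogramScene(label_volume=vol, voxel_size=vs)
        field = membrane_distance_field(scene)
        fib = straight_fibril(99.0, n=100)
        fib = Fibril(points=fib.points + np.array([13.5, 63.0, 63.0]))
        sample = fibril_membrane_distances([fib], field, scene)
        assert sample.values.min() < 2.5 * vs  # crossing: near zero
        # boundary voxels sit up to ~3 voxels inside the analytic surface
        assert sample.values.max() == pytest.approx(50.0, abs=3.0 * vs)

    def test_empty_list(self):
        scene = scene_from_membrane_voxels((8, 8, 8), [(4, 4, 4)])
        field = membrane_distance_field(scene)
        sample = fibril_membrane_distances([], field, scene)
        assert len(sample) == 0

    def test_outside_grid_names_fibril(self):
        scene = scene_from_membrane_voxels((8, 8, 8), [(4, 4, 4)])
        field = membrane_distance_field(scene)
        fib = Fibril(
            points=np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]]), id="runaway"
        )
        with pytest.raises(ValidationError, match="runaway"):
            fibril_membrane_distances([fib], field, scene)


class TestInterMembrane:
    def test_two_spheres_minimum_gap(self, two_sphere_scene):
        sample = inter_membrane_distances(two_sphere_scene)
        # centres 100 nm apart, radii 30 + 40 -> 30 nm surface gap
        assert sample.values.min() == pytest.approx(30.0, abs=2 * 2.0)

    def test_matches_brute_force(self, two_sphere_scene):
        scene = two_sphere_scene
        sample = inter_membrane_distances(scene)
        pts = scene.membrane_points
        brute = np.concatenate([
            cdist(pts[1], pts[2]).min(axis=1),
            cdist(pts[2], pts[1]).min(axis=1),
        ])
        np.testing.assert_allclose(np.sort(sample.values), np.sort(brute), atol=1e-9)

    def test_three_organelles_near_far(self):
        vol = np.zeros((120, 20, 20), dtype=np.int32)
        vol[10:14, 8:12, 8:12] = 1
        vol[16:20, 8:12, 8:12] = 2  # 2 voxels from organelle 1
        vol[110:114, 8:12, 8:12] = 3  # ~90 voxels away
        scene = TomogramScene(label_volume=vol, voxel_size=1.0)
        sample = inter_membrane_distances(scene)
        a = sample.values[sample.source_ids == 1]
        c = sample.values[sample.source_ids == 3]
        assert a.min() == pytest.approx(3.0)  # boundary voxels 13 -> 16
        assert c.min() > 80.0

    def test_touching_cubes_one_voxel_apart(self):
        vol = np.zeros((12, 8, 8), dtype=np.int32)
        vol[2:5, 2:5, 2:5] = 1
        vol[5:8, 2:5, 2:5] = 2
        scene = TomogramScene(label_volume=vol, voxel_size=1.0)
        sample = inter_membrane_distances(scene)
        assert sample.values.min() == pytest.approx(1.0)

    def test_single_organelle_undefined(self):
        vol = np.zeros((10, 10, 10), dtype=np.int32)
        vol[4:6, 4:6, 4:6] = 1
        scene = TomogramScene(label_volume=vol, voxel_size=1.0)
        with pytest.raises(ValidationError, match="undefined"):
            inter_membrane_distances(scene)


class TestRandomize:
    def empty_scene(self, shape=(50, 50, 25), vs=4.0):
        return TomogramScene(
            label_volume=np.zeros(shape, dtype=np.int32), voxel_size=vs
        )

    def test_centroid_uniform_in_admissible_box(self, rng):
        scene = self.empty_scene()
        fib = straight_fibril(40.0, n=5)
        xs = []
        for _ in range(10_000):
            moved, retries = randomize_fibrils(scene, [fib], rng)
            assert retries[0] == 0  # no organelles: first draw accepted
            xs.append(moved[0].centroid[0])
        xs = np.asarray(xs)
        lo, hi = 20.0, 180.0  # 40 nm straight fibril in a 200 nm box
        counts, _ = np.histogram(xs, bins=10, range=(lo, hi))
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3

    def test_lengths_preserved(self, rng):
        scene = self.empty_scene()
        fibs = [straight_fibril(60.0, n=7, id=f"f{i}") for i in range(10)]
        moved, _ = randomize_fibrils(scene, fibs, rng)
        for a, b in zip(fibs, moved):
            assert b.length == pytest.approx(a.length, rel=1e-12)
            np.testing.assert_allclose(
                b.segment_lengths, a.segment_lengths, rtol=1e-9
            )

    def test_infeasible_fibril_raises(self, rng):
        scene = self.empty_scene()
        fib = straight_fibril(500.0, n=10)  # longer than any box dimension
        with pytest.raises(PlacementError):
            randomize_fibrils(scene, [fib], rng, max_retries=50)

    def test_fixed_seed_reproducible(self):
        scene = self.empty_scene()
        fibs = [straight_fibril(60.0, n=4, id=f"f{i}") for i in range(5)]
        a, _ = randomize_fibrils(scene, fibs, np.random.default_rng(99))
        b, _ = randomize_fibrils(scene, fibs, np.random.default_rng(99))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.points, fb.points)

    def test_lumen_rejection(self, rng):
        vol = np.zeros((40, 40, 40), dtype=np.int32)
        vol[10:30, 10:30, 10:30] = 1
        scene = TomogramScene(label_volume=vol, voxel_size=1.0)
        fibs = [straight_fibril(12.0, n=13, id=f"f{i}") for i in range(20)]
        moved, _ = randomize_fibrils(scene, fibs, rng)
        for f in moved:
            assert np.all(scene.labels_at(f.points) == 0)

    def test_in_plane_mode_keeps_z_extent(self, rng):
        scene = self.empty_scene()
        pts = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 10.0]])
        fib = Fibril(points=pts)
        moved, _ = randomize_fibrils(scene, [fib], rng, rotations="in_plane")
        dz = np.ptp(moved[0].points[:, 2])
        assert dz == pytest.approx(10.0, abs=1e-9)


class TestNullEnsemble:
    def test_reproducible_single_sim(self):
        vol = make_sphere_volume((40, 40, 20), [(80.0, 80.0, 40.0)], [20.0], 4.0)
        scene = TomogramScene(label_volume=vol, voxel_size=4.0, tomogram_id="t")
        field = membrane_distance_field(scene)
        fibs = [straight_fibril(60.0, n=16, id=f"f{i}") for i in range(5)]
        edges = np.arange(0.0, 102.0, 2.0)
        a = null_ensemble(scene, fibs, field, edges, n_simulations=1, seed=5)
        b = null_ensemble(scene, fibs, field, edges, n_simulations=1, seed=5)
        np.testing.assert_array_equal(a.samples[0], b.samples[0])
        np.testing.assert_array_equal(
            a.profiles[0].frequencies, b.profiles[0].frequencies
        )

    def test_substreams_differ_by_index_and_id(self):
        r1 = simulation_rng(1, "tomo_a", 0).integers(0, 1 << 30)
        r2 = simulation_rng(1, "tomo_a", 1).integers(0, 1 << 30)
        r3 = simulation_rng(1, "tomo_b", 0).integers(0, 1 << 30)
        assert len({r1, r2, r3}) == 3

    def test_preserves_fibril_count_and_shape(self):
        vol = make_sphere_volume((40, 40, 20), [(80.0, 80.0, 40.0)], [20.0], 4.0)
        scene = TomogramScene(label_volume=vol, voxel_size=4.0, tomogram_id="t")
        field = membrane_distance_field(scene)
        fibs = [straight_fibril(60.0, n=16, id=f"f{i}") for i in range(5)]
        ens = null_ensemble(
            scene, fibs, field, np.arange(0.0, 102.0, 2.0),
            n_simulations=3, seed=1,
        )
        assert ens.n_simulations == 3
        for s in ens.samples:
            assert s.size == 5 * 16


class TestBand:
    def edges(self):
        return np.arange(0.0, 11.0, 1.0)

    def profile(self, freqs):
        freqs = np.asarray(freqs, dtype=float)
        return DistanceProfile(
            bin_edges=self.edges(), frequencies=freqs, sample_count=100
        )

    def test_identical_curves_zero_width(self):
        f = np.full(10, 0.1)
        b = band([self.profile(f) for _ in range(7)])
        np.testing.assert_allclose(b.lower, b.upper)
        np.testing.assert_allclose(b.median, f)

    def test_order_statistics_oracle(self):
        values = [(i + 1) / 100 for i in range(100)]
        profiles = [self.profile(np.full(10, v)) for v in values]
        b = band(profiles)
        arr = np.array(values)
        np.testing.assert_allclose(b.median, np.percentile(arr, 50))
        np.testing.assert_allclose(b.lower, np.percentile(arr, 5))
        np.testing.assert_allclose(b.upper, np.percentile(arr, 95))
        assert b.median[0] == pytest.approx(0.505)

    def test_single_curve_degenerate(self):
        f = np.linspace(0.0, 0.2, 10)
        b = band([self.profile(f)])
        np.testing.assert_allclose(b.median, f)
        np.testing.assert_allclose(b.lower, f)
        np.testing.assert_allclose(b.upper, f)

    def test_mismatched_bins_error(self):
        p1 = self.profile(np.full(10, 0.1))
        p2 = DistanceProfile(
            bin_edges=np.arange(0.0, 22.0, 2.0),
            frequencies=np.full(10, 0.1),
            sample_count=1,
        )
        with pytest.raises(ValidationError):
            band([p1, p2])

    def test_profile_frequencies_sum_to_one(self, rng):
        values = rng.uniform(0, 10, size=500)
        prof = DistanceProfile.from_sample(values, self.edges())
        assert prof.frequencies.sum() == pytest.approx(1.0)
        assert prof.sample_count == 500


class TestKS:
    def test_identical_samples(self):
        x = np.linspace(0.0, 15.0, 50)
        res = ks_compare(x, x.copy())
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.linspace(0.0, 5.0, 40)
        b = np.linspace(10.0, 20.0, 40)
        res = ks_compare(a, b, cutoff=20.0)
        assert res.statistic == 1.0
        assert res.pvalue < 1e-6

    def test_empty_after_truncation(self):
        with pytest.raises(ComputationError, match="cutoff"):
            ks_compare(np.array([30.0, 40.0]), np.array([5.0]), cutoff=20.0)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.uniform(0.0, 20.0, size=500)
            b = rng.uniform(0.0, 20.0, size=500)
            if ks_compare(a, b).pvalue < 0.05:
                rejections += 1
        assert 0.036 <= rejections / n_rep <= 0.064

    def test_truncation_counts(self):
        a = np.array([1.0, 5.0, 30.0])
        b = np.array([2.0, 50.0, 60.0])
        res = ks_compare(a, b, cutoff=20.0)
        assert res.n_truncated_a == 1
        assert res.n_truncated_b == 2


class TestEnsembleKS:
    def test_detects_planted_shift(self, rng):
        sims = [rng.uniform(0.0, 20.0, size=300) for _ in range(19)]
        exp = rng.uniform(0.0, 20.0, size=300) ** 2 / 20.0  # skewed low
        res = ensemble_ks_test(exp, sims)
        assert res.pvalue == pytest.approx(1.0 / 20.0)

    def test_null_case_not_extreme(self, rng):
        pvals = []
        for _ in range(20):
            sims = [rng.uniform(0.0, 20.0, size=200) for _ in range(19)]
            exp = rng.uniform(0.0, 20.0, size=200)
            pvals.append(ensemble_ks_test(exp, sims).pvalue)
        assert np.mean(pvals) > 0.2  # roughly uniform, not clustered at 0

    def test_requires_simulations(self, rng):
        with pytest.raises(ComputationError):
            ensemble_ks_test(rng.uniform(0, 20, 50), [np.array([1.0])])
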