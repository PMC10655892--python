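"""Shape, stiffness, contact-scaling and clustering analyses vs oracles."""

import numpy as np
import pytest
from scipy.stats import poisson

from condensac.fixtures import (
    blob_coords,
    cylinder_shell_coords,
    helix_coords,
    rod_coords,
    sphere_shell_coords,
)
from condensac.observables import (
    WrappedCoordinateError,
    bridge_valence,
    bristle_repulsion,
    cluster_bridges,
    contact_probability,
    extension_and_width,
    gyration_tensor_shape,
    local_stiffness,
    persistence_length,
    probe_distance,
    radius_of_gyration,
    tangent_correlation,
)
from condensac.units import UnitSystem


class TestRadiusOfGyration:
    def test_single_bead_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_symmetric_dumbbell(self):
        pos = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        assert radius_of_gyration(pos) == pytest.approx(1.5)

    def test_matches_direct_formula_on_random_beads(self):
        rng = np.random.default_rng(1)
        pos = rng.standard_normal((50, 3)) * 4.0
        com = pos.mean(axis=0)
        direct = np.sqrt(np.mean(np.sum((pos - com) ** 2, axis=1)))
        assert radius_of_gyration(pos) == pytest.approx(direct, rel=1e-12)

    def test_wrapped_coordinates_detected(self):
        pos = np.array([[0.0, 0.0, 0.0], [9.0, 0.0, 0.0]])
        bonds = np.array([[0, 1]])
        with pytest.raises(WrappedCoordinateError):
            radius_of_gyration(pos, box=10.0, bonds=bonds)


class TestGyrationShape:
    def test_collinear_beads_rank_one(self):
        shape = gyration_tensor_shape(rod_coords(40))
        assert shape.axes[0] == pytest.approx(0.0, abs=1e-10)
        assert shape.axes[1] == pytest.approx(0.0, abs=1e-10)
        assert shape.Ac == pytest.approx(0.0, abs=1e-10)

    def test_sphere_shell_is_spherical(self):
        shape = gyration_tensor_shape(sphere_shell_coords(4000, radius=5.0))
        assert shape.axes[2] / shape.axes[0] == pytest.approx(1.0, abs=0.05)
        assert shape.Ac < 0.15

    def test_cylinder_shell_has_zero_acylindricity(self):
        shape = gyration_tensor_shape(
            cylinder_shell_coords(4000, radius=4.0, length=40.0)
        )
        assert shape.axes[2] > 2 * shape.axes[1]
        assert shape.Ac == pytest.approx(0.0, abs=0.15)

    def test_rg_squared_equals_sum_of_squared_axes(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pos = rng.standard_normal((60, 3)) * rng.uniform(1, 5, size=3)
            shape = gyration_tensor_shape(pos)
            assert shape.Rg**2 == pytest.approx(
                float((shape.axes**2).sum()), rel=1e-12
            )
            assert shape.Rg == pytest.approx(
                radius_of_gyration(pos), rel=1e-12
            )

    def test_invariant_under_rotation(self):
        pos = blob_coords(150)
        theta = 1.1
        rot = np.array([
            [np.cos(theta), 0, np.sin(theta)],
            [0, 1, 0],
            [-np.sin(theta), 0, np.cos(theta)],
        ])
        a = gyration_tensor_shape(pos)
        b = gyration_tensor_shape(pos @ rot.T + [2.0, -1.0, 0.5])
        assert a.axes == pytest.approx(b.axes, rel=1e-9)


class TestTangentCorrelation:
    def test_straight_backbone_is_unity_everywhere(self):
        seps, corr = tangent_correlation(rod_coords(60), stride=5)
        assert np.allclose(corr, 1.0, atol=1e-12)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_ideal_helix_matches_closed_form(self, stride):
        radius, pitch, ppt = 2.0, 3.0, 10
        pos = helix_coords(200, radius=radius, pitch=pitch,
                           points_per_turn=ppt)
        seps, corr = tangent_correlation(pos, stride=stride, max_sep=12)
        dtheta = 2 * np.pi * stride / ppt
        a = 2 * radius * np.sin(dtheta / 2)     # rotating chord component
        b = pitch * stride / ppt                # axial component
        expected = (a**2 * np.cos(seps * dtheta) + b**2) / (a**2 + b**2)
        assert corr == pytest.approx(expected, abs=1e-9)

    def test_stride_too_large_rejected(self):
        with pytest.raises(ValueError):
            tangent_correlation(rod_coords(6), stride=10)


class TestPersistenceLength:
    def test_discrete_wormlike_chain_sampler_oracle(self):
        # bond angles drawn from p(cos a) ~ exp(k cos a): the tangent
        # correlation decays with <cos a> = coth(k) - 1/k per bond
        k, b, n_bonds, n_chains = 3.0, 1.0, 300, 60
        rng = np.random.default_rng(12)
        mean_cos = 1.0 / np.tanh(k) - 1.0 / k
        expected_lp = -b / np.log(mean_cos)
        frames = []
        for _ in range(n_chains):
            t = np.array([0.0, 0.0, 1.0])
            pts = [np.zeros(3)]
            for _ in range(n_bonds):
                u = rng.uniform()
                cos_a = 1.0 + np.log(u + (1 - u) * np.exp(-2 * k)) / k
                sin_a = np.sqrt(max(0.0, 1 - cos_a**2))
                phi = rng.uniform(0, 2 * np.pi)
                # local frame perpendicular to t
                ref = np.array([1.0, 0.0, 0.0])
                if abs(t @ ref) > 0.9:
                    ref = np.array([0.0, 1.0, 0.0])
                e1 = np.cross(t, ref)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(t, e1)
                t = cos_a * t + sin_a * (np.cos(phi) * e1 + np.sin(phi) * e2)
                t /= np.linalg.norm(t)
                pts.append(pts[-1] + b * t)
            frames.append(pts)
        lp = persistence_length(np.array(frames), fit_max=8)
        assert lp == pytest.approx(expected_lp, rel=0.05)


class TestContactProbability:
    def test_bonded_neighbours_always_in_contact(self):
        rng = np.random.default_rng(3)
        frames = np.cumsum(rng.standard_normal((5, 80, 3)), axis=1)
        curve = contact_probability(
            frames, contact_cutoff=50.0,
            units=UnitSystem(bp_per_bead=1000),
            fit_range_kbp=(2, 20),
        )
        assert curve.P[0] == pytest.approx(1.0)

    def test_ideal_chain_ensemble_scales_as_minus_three_halves(self):
        # freely jointed chain oracle: P(s) ~ s^(-3/2) at intermediate s
        rng = np.random.default_rng(7)
        n, chains = 400, 150
        steps = rng.standard_normal((chains, n, 3))
        steps /= np.linalg.norm(steps, axis=2, keepdims=True)
        frames = np.cumsum(steps, axis=1)
        curve = contact_probability(
            frames, contact_cutoff=1.5,
            units=UnitSystem(bp_per_bead=1000),   # 1 bead = 1 kbp
            fit_range_kbp=(8, 80),
        )
        assert curve.fit_exponent == pytest.approx(-1.5, abs=0.15)


class TestClustering:
    def test_all_isolated_and_single_blob(self):
        far = np.diag([10.0, 20.0, 30.0])
        stats = cluster_bridges(far, linkage_cutoff=1.3)
        assert stats.N_c == 3 and set(stats.cluster_sizes) == {1}
        blob = np.random.default_rng(2).uniform(0, 0.5, (12, 3))
        stats = cluster_bridges(blob, linkage_cutoff=1.3)
        assert stats.N_c == 1 and stats.cluster_sizes[0] == 12

    def test_matches_adjacency_matrix_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 6.0, (30, 3))
        cutoff = 1.3
        dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        graph = nx.from_numpy_array((dist < cutoff) & ~np.eye(30, dtype=bool))
        oracle = sorted(len(c) for c in nx.connected_components(graph))
        stats = cluster_bridges(pos, linkage_cutoff=cutoff)
        assert sorted(stats.cluster_sizes) == oracle
        assert stats.S_c == pytest.approx(30 / stats.N_c)

    def test_bridging_particle_merges_two_clusters(self):
        left = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        right = np.array([[2.4, 0, 0], [3.4, 0, 0]])
        pos = np.vstack([left, right])
        before = cluster_bridges(pos, linkage_cutoff=1.1)
        assert before.N_c == 2
        after = cluster_bridges(
            np.vstack([pos, [[1.7, 0, 0]]]), linkage_cutoff=1.1
        )
        assert after.N_c == before.N_c - 1

    def test_sizes_conserve_bridge_count(self):
        pos = np.random.default_rng(4).uniform(0, 8, (40, 3))
        stats = cluster_bridges(pos)
        assert stats.cluster_sizes.sum() == 40

    def test_empty_input(self):
        stats = cluster_bridges(np.empty((0, 3)))
        assert stats.N_c == 0


class TestBridgeValence:
    def test_isolated_bridge_zero(self):
        chrom = np.zeros((5, 3)) + [10.0, 0, 0]
        assert bridge_valence(np.zeros((1, 3)), chrom) == 0.0

    def test_constructed_k_beads_at_unit_distance(self):
        k = 4
        bridge = np.zeros((1, 3))
        theta = 2 * np.pi * np.arange(k) / k
        chrom = np.stack(
            [np.cos(theta), np.sin(theta), np.zeros(k)], axis=1
        )  # all at distance 1.0 < 1.1
        assert bridge_valence(bridge, chrom) == pytest.approx(k)


class TestExtensionAndWidth:
    def test_straight_rod(self):
        pos = rod_coords(50, spacing=1.0)
        ext, width = extension_and_width(pos, (0, 49))
        assert ext == pytest.approx(49.0)
        assert width == pytest.approx(0.0, abs=1e-10)

    def test_cylinder_shell_width_is_diameter(self):
        pos = cylinder_shell_coords(5000, radius=4.0, length=60.0)
        _, width = extension_and_width(pos, (0, 1))
        assert width == pytest.approx(8.0, rel=0.02)


class TestLocalStiffness:
    def test_straight_backbone(self):
        assert local_stiffness(rod_coords(30), stride=2) == pytest.approx(1.0)

    def test_right_angle_square_wave(self):
        # unit steps alternating +x, +y: every turn is 90 degrees
        steps = np.array([[1.0, 0, 0], [0, 1.0, 0]] * 10)
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        assert local_stiffness(pos, stride=1) == pytest.approx(0.0, abs=1e-12)

    def test_random_walk_is_uncorrelated(self):
        rng = np.random.default_rng(21)
        steps = rng.standard_normal((4000, 3))
        pos = np.cumsum(steps, axis=0)
        assert abs(local_stiffness(pos, stride=1)) < 0.05


class TestProbeDistance:
    def test_identical_regions_zero(self):
        frames = np.random.default_rng(1).standard_normal((3, 20, 3))
        assert probe_distance(frames, (2, 6), (2, 6)) == 0.0

    def test_two_static_points(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 7.0
        assert probe_distance(frames, (0, 1), (1, 2)) == pytest.approx(7.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            probe_distance(np.zeros((1, 5, 3)), (2, 2), (3, 4))


class TestBristleRepulsion:
    def test_sqrt_scaling_in_monomer_number(self):
        f1 = bristle_repulsion(1.0, 1.5, 1.0, 40)
        f4 = bristle_repulsion(1.0, 1.5, 1.0, 160)
        assert f4 / f1 == pytest.approx(2.0)

    def test_spacing_scaling_minus_three_halves(self):
        f1 = bristle_repulsion(1.0, 1.0, 1.0, 40)
        f4 = bristle_repulsion(1.0, 4.0, 1.0, 40)
        assert f4 / f1 == pytest.approx(1.0 / 8.0)

    def test_poisson_average_below_uniform_by_concavity(self):
        mean = 40
        ks = np.arange(5, 200)
        pmf = poisson.pmf(ks, mean)
        pmf /= pmf.sum()
        f_poisson = np.sum(
            pmf * [bristle_repulsion(1.0, 1.5, 1.0, k) for k in ks]
        )
        f_uniform = bristle_repulsion(1.0, 1.5, 1.0, mean)
        assert f_poisson < f_uniform
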