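"""Integrator physics: determinism, thermostat, diffusion, conservation."""

import numpy as np
import pytest

from condensac.dynamics import (
    IntegrationError,
    PullingConfig,
    SimulationState,
    apply_end_forces,
    compute_forces_energy,
    langevin_run,
    neighbor_pairs,
)
from condensac.forcefield import ForceField
from condensac.topology import (
    ChromosomeTopology,
    build_uniform_bottlebrush,
    initial_bottlebrush_coords,
    place_bridges,
)


def free_particles(n: int) -> ChromosomeTopology:
    """Ideal-gas topology: no bonds, no angles, no loops."""
    return ChromosomeTopology(
        species=np.zeros(n, dtype=np.int8),
        chain_bonds=np.empty((0, 2), dtype=np.int64),
        loop_springs=np.empty((0, 2), dtype=np.int64),
        angle_triplets=np.empty((0, 3), dtype=np.int64),
        loop_table=np.empty((0, 2), dtype=np.int64),
    )


def dumbbell() -> ChromosomeTopology:
    return ChromosomeTopology(
        species=np.zeros(2, dtype=np.int8),
        chain_bonds=np.array([[0, 1]], dtype=np.int64),
        loop_springs=np.empty((0, 2), dtype=np.int64),
        angle_triplets=np.empty((0, 3), dtype=np.int64),
        loop_table=np.empty((0, 2), dtype=np.int64),
    )


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_trajectory(self):
        topo = build_uniform_bottlebrush(3, 6)
        pos = initial_bottlebrush_coords(topo, seed=1)
        ff = ForceField(A=10.0)
        runs = []
        for _ in range(2):
            st = SimulationState.create(pos, box=30.0, seed=77)
            traj = langevin_run(st, topo, ff, 400, stride=100)
            runs.append((traj.frames.copy(), st.positions.copy(),
                         st.velocities.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])
        assert np.array_equal(runs[0][2], runs[1][2])

    def test_different_seed_diverges(self):
        topo = build_uniform_bottlebrush(3, 6)
        pos = initial_bottlebrush_coords(topo, seed=1)
        ff = ForceField(A=10.0)
        st1 = SimulationState.create(pos, box=30.0, seed=77)
        st2 = SimulationState.create(pos, box=30.0, seed=78)
        langevin_run(st1, topo, ff, 200)
        langevin_run(st2, topo, ff, 200)
        assert not np.array_equal(st1.positions, st2.positions)


class TestThermostat:
    def test_single_free_particle_equipartition(self):
        topo = free_particles(1)
        st = SimulationState.create(np.zeros((1, 3)), box=0.0, seed=5)
        traj = langevin_run(st, topo, ForceField(A=0.0), 100_000, stride=200)
        # <KE> = (3/2) kBT per particle; ~500 samples decorrelated over tau
        mean_ke = float(traj.kinetic.mean())
        se = float(traj.kinetic.std()) / np.sqrt(traj.n_frames / 2)
        assert abs(mean_ke - 1.5) < max(3 * se, 0.08)

    def test_kinetic_temperature_within_two_percent_on_500_beads(self):
        topo = build_uniform_bottlebrush(50, 10)
        pos = initial_bottlebrush_coords(topo, seed=2)
        st = SimulationState.create(pos, box=80.0, seed=9)
        ff = ForceField(A=10.0)
        langevin_run(st, topo, ff, 2000)  # settle
        traj = langevin_run(st, topo, ff, 20_000, stride=100)
        t_kin = 2.0 * traj.kinetic.mean() / (3.0 * topo.n_beads)
        assert t_kin == pytest.approx(1.0, rel=0.02)


class TestFreeDiffusion:
    def test_msd_slope_matches_einstein_relation(self):
        # 100 non-interacting beads: MSD = 6 (kBT/gamma) t at t >> m/gamma
        n = 100
        topo = free_particles(n)
        st = SimulationState.create(np.zeros((n, 3)), box=0.0, seed=3)
        lag_tau = 20.0
        traj = langevin_run(st, topo, ForceField(A=0.0), 40_000, stride=2000)
        disp = np.diff(traj.frames, axis=0)      # independent 20-tau hops
        msd = float((disp**2).sum(axis=2).mean())
        assert msd == pytest.approx(6.0 * lag_tau, rel=0.1)


class TestEnergyConservation:
    def test_velocity_verlet_limit_drift_below_1e4(self):
        # at gamma=0 (no noise) the splitting reduces to velocity Verlet;
        # dt=0.002 keeps the bounded shadow-Hamiltonian oscillation of the
        # stiff K=100 bonds below the drift tolerance being checked
        topo = build_uniform_bottlebrush(4, 8)
        pos = initial_bottlebrush_coords(topo, seed=4)
        st = SimulationState.create(pos, box=40.0, seed=11)
        ff = ForceField(A=10.0)
        langevin_run(st, topo, ff, 2000)  # thermalise with gamma=1
        def total_energy_now():
            _, pe = compute_forces_energy(st.positions, topo, ff, box=st.box)
            return pe + 0.5 * float((st.velocities**2).sum())
        e0 = total_energy_now()
        langevin_run(st, topo, ff, 10_000, gamma=0.0, dt=0.002)
        e1 = total_energy_now()
        assert abs(e1 - e0) / abs(e0) < 1e-4


class TestNeighborList:
    def test_pair_present_below_and_absent_beyond(self):
        pos = np.array([[0.0, 0, 0], [2.35, 0, 0], [9.0, 0, 0]])
        pairs = neighbor_pairs(pos, box=30.0, cutoff=2.4, skin=0.4)
        assert [0, 1] in pairs.tolist()
        assert [0, 2] not in pairs.tolist()
        far = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert neighbor_pairs(far, box=30.0, cutoff=2.4, skin=0.4).size == 0

    def test_minimum_image_violation_rejected(self):
        pos = np.zeros((4, 3))
        with pytest.raises(ValueError, match="minimum-image"):
            neighbor_pairs(pos, box=4.0, cutoff=2.4, skin=0.4)

    def test_periodic_wraparound_pair_found(self):
        pos = np.array([[0.5, 0, 0], [19.5, 0, 0]])  # 1.0 apart via image
        pairs = neighbor_pairs(pos, box=20.0, cutoff=2.4)
        assert [0, 1] in pairs.tolist()


class TestEndForces:
    def test_net_external_force_is_zero(self):
        topo = build_uniform_bottlebrush(2, 10)
        pos = initial_bottlebrush_coords(topo, seed=6)
        st = SimulationState.create(pos, box=40.0, seed=1)
        field = apply_end_forces(st, PullingConfig(5.0, 0, 19))
        assert np.allclose(field.sum(axis=0), 0.0)
        assert np.linalg.norm(field[0]) == pytest.approx(5.0)

    def test_dumbbell_mean_extension_from_force_balance(self):
        # U = K (r - r0)^2 under +-F along the axis: <r> ~ r0 + F/(2K)
        topo = dumbbell()
        pos = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        st = SimulationState.create(pos, box=0.0, seed=13)
        pulling = PullingConfig(20.0, 0, 1)
        ff = ForceField(A=0.0)
        langevin_run(st, topo, ff, 2000, pulling=pulling)
        traj = langevin_run(st, topo, ff, 40_000, stride=50, pulling=pulling)
        r = np.linalg.norm(
            traj.frames[:, 0] - traj.frames[:, 1], axis=1
        )
        assert r.mean() == pytest.approx(1.1 + 20.0 / 200.0, rel=0.02)

    def test_zero_force_identical_to_unpulled_run(self):
        topo = build_uniform_bottlebrush(2, 8)
        pos = initial_bottlebrush_coords(topo, seed=8)
        ff = ForceField(A=10.0)
        st1 = SimulationState.create(pos, box=30.0, seed=21)
        st2 = SimulationState.create(pos, box=30.0, seed=21)
        langevin_run(st1, topo, ff, 300)
        langevin_run(st2, topo, ff, 300, pulling=PullingConfig(0.0, 0, 15))
        assert np.array_equal(st1.positions, st2.positions)

    def test_coincident_pull_beads_rejected(self):
        with pytest.raises(ValueError):
            PullingConfig(1.0, 3, 3)


class TestFailureModes:
    def test_non_finite_coordinates_raise_integration_error(self):
        topo = free_particles(3)
        pos = np.zeros((3, 3))
        pos[0, 0] = np.nan
        st = SimulationState.create(pos, box=0.0, seed=2)
        with pytest.raises(IntegrationError):
            langevin_run(st, topo, ForceField(A=0.0), 100, stride=50)

    def test_state_topology_mismatch_rejected(self):
        topo = build_uniform_bottlebrush(2, 6)
        st = SimulationState.create(np.zeros((5, 3)), box=20.0, seed=1)
        with pytest.raises(ValueError):
            langevin_run(st, topo, ForceField(), 10)


class TestBridgedSystemSmoke:
    def test_bridges_bind_and_energy_stays_finite(self):
        topo = build_uniform_bottlebrush(6, 10)
        pos = initial_bottlebrush_coords(topo, seed=3)
        bridges = place_bridges(12, 40.0, seed=5, near=pos)
        st = SimulationState.create(np.vstack([pos, bridges]), box=40.0,
                                    seed=31)
        ff = ForceField(A=1.0)
        traj = langevin_run(st, topo, ff, 5000, stride=1000)
        assert np.isfinite(st.positions).all()
        assert traj.n_frames == 5
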