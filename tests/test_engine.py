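"""Langevin integrator: determinism, thermostat physics, schedule bookkeeping."""

import numpy as np
import pytest

import mitobrush as mb
from mitobrush.builder import sample_loops
from mitobrush.engine import Simulator, default_end_regions
from mitobrush.errors import ConfigError
from mitobrush.state import SimulationState


def _two_bead_state(r0=5.0, box=200.0):
    """Two beads joined by a harmonic spring, far outside all pair cutoffs."""
    ann = sample_loops(2, (2_000, 4_000), seed=0)
    return SimulationState(
        chromatin_coords=np.array([[0.0, 0, 0], [r0, 0, 0]]),
        bridge_coords=np.empty((0, 3)),
        chromatin_vel=np.zeros((2, 3)),
        bridge_vel=np.empty((0, 3)),
        bonds=np.array([[0, 1]]),
        bond_kinds=np.array([2], dtype=np.int8),  # harmonic
        annotation=ann,
        box=np.full(3, box),
    )


class TestIntegrator:
    def test_velocity_decay_of_free_damped_particle(self):
        # zero force, zero temperature: v(t) = v0 * exp(-gamma * t)
        state = _two_bead_state(r0=50.0)
        state.chromatin_vel[:] = [[1.0, 0, 0], [1.0, 0, 0]]
        eng = mb.EngineParams(dt=0.01, friction=2.0, temperature=0.0, seed=1)
        params = mb.ForceFieldParams(centromere_k=0.0)
        out = mb.langevin_step(state, eng, params, n_steps=100)
        expected = np.exp(-2.0 * 0.01 * 100)
        np.testing.assert_allclose(out.chromatin_vel[:, 0], expected, rtol=1e-10)

    def test_same_seed_bitwise_identical(self, mini_state):
        eng = mb.EngineParams(seed=123)
        a = mb.langevin_step(mini_state, eng, mb.ForceFieldParams(), n_steps=200)
        b = mb.langevin_step(mini_state, eng, mb.ForceFieldParams(), n_steps=200)
        np.testing.assert_array_equal(a.chromatin_coords, b.chromatin_coords)
        np.testing.assert_array_equal(a.bridge_vel, b.bridge_vel)

    def test_equipartition_in_harmonic_well(self):
        """Stationary bond-length variance approaches kT/k (radial dof)."""
        k, r0 = 50.0, 5.0
        params = mb.ForceFieldParams(centromere_k=k)
        sim = Simulator(_two_bead_state(r0=r0), params, mb.EngineParams(seed=4), phase=2)
        sim.run(5_000)  # thermalise
        samples = []
        for _ in range(1_500):
            sim.run(40)
            d = sim.pos[1] - sim.pos[0]
            samples.append(np.linalg.norm(d))
        var = np.var(samples, ddof=1)
        assert abs(var - 1.0 / k) / (1.0 / k) < 0.05

    def test_kinetic_temperature_near_target(self, mini_traj):
        v = mini_traj.final_state
        sim = Simulator(v, mb.ForceFieldParams(), mb.EngineParams(seed=9), phase=2)
        temps = []
        for _ in range(200):
            sim.run(10)
            temps.append(sim.kinetic_temperature())
        assert abs(np.mean(temps) - 1.0) < 0.05

    def test_unstable_dt_rejected(self):
        with pytest.raises(ConfigError):
            mb.langevin_step(
                _two_bead_state(), mb.EngineParams(dt=1.0), mb.ForceFieldParams()
            )


class TestSchedule:
    def test_snapshot_count_bookkeeping(self, mini_state):
        traj = mb.run_schedule(
            mini_state, mb.ForceFieldParams(), mb.EngineParams(seed=2),
            mb.Schedule(phase1_steps=500, phase2_steps=1500, snapshot_every=300),
        )
        assert traj.n_frames == (500 + 1500) // 300 + 1
        assert traj.phases[0] == 1 and traj.phases[-1] == 2

    def test_no_attraction_phase_leaves_bridges_unbound(self, mini_state):
        """With phase 2 absent, bridge-chromatin contacts stay at the random-
        placement level instead of accumulating."""
        from scipy.spatial import cKDTree

        traj = mb.run_schedule(
            mini_state, mb.ForceFieldParams(), mb.EngineParams(seed=5),
            mb.Schedule(phase1_steps=3_000, phase2_steps=0, snapshot_every=500),
        )

        def contacts(c, b):
            if len(b) == 0:
                return 0
            return len(cKDTree(c).query_ball_point(b, 1.3, return_length=True).nonzero()[0])

        initial = contacts(traj.chromatin[0], traj.bridges[0])
        finals = [contacts(traj.chromatin[i], traj.bridges[i]) for i in range(3, traj.n_frames)]
        m = mini_state.n_bridges
        assert np.mean(finals) <= max(initial, 1) + 0.35 * m

    def test_two_runs_same_seed_identical_trajectories(self, mini_state):
        sched = mb.Schedule(phase1_steps=200, phase2_steps=800, snapshot_every=200)
        a = mb.run_schedule(mini_state, mb.ForceFieldParams(), mb.EngineParams(seed=11), sched)
        b = mb.run_schedule(mini_state, mb.ForceFieldParams(), mb.EngineParams(seed=11), sched)
        np.testing.assert_array_equal(a.chromatin, b.chromatin)
        np.testing.assert_array_equal(a.bridges, b.bridges)


class TestPulling:
    def test_zero_force_matches_unforced_run(self, mini_traj):
        protocol = mb.PullingProtocol(force_magnitude=0.0, pull_steps=300, release_steps=300)
        pulled = mb.apply_pulling(mini_traj, protocol, engine=mb.EngineParams(seed=21))
        # same seed, no force: extension stays statistically flat
        ext = pulled.extension
        assert np.all(np.isfinite(ext))
        assert abs(ext[-1] - ext[0]) < 0.8 * ext[0]

    def test_large_force_straightens_plain_chain(self):
        """Small-chain oracle: a 20-bead linear chain under strong opposite
        end forces approaches its contour length."""
        from mitobrush.state import Trajectory

        n = 20
        ann = sample_loops(n, (2_000, 2_000 * n), seed=0)
        coords = np.zeros((n, 3))
        coords[:, 2] = np.arange(n) * 1.0
        coords += 0.05 * np.random.default_rng(0).standard_normal((n, 3))
        bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
        state = SimulationState(
            chromatin_coords=coords,
            bridge_coords=np.empty((0, 3)),
            chromatin_vel=np.zeros((n, 3)),
            bridge_vel=np.empty((0, 3)),
            bonds=bonds,
            bond_kinds=np.zeros(n - 1, dtype=np.int8),
            annotation=ann,
            box=np.full(3, 100.0),
        )
        traj = Trajectory(
            chromatin=coords[None], bridges=np.empty((1, 0, 3)),
            times=np.array([0]), phases=np.array([2], dtype=np.int8),
            annotation=ann, box=state.box,
            metadata={"params": mb.ForceFieldParams(), "seed": 0,
                      "schedule": mb.Schedule(snapshot_every=500)},
            final_state=state,
        )
        protocol = mb.PullingProtocol(
            force_magnitude=30.0, end_regions=((0,), (n - 1,)),
            pull_steps=5_000, release_steps=0,
        )
        pulled = mb.apply_pulling(traj, protocol, engine=mb.EngineParams(seed=2))
        contour = (n - 1) * 1.0
        tail = pulled.extension[-3:]
        assert np.mean(tail) > 0.85 * contour
        assert np.mean(tail) < 1.9 * contour  # finite extensibility holds

    def test_end_regions_default_are_first_and_last_loops(self, mini_state):
        a, b = default_end_regions(mini_state.annotation)
        assert a[0] == 0 and b[-1] == mini_state.n_chromatin - 1
        assert not set(a) & set(b)
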