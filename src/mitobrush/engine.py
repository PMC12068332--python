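"""Langevin dynamics and the two-phase compaction schedule.

Integration uses the underdamped BAOAB splitting (kick - drift - Ornstein-
Uhlenbeck - drift - kick) in reduced units: bead mass m = 1, k_B*T = 1,
bead diameter = 1.  The thermostat acts on every particle independently;
one seeded generator drives the whole run, drawing exactly one (N, 3)
standard-normal block per step, so trajectories are bit-reproducible for a
fixed seed.

The schedule mirrors the biological narrative: phase 1 runs with bridge
attractions off (diffusing steric bridges around the bottlebrush), phase 2
switches on the weak chromatin / strong anchor wells and lets the
self-assembled cylinder form.  Optional pulling phases (3: constant
opposite end forces, 4: release) emulate chromosome micromanipulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import bond_kernel, nonbonded_kernel
from .errors import ConfigError, IntegrationError
from .forcefield import ForceFieldParams, bond_table, class_table
from .state import SimulationState, Trajectory, TYPE_BRIDGE

logger = logging.getLogger(__name__)

# Verlet-list skin: generous because the k-d tree rebuild, not the pair
# kernel, dominates at typical system sizes (~10^3 particles)
_SKIN = 1.0


@dataclass(frozen=True)
class EngineParams:
    """Integrator housekeeping (reduced units)."""

    dt: float = 0.01
    friction: float = 1.0
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.friction < 0 or self.temperature < 0:
            raise ConfigError("dt must be > 0, friction and temperature >= 0")

    def with_(self, **kw) -> "EngineParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PullingProtocol:
    """Constant opposite forces at the two chromosome extremities."""

    force_magnitude: float = 20.0  # total force per end region, reduced units
    end_regions: Optional[tuple[tuple[int, ...], tuple[int, ...]]] = None  # None = auto
    pull_steps: int = 20_000
    # long enough for bridging-induced re-aggregation, not just elastic recoil
    release_steps: int = 60_000

    def __post_init__(self):
        if self.pull_steps < 0 or self.release_steps < 0:
            raise ConfigError("step counts must be >= 0")
        if self.end_regions is not None:
            a, b = map(set, self.end_regions)
            if a & b:
                raise ConfigError("pulling end regions must be disjoint")


@dataclass(frozen=True)
class Schedule:
    """Two-phase attraction schedule plus optional micromanipulation."""

    phase1_steps: int = 2_000
    phase2_steps: int = 60_000
    snapshot_every: int = 2_000
    pulling: Optional[PullingProtocol] = None

    def __post_init__(self):
        if min(self.phase1_steps, self.phase2_steps) < 0 or self.snapshot_every <= 0:
            raise ConfigError("step counts must be >= 0 and snapshot_every > 0")

    def with_(self, **kw) -> "Schedule":
        return replace(self, **kw)


def stability_limit(params: ForceFieldParams) -> float:
    """Rough dt bound from the stiffest configured potential (~1/5 of 2/omega)."""
    curv_bond = params.bond_k / (1.0 - 0.64)  # FENE curvature near 80% extension
    curv_lj = 57.15 * max(params.eps_strong, 1.0)
    curv_soft = params.A * math.pi ** 2 / params.cutoff_cc ** 2
    omega = math.sqrt(max(curv_bond, curv_lj, curv_soft))
    return 0.4 / omega


def validate_dt(engine: EngineParams, params: ForceFieldParams) -> None:
    limit = stability_limit(params)
    if engine.dt > limit:
        raise ConfigError(f"dt={engine.dt} exceeds stability bound {limit:.4g}")
    if engine.dt > 0.75 * limit:
        logger.warning("dt=%g is within 2x of the stability bound %.4g", engine.dt, limit)


class Simulator:
    """Stateful integrator bound to one system.

    Holds the combined (chromatin + bridge) coordinate block, the Verlet
    neighbour list, and the per-phase interaction tables.  Most users go
    through :func:`run_schedule`; the class is public for custom protocols.
    """

    def __init__(
        self,
        state: SimulationState,
        params: ForceFieldParams,
        engine: EngineParams = EngineParams(),
        phase: int = 2,
    ):
        validate_dt(engine, params)
        self.params = params
        self.engine = engine
        self.annotation = state.annotation
        self.box = state.box.copy()
        self.n_chromatin = state.n_chromatin
        self.n_bridges = state.n_bridges
        self.pos = np.concatenate([state.chromatin_coords, state.bridge_coords], axis=0)
        self.vel = np.concatenate([state.chromatin_vel, state.bridge_vel], axis=0)
        self.types = np.concatenate(
            [state.particle_types(), np.full(state.n_bridges, TYPE_BRIDGE, dtype=np.int8)]
        )
        self.bonds = state.bonds
        self.bond_kinds = state.bond_kinds
        self.btab = bond_table(params)
        self._tabs = {1: class_table(params, 1), 2: class_table(params, 2)}
        self.phase = phase
        self.step_index = state.time_step_index
        self.rng = np.random.default_rng(np.random.SeedSequence([engine.seed, 0x_D1CE]))
        n = self.pos.shape[0]
        sb = np.sort(self.bonds, axis=1)
        self._excl_keys = np.unique(sb[:, 0] * n + sb[:, 1]) if len(sb) else np.empty(0, np.int64)
        self._pairs = np.empty((0, 2), dtype=np.int64)
        self._ref_pos = None
        self._forces = np.zeros_like(self.pos)
        self._potential = 0.0
        self._external: Optional[np.ndarray] = None
        self._compute_forces(rebuild=True)

    # -- neighbour list ----------------------------------------------------

    def _build_pairs(self) -> None:
        n = self.pos.shape[0]
        wrapped = np.mod(self.pos, self.box)
        wrapped[wrapped >= self.box] = 0.0  # fp guard: x % L can round to L
        tree = cKDTree(wrapped, boxsize=self.box)
        pairs = tree.query_pairs(self.params.max_cutoff + _SKIN, output_type="ndarray")
        if pairs.size:
            keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
            pairs = pairs[~np.isin(keys, self._excl_keys)]
        self._pairs = np.ascontiguousarray(pairs, dtype=np.int64)
        self._ref_pos = self.pos.copy()

    def _needs_rebuild(self) -> bool:
        if self._ref_pos is None:
            return True
        disp = self.pos - self._ref_pos
        return float(np.max(np.sum(disp * disp, axis=1))) > (0.5 * _SKIN) ** 2

    def _compute_forces(self, rebuild: bool = False) -> None:
        if rebuild or self._needs_rebuild():
            self._build_pairs()
        self._forces[:] = 0.0
        e_nb = nonbonded_kernel(
            self.pos, self.types, self._pairs, self._tabs[self.phase], self.box, self._forces
        )
        e_b, worst = bond_kernel(
            self.pos, self.bonds, self.bond_kinds, self.btab, self.box, self._forces
        )
        if worst >= 0.999:
            raise IntegrationError(
                f"bond over-extension at step {self.step_index} "
                f"(|r - r0| reached {worst:.3f} of the divergence length)"
            )
        self._potential = e_nb + e_b
        if self._external is not None:
            self._forces += self._external

    # -- public surface ----------------------------------------------------

    def set_phase(self, phase: int) -> None:
        if phase not in (1, 2):
            raise ConfigError(f"phase must be 1 or 2, got {phase}")
        self.phase = phase
        self._compute_forces(rebuild=True)

    def set_external_forces(self, external: Optional[np.ndarray]) -> None:
        """Constant per-particle force field added to every evaluation."""
        self._external = None if external is None else np.asarray(external, dtype=np.float64)
        self._compute_forces()

    @property
    def potential_energy(self) -> float:
        return self._potential

    def kinetic_temperature(self) -> float:
        return float(np.mean(np.sum(self.vel * self.vel, axis=1))) / 3.0

    def run(self, n_steps: int) -> None:
        dt = self.engine.dt
        half = 0.5 * dt
        c1 = math.exp(-self.engine.friction * dt)
        c2 = math.sqrt(max(0.0, (1.0 - c1 * c1)) * self.engine.temperature)
        for _ in range(n_steps):
            self.vel += half * self._forces
            self.pos += half * self.vel
            noise = self.rng.standard_normal(self.pos.shape)
            self.vel *= c1
            self.vel += c2 * noise
            self.pos += half * self.vel
            self._compute_forces()
            self.vel += half * self._forces
            self.step_index += 1
        if not np.all(np.isfinite(self.pos)):
            raise IntegrationError(f"non-finite coordinates at step {self.step_index}")

    def to_state(self) -> SimulationState:
        nc = self.n_chromatin
        return SimulationState(
            chromatin_coords=self.pos[:nc].copy(),
            bridge_coords=self.pos[nc:].copy(),
            chromatin_vel=self.vel[:nc].copy(),
            bridge_vel=self.vel[nc:].copy(),
            bonds=self.bonds.copy(),
            bond_kinds=self.bond_kinds.copy(),
            annotation=self.annotation,
            box=self.box.copy(),
            time_step_index=self.step_index,
        )


# ---------------------------------------------------------------------------
# functional surface


def total_forces(
    state: SimulationState, params: ForceFieldParams, phase: int = 2
) -> np.ndarray:
    """Forces on every particle (chromatin first, then bridges), shape (n+m, 3)."""
    sim = Simulator(state, params, EngineParams(), phase=phase)
    return sim._forces.copy()


def total_energy(
    state: SimulationState, params: ForceFieldParams, phase: int = 2
) -> float:
    sim = Simulator(state, params, EngineParams(), phase=phase)
    return sim.potential_energy


def langevin_step(
    state: SimulationState,
    engine: EngineParams,
    params: ForceFieldParams,
    phase: int = 2,
    n_steps: int = 1,
) -> SimulationState:
    """Advance ``state`` by ``n_steps`` BAOAB steps and return the new state."""
    sim = Simulator(state, params, engine, phase=phase)
    sim.run(n_steps)
    return sim.to_state()


def _snapshot(traj_frames, sim, phase_label):
    nc = sim.n_chromatin
    traj_frames["chromatin"].append(sim.pos[:nc].copy())
    traj_frames["bridges"].append(sim.pos[nc:].copy())
    traj_frames["times"].append(sim.step_index)
    traj_frames["phases"].append(phase_label)


def _finalize(frames, sim, metadata, extension=None) -> Trajectory:
    return Trajectory(
        chromatin=np.array(frames["chromatin"]),
        bridges=np.array(frames["bridges"]),
        times=np.array(frames["times"], dtype=np.int64),
        phases=np.array(frames["phases"], dtype=np.int8),
        annotation=sim.annotation,
        box=sim.box.copy(),
        metadata=metadata,
        extension=None if extension is None else np.array(extension),
        final_state=sim.to_state(),
    )


def run_schedule(
    state: SimulationState,
    params: ForceFieldParams,
    engine: EngineParams,
    schedule: Schedule,
) -> Trajectory:
    """Run phase 1 (steric bridges) then phase 2 (attractions on).

    Snapshots are taken at step 0 and every ``snapshot_every`` steps, giving
    ``floor(total/stride) + 1`` frames.  On integration failure the partial
    trajectory is attached to the raised :class:`IntegrationError` as
    ``partial_trajectory``.
    """
    sim = Simulator(state, params, engine, phase=1)
    frames = {"chromatin": [], "bridges": [], "times": [], "phases": []}
    metadata = {
        "params": params,
        "engine": engine,
        "schedule": schedule,
        "seed": engine.seed,
        "phase1_end_step": state.time_step_index + schedule.phase1_steps,
    }
    _snapshot(frames, sim, 1)
    total = schedule.phase1_steps + schedule.phase2_steps
    stride = schedule.snapshot_every
    done = 0
    try:
        while done < total:
            chunk = min(stride - done % stride, total - done)
            boundary = schedule.phase1_steps - done
            if 0 < boundary < chunk:
                chunk = boundary  # stop exactly at the phase switch
            sim.run(chunk)
            done += chunk
            if done == schedule.phase1_steps and schedule.phase2_steps > 0:
                sim.set_phase(2)
            if done % stride == 0:
                _snapshot(frames, sim, 1 if done <= schedule.phase1_steps else 2)
                logger.debug(
                    "step %d/%d phase %d E_pot=%.1f T_kin=%.3f",
                    done, total, sim.phase, sim.potential_energy, sim.kinetic_temperature(),
                )
    except IntegrationError as err:
        err.partial_trajectory = _finalize(frames, sim, metadata)
        raise
    traj = _finalize(frames, sim, metadata)
    if schedule.pulling is not None:
        return apply_pulling(traj, schedule.pulling, engine=engine)
    return traj


def default_end_regions(
    annotation, n_end_loops: int = 1
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Bead sets of the first and last ``n_end_loops`` loops of the chain."""
    first = annotation.loops[:n_end_loops]
    last = annotation.loops[-n_end_loops:]
    a = tuple(range(first[0][0], first[-1][1]))
    b = tuple(range(last[0][0], last[-1][1]))
    return a, b


def _extension(pos, region_a, region_b) -> float:
    return float(
        np.linalg.norm(pos[list(region_b)].mean(axis=0) - pos[list(region_a)].mean(axis=0))
    )


def apply_pulling(
    traj: Trajectory,
    protocol: PullingProtocol,
    engine: Optional[EngineParams] = None,
    snapshot_every: Optional[int] = None,
) -> Trajectory:
    """Stretch-release micromanipulation, continuing from a trajectory's end.

    Equal and opposite constant forces (total ``force_magnitude`` per side,
    shared evenly over each end region) act along the line joining the two
    end-region centroids during ``pull_steps``, then are removed for
    ``release_steps``.  The centroid-to-centroid extension is recorded at
    every snapshot.  The box is enlarged to the full chain contour length so
    a stretched chromosome can never touch its periodic images.
    """
    state = traj.final_state
    if state is None:
        raise ConfigError("trajectory carries no final state to continue from")
    params: ForceFieldParams = traj.metadata["params"]
    engine = engine or traj.metadata.get("engine") or EngineParams()
    stride = snapshot_every or traj.metadata["schedule"].snapshot_every

    state = state.copy()
    contour = float(state.n_chromatin) * params.bond_r0
    state.box = np.maximum(state.box, 1.2 * contour + 20.0)

    regions = protocol.end_regions or default_end_regions(state.annotation)
    ra, rb = regions
    sim = Simulator(state, params, engine, phase=2)
    u = sim.pos[list(rb)].mean(axis=0) - sim.pos[list(ra)].mean(axis=0)
    u /= max(np.linalg.norm(u), 1e-12)
    external = np.zeros_like(sim.pos)
    external[list(ra)] = -protocol.force_magnitude / len(ra) * u
    external[list(rb)] = +protocol.force_magnitude / len(rb) * u

    frames = {"chromatin": [], "bridges": [], "times": [], "phases": []}
    extension = []
    metadata = dict(traj.metadata)
    metadata["pulling"] = protocol
    _snapshot(frames, sim, 3)
    extension.append(_extension(sim.pos, ra, rb))

    def _run_block(n_steps, phase_label):
        done = 0
        while done < n_steps:
            chunk = min(stride, n_steps - done)
            sim.run(chunk)
            done += chunk
            _snapshot(frames, sim, phase_label)
            extension.append(_extension(sim.pos, ra, rb))

    try:
        sim.set_external_forces(external)
        _run_block(protocol.pull_steps, 3)
        sim.set_external_forces(None)
        _run_block(protocol.release_steps, 4)
    except IntegrationError as err:
        err.partial_trajectory = _finalize(frames, sim, metadata, extension)
        raise
    return _finalize(frames, sim, metadata, extension)
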