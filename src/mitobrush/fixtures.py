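"""Deterministic toy systems for tests, demos and format checks.

Everything here is generated on demand from a seed; no fixture ever ships
as a data file.  In-memory generators (``toy_*``) feed the test suite;
:func:`make_fixture` writes the corresponding files for CLI users.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import trajio
from .analysis import ContactProfile
from .builder import annotation_to_bed, build_bottlebrush, place_bridges
from .errors import ConfigError
from .state import BottlebrushConfig, SimulationState, Trajectory

FIXTURE_NAMES = ("mini_bottlebrush", "linear_chain_20", "synthetic_cylinder", "powerlaw_profile")


def toy_mini_state(seed: int = 1, with_bridges: bool = True) -> SimulationState:
    """A 90-bead bottlebrush of exactly three 60 kbp loops."""
    cfg = BottlebrushConfig(n_beads=90, loop_len_range_bp=(60_000, 60_000), seed=seed)
    state = build_bottlebrush(cfg)
    if with_bridges:
        state = place_bridges(state, "auto", seed=seed)
    return state


def toy_linear_chain(n: int = 20, spacing: float = 1.0) -> np.ndarray:
    """A straight chain of ``n`` beads along the z axis."""
    coords = np.zeros((n, 3))
    coords[:, 2] = np.arange(n) * spacing
    return coords


def toy_cylinder_cloud(
    seed: int = 1,
    n_points: int = 2000,
    radius: float = 3.0,
    length: float = 30.0,
    void: tuple[float, float] | None = None,
) -> np.ndarray:
    """Uniform point cloud filling a cylinder along z, centred at the origin.

    ``void`` carves out an axial slab [lo, hi) (z units) to emulate a
    chromosome gap; points are ordered by z so that index ranges map onto
    axial windows.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x_C711]))
    pts = []
    while len(pts) < n_points:
        z = (rng.random() - 0.5) * length
        if void is not None and void[0] <= z < void[1]:
            continue
        r = radius * np.sqrt(rng.random())
        phi = 2.0 * np.pi * rng.random()
        pts.append((r * np.cos(phi), r * np.sin(phi), z))
    arr = np.array(pts)
    return arr[np.argsort(arr[:, 2])]


def toy_powerlaw_profile(
    exponent: float = 0.5,
    s_min_bp: float = 2_000,
    s_max_bp: float = 1_000_000,
    n_bins: int = 40,
    cutoff: float = 2.0,
) -> ContactProfile:
    """An exact P(s) = (s / s_min)^-exponent profile."""
    s = np.geomspace(s_min_bp, s_max_bp, n_bins)
    return ContactProfile(s_values=s, p_values=(s / s_min_bp) ** (-exponent), cutoff=cutoff)


def _single_frame_traj(state: SimulationState) -> Trajectory:
    return Trajectory(
        chromatin=state.chromatin_coords[None],
        bridges=state.bridge_coords[None],
        times=np.array([0]),
        phases=np.array([1], dtype=np.int8),
        annotation=state.annotation,
        box=state.box,
    )


def make_fixture(name: str, seed: int, out_dir) -> dict[str, Path]:
    """Write the named fixture's files under ``out_dir``; returns {label: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "mini_bottlebrush":
        state = toy_mini_state(seed)
        paths = {
            "xyz": out / f"mini_bottlebrush_s{seed}.xyz",
            "bed": out / f"mini_bottlebrush_s{seed}.loops.bed",
        }
        trajio.write_xyz(_single_frame_traj(state), paths["xyz"])
        annotation_to_bed(state.annotation, paths["bed"])
        return paths
    if name == "linear_chain_20":
        coords = toy_linear_chain(20)
        path = out / "linear_chain_20.xyz"
        with open(path, "w") as fh:
            fh.write("20\nframe=0 time=0 phase=1\n")
            for x, y, z in coords:
                fh.write(f"CHR {x:.6f} {y:.6f} {z:.6f}\n")
        return {"xyz": path}
    if name == "synthetic_cylinder":
        cloud = toy_cylinder_cloud(seed)
        path = out / f"synthetic_cylinder_s{seed}.xyz"
        with open(path, "w") as fh:
            fh.write(f"{len(cloud)}\nframe=0 time=0 phase=1\n")
            for x, y, z in cloud:
                fh.write(f"CHR {x:.6f} {y:.6f} {z:.6f}\n")
        return {"xyz": path}
    if name == "powerlaw_profile":
        from .analysis import export_contact_profile

        profile = toy_powerlaw_profile()
        path = out / "powerlaw_profile.tsv"
        export_contact_profile(profile, path)
        return {"tsv": path, "meta": Path(str(path) + ".json")}
    raise ConfigError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
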