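"""Core simulation containers: annotations, configurations, states, trajectories.

Units are reduced throughout: the chromatin bead diameter is the unit of
length, k_B*T the unit of energy, and the bead mass the unit of mass.  The
genomic scale enters only through :class:`CoarseGrainingMap` (base pairs per
bead, default 2 kbp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigError

# bond kinds (values stored in SimulationState.bond_kinds)
BOND_BACKBONE = 0
BOND_LOOP = 1
BOND_CENTROMERE = 2

# particle type codes used by the force kernels
TYPE_CHROMATIN = 0
TYPE_ANCHOR = 1  # attractive loop anchor (still chromatin for steric purposes)
TYPE_BRIDGE = 2


@dataclass(frozen=True)
class CoarseGrainingMap:
    """Genomic-to-bead resolution of the polymer model.

    Parameters
    ----------
    bp_per_bead:
        Base pairs represented by one bead.  Default 2000 (2 kbp), the
        resolution at which nucleosomal detail is averaged out.
    sigma_nm:
        Optional physical bead diameter in nanometres.  Metadata only; it
        never enters the dynamics, which run in reduced units.
    """

    bp_per_bead: int = 2000
    sigma_nm: Optional[float] = None

    def __post_init__(self):
        if self.bp_per_bead < 1:
            raise ConfigError(f"bp_per_bead must be >= 1, got {self.bp_per_bead}")

    def bp_to_beads(self, bp: float) -> int:
        return int(round(bp / self.bp_per_bead))

    def beads_to_bp(self, beads: int) -> int:
        return int(beads * self.bp_per_bead)


@dataclass(frozen=True)
class LoopAnnotation:
    """Partition of a chain into consecutive chromatin loops.

    ``loops`` are half-open bead-index intervals ``[start, end)`` that tile
    the chain contiguously.  Adjacent loops share a boundary anchor, so a
    chain of *n* loops carries *n + 1* anchors: the start bead of every loop
    plus the last bead of the chain.  Each loop is closed by one
    looping-condensin spring joining its two root beads.

    ``attractive_anchors`` is the subset of anchors that attract bridging
    particles strongly; lesions remove anchors from this set without
    touching chain connectivity.
    """

    loops: tuple[tuple[int, int], ...]
    anchor_beads: frozenset[int]
    looping_springs: tuple[tuple[int, int], ...]
    attractive_anchors: frozenset[int]
    cg: CoarseGrainingMap = field(default_factory=CoarseGrainingMap)
    truncated_last: bool = False
    lesioned_loops: tuple[int, ...] = ()
    # for multi-chain states: half-open bead ranges of each chromatid
    chain_ranges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.loops:
            raise ConfigError("annotation must contain at least one loop")
        if not self.attractive_anchors <= self.anchor_beads:
            raise ConfigError("attractive_anchors must be a subset of anchor_beads")
        ranges = self.chain_ranges or ((self.loops[0][0], self.loops[-1][1]),)
        pos = ranges[0][0]
        ri = 0
        for start, end in self.loops:
            if start != pos:
                # allow a jump exactly at a chain boundary
                if ri + 1 < len(ranges) and start == ranges[ri + 1][0] and pos == ranges[ri][1]:
                    ri += 1
                    pos = start
                else:
                    raise ConfigError(
                        f"loops do not tile the chain: gap/overlap at bead {pos} vs loop start {start}"
                    )
            if end <= start:
                raise ConfigError(f"empty or inverted loop ({start}, {end})")
            pos = end
        if pos != ranges[-1][1]:
            raise ConfigError("loops do not reach the end of the chain")
        if len(self.looping_springs) > len(self.loops):
            raise ConfigError("more looping springs than loops")
        object.__setattr__(self, "loops", tuple(map(tuple, self.loops)))

    @property
    def n_beads(self) -> int:
        ranges = self.chain_ranges or ((self.loops[0][0], self.loops[-1][1]),)
        return sum(e - s for s, e in ranges)

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    def loop_lengths_beads(self) -> np.ndarray:
        return np.array([e - s for s, e in self.loops], dtype=np.int64)

    def loop_lengths_bp(self) -> np.ndarray:
        return self.loop_lengths_beads() * self.cg.bp_per_bead

    def loop_roots(self, i: int) -> tuple[int, int]:
        """The two root (anchor) beads of loop ``i``."""
        start, end = self.loops[i]
        ranges = self.chain_ranges or ((self.loops[0][0], self.loops[-1][1]),)
        for s, e in ranges:
            if s <= start < e:
                return (start, end if end < e else e - 1)
        raise ConfigError(f"loop {i} outside all chain ranges")


@dataclass(frozen=True)
class BottlebrushConfig:
    """Build parameters for one bottlebrush chromatid.

    Defaults encode the wild-type conditions: loops drawn uniformly from
    60-120 kbp at 2 kbp/bead, one bridging particle per attractive anchor
    (``n_bridges="auto"``).
    """

    n_beads: int
    loop_len_range_bp: tuple[int, int] = (60_000, 120_000)
    n_bridges: int | str = "auto"
    box_size: Optional[float] = None  # cubic box edge, bead diameters; None = auto
    centromere_span: Optional[tuple[int, int]] = None
    seed: int = 0
    cg: CoarseGrainingMap = field(default_factory=CoarseGrainingMap)

    def __post_init__(self):
        if self.n_beads <= 0:
            raise ConfigError(f"n_beads must be positive, got {self.n_beads}")
        lo, hi = self.loop_len_range_bp
        if lo > hi:
            raise ConfigError(f"loop length range inverted: {self.loop_len_range_bp}")
        if lo < self.cg.bp_per_bead:
            raise ConfigError(
                f"minimum loop length {lo} bp is below one bead ({self.cg.bp_per_bead} bp)"
            )
        if self.n_beads < self.cg.bp_to_beads(lo):
            raise ConfigError(
                f"chain of {self.n_beads} beads cannot hold one loop of >= {lo} bp"
            )
        if isinstance(self.n_bridges, str) and self.n_bridges != "auto":
            raise ConfigError(f"n_bridges must be an integer or 'auto', got {self.n_bridges!r}")
        if isinstance(self.n_bridges, int) and self.n_bridges < 0:
            raise ConfigError("n_bridges must be >= 0")

    def with_(self, **kw) -> "BottlebrushConfig":
        return replace(self, **kw)


@dataclass
class SimulationState:
    """Full mechanical state of one system at one instant.

    Coordinates are stored unwrapped (continuous in space); the periodic
    ``box`` enters only through minimum-image convention in the non-bonded
    force evaluation, and is chosen large enough at build time that the
    chromosome never interacts with its own images.
    """

    chromatin_coords: np.ndarray  # (n, 3) float64
    bridge_coords: np.ndarray  # (m, 3) float64
    chromatin_vel: np.ndarray
    bridge_vel: np.ndarray
    bonds: np.ndarray  # (nb, 2) int64, bead indices into chromatin
    bond_kinds: np.ndarray  # (nb,) int8, BOND_* codes
    annotation: LoopAnnotation
    box: np.ndarray  # (3,) float64 edge lengths
    time_step_index: int = 0

    def __post_init__(self):
        self.chromatin_coords = np.ascontiguousarray(self.chromatin_coords, dtype=np.float64)
        self.bridge_coords = np.ascontiguousarray(
            self.bridge_coords.reshape(-1, 3), dtype=np.float64
        )
        self.chromatin_vel = np.ascontiguousarray(self.chromatin_vel, dtype=np.float64)
        self.bridge_vel = np.ascontiguousarray(self.bridge_vel.reshape(-1, 3), dtype=np.float64)
        self.bonds = np.ascontiguousarray(self.bonds.reshape(-1, 2), dtype=np.int64)
        self.bond_kinds = np.ascontiguousarray(self.bond_kinds, dtype=np.int8)
        self.box = np.asarray(self.box, dtype=np.float64)
        if not np.all(np.isfinite(self.chromatin_coords)) or not np.all(
            np.isfinite(self.bridge_coords)
        ):
            raise ConfigError("non-finite coordinates in state")

    @property
    def n_chromatin(self) -> int:
        return self.chromatin_coords.shape[0]

    @property
    def n_bridges(self) -> int:
        return self.bridge_coords.shape[0]

    def particle_types(self) -> np.ndarray:
        """Per-chromatin-bead type codes (TYPE_CHROMATIN / TYPE_ANCHOR)."""
        t = np.full(self.n_chromatin, TYPE_CHROMATIN, dtype=np.int8)
        if self.annotation.attractive_anchors:
            t[sorted(self.annotation.attractive_anchors)] = TYPE_ANCHOR
        return t

    def copy(self) -> "SimulationState":
        return SimulationState(
            chromatin_coords=self.chromatin_coords.copy(),
            bridge_coords=self.bridge_coords.copy(),
            chromatin_vel=self.chromatin_vel.copy(),
            bridge_vel=self.bridge_vel.copy(),
            bonds=self.bonds.copy(),
            bond_kinds=self.bond_kinds.copy(),
            annotation=self.annotation,
            box=self.box.copy(),
            time_step_index=self.time_step_index,
        )


@dataclass
class Trajectory:
    """Time-ordered snapshots of one run plus the metadata to reproduce it.

    ``chromatin``/``bridges`` are stacked per-frame coordinate arrays with
    shapes (F, n, 3) and (F, m, 3); ``phases`` records which schedule phase
    (1 = steric only, 2 = attractions on, 3 = pulling, 4 = release) each
    frame belongs to.  ``extension`` is populated by pulling runs.
    """

    chromatin: np.ndarray
    bridges: np.ndarray
    times: np.ndarray  # step index of each frame
    phases: np.ndarray
    annotation: LoopAnnotation
    box: np.ndarray
    metadata: dict = field(default_factory=dict)
    extension: Optional[np.ndarray] = None
    final_state: Optional[SimulationState] = None

    @property
    def n_frames(self) -> int:
        return self.chromatin.shape[0]

    def frame_state(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.chromatin[i], self.bridges[i]

    def select_frames(self, frames) -> np.ndarray:
        """Resolve a frame selection into an index array.

        ``frames`` may be None (all), an int (single frame, negatives ok), a
        slice, a sequence of indices, or the strings ``"last"`` /
        ``"final_quarter"`` / ``"final_half"``.
        """
        F = self.n_frames
        if frames is None:
            return np.arange(F)
        if isinstance(frames, str):
            if frames == "last":
                return np.array([F - 1])
            if frames == "final_quarter":
                return np.arange(max(0, F - max(1, F // 4)), F)
            if frames == "final_half":
                return np.arange(max(0, F - max(1, F // 2)), F)
            raise ConfigError(f"unknown frame selection {frames!r}")
        if isinstance(frames, (int, np.integer)):
            return np.array([int(frames) % F])
        if isinstance(frames, slice):
            return np.arange(F)[frames]
        return np.asarray(list(frames), dtype=np.int64)


def chain_ranges_of(annotation: LoopAnnotation) -> tuple[tuple[int, int], ...]:
    if annotation.chain_ranges:
        return annotation.chain_ranges
    return ((annotation.loops[0][0], annotation.loops[-1][1]),)


def backbone_bond_pairs(annotation: LoopAnnotation) -> np.ndarray:
    """Consecutive-bead bonds within each chain (none across chain joins)."""
    pairs = []
    for s, e in chain_ranges_of(annotation):
        idx = np.arange(s, e - 1)
        pairs.append(np.stack([idx, idx + 1], axis=1))
    return np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=np.int64)
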