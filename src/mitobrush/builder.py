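"""Construction of initial configurations.

The prophase chromatid is modelled as a bottlebrush polymer: a linear chain
of beads (2 kbp each by default) tiled by consecutive chromatin loops whose
two root beads ("condensin loop anchors") are joined by a looping spring.
Adjacent loops share their boundary anchor, so *n* loops carry *n + 1*
anchors.  Bridging condensins are separate spheres placed in the free
volume around the chain.

Build geometry: anchors are laid along a weakly helical axis and each
loop's interior beads are placed on a near-circular arc in a plane rotated
around that axis (successive loops rotated by the golden angle so that they
spread azimuthally, mimicking the steric splay of a bottlebrush).  A short
zero-temperature steric relaxation with capped displacements then removes
the worst overlaps without endangering any bond.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, PackingError
from .state import (
    BOND_BACKBONE,
    BOND_CENTROMERE,
    BOND_LOOP,
    BottlebrushConfig,
    CoarseGrainingMap,
    LoopAnnotation,
    SimulationState,
    backbone_bond_pairs,
)

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))
_ANCHOR_SPACING = 1.0  # arclength between consecutive anchors, bead diameters
_ARC_BOND = 0.90  # target spacing of loop beads along their build arc
_BACKBONE_PERSISTENCE = 8.0  # wormlike anchor path, in anchor spacings
_HELIX_RADIUS = 0.8
_HELIX_PITCH = 15.0
_BOX_MARGIN = 10.0


# ---------------------------------------------------------------------------
# loop sampling


def sample_loops(
    n_beads: int,
    loop_len_range_bp: tuple[int, int],
    cg: CoarseGrainingMap = CoarseGrainingMap(),
    seed: int = 0,
    offset: int = 0,
) -> LoopAnnotation:
    """Tile a chain of ``n_beads`` with consecutive loops.

    Loop lengths are drawn independently and uniformly (in beads) from the
    configured genomic range; the final loop is truncated to fit the chain
    exactly and flagged via ``truncated_last``.  ``offset`` shifts all bead
    indices (used when assembling multi-chain systems).
    """
    lo_bp, hi_bp = loop_len_range_bp
    lo = cg.bp_to_beads(lo_bp)
    hi = cg.bp_to_beads(hi_bp)
    if lo < 1:
        raise ConfigError(f"loop length range {loop_len_range_bp} bp is below one bead")
    if lo > hi:
        raise ConfigError(f"loop length range inverted: {loop_len_range_bp}")
    if n_beads < lo:
        raise ConfigError(f"chain of {n_beads} beads shorter than minimum loop ({lo} beads)")

    rng = np.random.default_rng(seed)
    loops: list[tuple[int, int]] = []
    pos = 0
    truncated = False
    while pos < n_beads:
        L = int(rng.integers(lo, hi + 1))
        if pos + L > n_beads:
            L = n_beads - pos
            truncated = True
        loops.append((offset + pos, offset + pos + L))
        pos += L

    anchors = {s for s, _ in loops}
    anchors.add(offset + n_beads - 1)
    springs = []
    for i, (s, e) in enumerate(loops):
        root2 = e if i < len(loops) - 1 else e - 1
        if root2 > s:
            springs.append((s, root2))
    return LoopAnnotation(
        loops=tuple(loops),
        anchor_beads=frozenset(anchors),
        looping_springs=tuple(springs),
        attractive_anchors=frozenset(anchors),
        cg=cg,
        truncated_last=truncated,
        chain_ranges=((offset, offset + n_beads),),
    )


# ---------------------------------------------------------------------------
# geometry


def _worm_path(n_points: int, rng: np.random.Generator) -> np.ndarray:
    """Wormlike anchor path: persistent random walk with a weak helical twist.

    A prophase chromatid is a long *flexible* brush, so the backbone is laid
    along a smoothly contorted curve (persistence ~ 8 anchor spacings)
    rather than a straight axis; a small helical modulation mimics the weak
    helicity of the initial brush.
    """
    eta = 1.0 / math.sqrt(_BACKBONE_PERSISTENCE)
    d = np.array([0.0, 0.0, 1.0])
    pts = np.zeros((n_points, 3))
    dirs = np.zeros((n_points, 3))
    for k in range(1, n_points):
        d = d + eta * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        dirs[k] = d
        pts[k] = pts[k - 1] + _ANCHOR_SPACING * d
    # weak helix in the local normal plane
    ref = np.array([1.0, 0.0, 0.0])
    for k in range(n_points):
        t = dirs[k] if k else np.array([0.0, 0.0, 1.0])
        u1 = ref - np.dot(ref, t) * t
        nu = np.linalg.norm(u1)
        u1 = u1 / nu if nu > 1e-9 else np.array([0.0, 1.0, 0.0])
        u2 = np.cross(t, u1)
        theta = 2.0 * math.pi * k * _ANCHOR_SPACING / _HELIX_PITCH
        pts[k] = pts[k] + _HELIX_RADIUS * (math.cos(theta) * u1 + math.sin(theta) * u2)
    return pts


def _bottlebrush_coords(annotation: LoopAnnotation, rng: np.random.Generator) -> np.ndarray:
    """Place one chain's beads: anchors on a wormlike path, loops as arcs."""
    (c0, c1), = annotation.chain_ranges or ((annotation.loops[0][0], annotation.loops[-1][1]),)
    n = c1 - c0
    coords = np.zeros((n, 3))

    # anchor beads in order along the chain
    roots = [annotation.loop_roots(i) for i in range(annotation.n_loops)]
    anchor_order = [roots[0][0]] + [r2 for _, r2 in roots]
    path = _worm_path(len(anchor_order), rng)
    for k, a in enumerate(anchor_order):
        coords[a - c0] = path[k]

    for i, (r1, r2) in enumerate(roots):
        n_int = r2 - r1 - 1
        if n_int <= 0:
            continue
        A = coords[r1 - c0]
        B = coords[r2 - c0]
        chord = np.linalg.norm(B - A)
        target_arc = (n_int + 1) * _ARC_BOND
        R = max((target_arc + chord) / (2.0 * math.pi), chord / 2.0 + 0.3)
        phi = _GOLDEN_ANGLE * i
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        # make u orthogonal to the chord so the circle plane contains A and B
        ab = (B - A) / max(chord, 1e-12)
        u = u - np.dot(u, ab) * ab
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            u = np.array([1.0, 0.0, 0.0]) - ab[0] * ab
            nu = np.linalg.norm(u)
        u /= nu
        M = 0.5 * (A + B)
        h = math.sqrt(max(R * R - 0.25 * chord * chord, 0.0))
        O = M + h * u
        ex = A - O
        ex /= np.linalg.norm(ex)
        ob = B - O
        ey = ob - np.dot(ob, ex) * ex
        ney = np.linalg.norm(ey)
        ey = ey / ney if ney > 1e-9 else np.cross(ab, ex)
        theta_ab = 2.0 * math.asin(min(1.0, chord / (2.0 * R)))
        major = 2.0 * math.pi - theta_ab
        for j in range(1, n_int + 1):
            alpha = -major * j / (n_int + 1)
            coords[r1 + j - c0] = O + R * (math.cos(alpha) * ex + math.sin(alpha) * ey)

    coords += 0.05 * rng.standard_normal(coords.shape)
    return coords


def _steric_relax(
    coords: np.ndarray,
    bonds: np.ndarray,
    n_iter: int = 150,
    max_disp: float = 0.05,
    cutoff: float = 1.0,
) -> np.ndarray:
    """Zero-temperature push-apart with capped displacements.

    Uses a linear-core repulsion between all non-bonded pairs within
    ``cutoff`` plus a harmonic pull of every bond toward unit rest length;
    displacement capping guarantees no bond can blow up.
    """
    x = coords.copy()
    n = x.shape[0]
    bonded = set(map(tuple, np.sort(bonds, axis=1).tolist()))
    for _ in range(n_iter):
        f = np.zeros_like(x)
        tree = cKDTree(x)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size:
            keep = np.fromiter(
                ((int(i), int(j)) not in bonded for i, j in pairs), bool, count=len(pairs)
            )
            pairs = pairs[keep]
        if pairs.size:
            d = x[pairs[:, 0]] - x[pairs[:, 1]]
            r = np.linalg.norm(d, axis=1)
            r = np.maximum(r, 1e-9)
            mag = 5.0 * (cutoff - r) / cutoff
            fv = (mag / r)[:, None] * d
            np.add.at(f, pairs[:, 0], fv)
            np.add.at(f, pairs[:, 1], -fv)
        d = x[bonds[:, 0]] - x[bonds[:, 1]]
        r = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
        fb = (-10.0 * (r - 1.0) / r)[:, None] * d
        np.add.at(f, bonds[:, 0], fb)
        np.add.at(f, bonds[:, 1], -fb)
        step = 0.02 * f
        norm = np.linalg.norm(step, axis=1)
        big = norm > max_disp
        if np.any(big):
            step[big] *= (max_disp / norm[big])[:, None]
        x += step
    return x


def _auto_box(coords: np.ndarray, margin: float = _BOX_MARGIN) -> np.ndarray:
    extent = coords.max(axis=0) - coords.min(axis=0)
    edge = float(np.max(extent)) + 2.0 * margin
    return np.array([edge, edge, edge])


def _assemble_state(
    coords: np.ndarray,
    annotation: LoopAnnotation,
    extra_bonds: Optional[np.ndarray] = None,
    extra_kinds: Optional[np.ndarray] = None,
    box_size: Optional[float] = None,
) -> SimulationState:
    bb = backbone_bond_pairs(annotation)
    lp = np.array(annotation.looping_springs, dtype=np.int64).reshape(-1, 2)
    bonds = [bb, lp]
    kinds = [
        np.full(len(bb), BOND_BACKBONE, dtype=np.int8),
        np.full(len(lp), BOND_LOOP, dtype=np.int8),
    ]
    if extra_bonds is not None and len(extra_bonds):
        bonds.append(np.asarray(extra_bonds, dtype=np.int64).reshape(-1, 2))
        kinds.append(np.asarray(extra_kinds, dtype=np.int8))
    bonds_arr = np.concatenate(bonds, axis=0)
    kinds_arr = np.concatenate(kinds)
    relaxed = _steric_relax(coords, bonds_arr)
    if box_size is not None:
        box = np.array([float(box_size)] * 3)
        extent = relaxed.max(axis=0) - relaxed.min(axis=0)
        if np.any(extent > box - 2.0):
            raise PackingError(
                f"box edge {box_size} too small for built chain (extent {extent.max():.1f})"
            )
    else:
        box = _auto_box(relaxed)
    return SimulationState(
        chromatin_coords=relaxed,
        bridge_coords=np.empty((0, 3)),
        chromatin_vel=np.zeros_like(relaxed),
        bridge_vel=np.empty((0, 3)),
        bonds=bonds_arr,
        bond_kinds=kinds_arr,
        annotation=annotation,
        box=box,
    )


def build_bottlebrush(cfg: BottlebrushConfig) -> SimulationState:
    """Build a single pre-relaxed bottlebrush chromatid (no bridges yet)."""
    annotation = sample_loops(cfg.n_beads, cfg.loop_len_range_bp, cfg.cg, seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x_B0B]))
    coords = _bottlebrush_coords(annotation, rng)
    return _assemble_state(coords, annotation, box_size=cfg.box_size)


def build_sisters(
    cfg_a: BottlebrushConfig,
    cfg_b: BottlebrushConfig,
    centromere_span: tuple[int, int],
) -> SimulationState:
    """Two bottlebrush chromatids cross-linked pairwise at the centromere.

    ``centromere_span`` is a half-open bead interval interpreted within each
    chain; bead ``span[0] + i`` of chromatid A is linked to the homologous
    bead of chromatid B by a harmonic spring, one spring per bead pair.
    """
    lo, hi = centromere_span
    if lo < 0 or hi < lo or hi > min(cfg_a.n_beads, cfg_b.n_beads):
        raise ConfigError(f"centromere span {centromere_span} invalid for both chains")

    ann_a = sample_loops(cfg_a.n_beads, cfg_a.loop_len_range_bp, cfg_a.cg, seed=cfg_a.seed)
    ann_b = sample_loops(
        cfg_b.n_beads, cfg_b.loop_len_range_bp, cfg_b.cg, seed=cfg_b.seed,
        offset=cfg_a.n_beads,
    )
    merged = LoopAnnotation(
        loops=ann_a.loops + ann_b.loops,
        anchor_beads=ann_a.anchor_beads | ann_b.anchor_beads,
        looping_springs=ann_a.looping_springs + ann_b.looping_springs,
        attractive_anchors=ann_a.attractive_anchors | ann_b.attractive_anchors,
        cg=cfg_a.cg,
        truncated_last=ann_a.truncated_last or ann_b.truncated_last,
        chain_ranges=((0, cfg_a.n_beads), (cfg_a.n_beads, cfg_a.n_beads + cfg_b.n_beads)),
    )
    rng_a = np.random.default_rng(np.random.SeedSequence([cfg_a.seed, 0x_B0B]))
    rng_b = np.random.default_rng(np.random.SeedSequence([cfg_b.seed, 0x_B0B, 1]))
    coords_a = _bottlebrush_coords(ann_a, rng_a)
    coords_b = _bottlebrush_coords(ann_b, rng_b)
    # side-by-side, offset far enough that the brushes barely interpenetrate
    mean_loop = float(np.mean(merged.loop_lengths_beads()))
    offset = mean_loop * _ARC_BOND / math.pi + 3.0
    coords_b = coords_b + np.array([offset, 0.0, 0.0])
    coords = np.concatenate([coords_a, coords_b], axis=0)

    n_links = hi - lo
    if n_links:
        ia = np.arange(lo, hi)
        ib = ia + cfg_a.n_beads
        cen_bonds = np.stack([ia, ib], axis=1)
        cen_kinds = np.full(n_links, BOND_CENTROMERE, dtype=np.int8)
    else:
        cen_bonds = cen_kinds = None
    return _assemble_state(
        coords, merged, extra_bonds=cen_bonds, extra_kinds=cen_kinds,
        box_size=cfg_a.box_size,
    )


# ---------------------------------------------------------------------------
# bridges


def place_bridges(
    state: SimulationState,
    n_bridges: int | str = "auto",
    seed: int = 0,
    min_dist: float = 1.0,
    margin: float = 3.0,
    max_attempts_per_bridge: int = 500,
) -> SimulationState:
    """Scatter bridging particles uniformly in the free volume around the chain.

    Placement is uniform over the chromatin bounding box inflated by
    ``margin`` (clipped to the periodic box); candidates within ``min_dist``
    of any chromatin bead or already-placed bridge are rejected.
    ``"auto"`` places one bridge per attractive anchor, the wild-type
    stoichiometry of the model (bridges comparable in number to anchors).
    """
    if n_bridges == "auto":
        n = len(state.annotation.attractive_anchors)
    else:
        n = int(n_bridges)
    out = state.copy()
    if n == 0:
        out.bridge_coords = np.empty((0, 3))
        out.bridge_vel = np.empty((0, 3))
        return out

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x_B21D]))
    lo = state.chromatin_coords.min(axis=0) - margin
    hi = state.chromatin_coords.max(axis=0) + margin
    span = np.minimum(hi - lo, state.box)
    tree = cKDTree(state.chromatin_coords)
    placed: list[np.ndarray] = []
    attempts = 0
    cap = max_attempts_per_bridge * n
    while len(placed) < n:
        if attempts >= cap:
            raise PackingError(
                f"could not place {n} bridges after {cap} attempts; free volume too small"
            )
        attempts += 1
        cand = lo + rng.random(3) * span
        if tree.query(cand, k=1)[0] < min_dist:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - cand, axis=1)) < min_dist:
            continue
        placed.append(cand)
    out.bridge_coords = np.array(placed)
    out.bridge_vel = np.zeros((n, 3))
    return out


def build_system(cfg: BottlebrushConfig, bridge_seed: Optional[int] = None) -> SimulationState:
    """Convenience: bottlebrush (or sisters if a centromere span is set) + bridges."""
    if cfg.centromere_span is not None:
        state = build_sisters(cfg, cfg.with_(seed=cfg.seed + 1), cfg.centromere_span)
    else:
        state = build_bottlebrush(cfg)
    return place_bridges(
        state, cfg.n_bridges, seed=cfg.seed if bridge_seed is None else bridge_seed
    )


# ---------------------------------------------------------------------------
# perturbations


_KO_DEFAULT_FACTORS = {
    "condensin_I": (2.0, 0.5),  # more looping activity, less bridging
    "condensin_II": (0.5, 2.0),  # shorter loops, more bridges
}


def expected_auto_bridges(cfg: BottlebrushConfig) -> int:
    """Expected ``auto`` bridge count: mean loop count + 1 shared anchors."""
    lo = cfg.cg.bp_to_beads(cfg.loop_len_range_bp[0])
    hi = cfg.cg.bp_to_beads(cfg.loop_len_range_bp[1])
    mean_loop = 0.5 * (lo + hi)
    return int(round(cfg.n_beads / mean_loop)) + 1


def knockout_transform(
    cfg: BottlebrushConfig,
    which: str,
    factors: Optional[tuple[float, float]] = None,
) -> BottlebrushConfig:
    """Re-balance looping vs bridging activity to emulate a condensin knockout.

    ``loop_factor`` scales the loop-length range (condensin I knockout
    raises it: the surviving complexes loop more); ``bridge_factor`` scales
    the bridge count (condensin I knockout lowers it).  Condensin II
    knockout is the mirror image: shorter loops, more bridges.  A numeric
    ``n_bridges`` is scaled directly; ``"auto"`` is first resolved against
    the untransformed loop range so that the factor acts on the wild-type
    stoichiometry.
    """
    if which not in _KO_DEFAULT_FACTORS:
        raise ConfigError(f"unknown knockout {which!r}; expected one of {sorted(_KO_DEFAULT_FACTORS)}")
    loop_factor, bridge_factor = factors if factors is not None else _KO_DEFAULT_FACTORS[which]
    if loop_factor <= 0 or bridge_factor <= 0:
        raise ConfigError("knockout factors must be positive")
    lo, hi = cfg.loop_len_range_bp
    new_range = (int(round(lo * loop_factor)), int(round(hi * loop_factor)))
    if new_range[0] < cfg.cg.bp_per_bead:
        raise ConfigError(
            f"loop_factor {loop_factor} yields sub-bead loops ({new_range[0]} bp)"
        )
    if cfg.n_bridges == "auto":
        base = expected_auto_bridges(cfg)
    else:
        base = int(cfg.n_bridges)
    new_bridges = int(round(base * bridge_factor))
    return cfg.with_(loop_len_range_bp=new_range, n_bridges=new_bridges)


def apply_lesion(annotation: LoopAnnotation, first_loop: int, k: int) -> LoopAnnotation:
    """Remove the condensin machinery of ``k`` consecutive loops.

    Models faulty condensin loading at a common fragile site: the looping
    springs of loops ``first_loop .. first_loop+k-1`` are deleted and every
    anchor belonging exclusively to those loops loses its strong bridge
    attraction.  Chain connectivity and the loop tiling are untouched.
    """
    if k < 0 or first_loop < 0 or first_loop + k > annotation.n_loops:
        raise ConfigError(
            f"lesion [{first_loop}, {first_loop + k}) outside 0..{annotation.n_loops}"
        )
    if k == 0:
        return annotation
    lesioned = set(range(first_loop, first_loop + k))
    removed_springs = set()
    lesion_roots: set[int] = set()
    surviving_roots: set[int] = set()
    for i in range(annotation.n_loops):
        r = annotation.loop_roots(i)
        if i in lesioned:
            removed_springs.add(tuple(sorted(r)))
            lesion_roots.update(r)
        elif i not in annotation.lesioned_loops:
            surviving_roots.update(r)
    springs = tuple(
        s for s in annotation.looping_springs if tuple(sorted(s)) not in removed_springs
    )
    exclusive = lesion_roots - surviving_roots
    return LoopAnnotation(
        loops=annotation.loops,
        anchor_beads=annotation.anchor_beads,
        looping_springs=springs,
        attractive_anchors=annotation.attractive_anchors - exclusive,
        cg=annotation.cg,
        truncated_last=annotation.truncated_last,
        lesioned_loops=tuple(sorted(set(annotation.lesioned_loops) | lesioned)),
        chain_ranges=annotation.chain_ranges,
    )


def lesion_bead_span(annotation: LoopAnnotation) -> Optional[tuple[int, int]]:
    """Half-open bead interval covered by the (contiguous) lesioned loops."""
    if not annotation.lesioned_loops:
        return None
    first = annotation.loops[annotation.lesioned_loops[0]]
    last = annotation.loops[annotation.lesioned_loops[-1]]
    return (first[0], last[1])


def apply_lesion_to_state(state: SimulationState, first_loop: int, k: int) -> SimulationState:
    """Lesion a built state: drop the excised looping springs and re-annotate."""
    ann = apply_lesion(state.annotation, first_loop, k)
    keep_springs = set(map(tuple, np.sort(np.array(ann.looping_springs).reshape(-1, 2), axis=1).tolist()))
    mask = np.ones(len(state.bonds), dtype=bool)
    for b in range(len(state.bonds)):
        if state.bond_kinds[b] == BOND_LOOP:
            pair = tuple(sorted(state.bonds[b].tolist()))
            if pair not in keep_springs:
                mask[b] = False
    out = state.copy()
    out.bonds = state.bonds[mask]
    out.bond_kinds = state.bond_kinds[mask]
    out.annotation = ann
    return out


# ---------------------------------------------------------------------------
# BED-like annotation I/O (0-based, half-open genomic coordinates)

_BED_COLUMNS = ["chrom", "start", "end", "loop_id", "anchor_start", "anchor_end", "attractive"]


def annotation_to_bed(annotation: LoopAnnotation, path, chrom: str = "chr_sim") -> None:
    """Write loops as a BED-like table (one row per loop, genomic bp units)."""
    bp = annotation.cg.bp_per_bead
    rows = []
    for i, (s, e) in enumerate(annotation.loops):
        r1, r2 = annotation.loop_roots(i)
        rows.append(
            {
                "chrom": chrom,
                "start": s * bp,
                "end": e * bp,
                "loop_id": f"loop_{i}",
                "anchor_start": r1,
                "anchor_end": r2,
                "attractive": int(
                    r1 in annotation.attractive_anchors and r2 in annotation.attractive_anchors
                ),
            }
        )
    pd.DataFrame(rows, columns=_BED_COLUMNS).to_csv(path, sep="\t", index=False, header=True)


def annotation_from_bed(path, cg: CoarseGrainingMap = CoarseGrainingMap()) -> LoopAnnotation:
    """Reconstruct a :class:`LoopAnnotation` from the BED-like table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"annotation table missing columns {missing}")
    loops = []
    springs = []
    anchors: set[int] = set()
    attractive: set[int] = set()
    for _, row in df.iterrows():
        s = int(row["start"]) // cg.bp_per_bead
        e = int(row["end"]) // cg.bp_per_bead
        loops.append((s, e))
        r1, r2 = int(row["anchor_start"]), int(row["anchor_end"])
        anchors.update((r1, r2))
        springs.append((r1, r2))
        if int(row["attractive"]):
            attractive.update((r1, r2))
    return LoopAnnotation(
        loops=tuple(loops),
        anchor_beads=frozenset(anchors),
        looping_springs=tuple(springs),
        attractive_anchors=frozenset(attractive),
        cg=cg,
    )
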