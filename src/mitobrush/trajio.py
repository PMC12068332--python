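"""Trajectory readers and writers.

Two formats:

* plain-text XYZ, one frame per block, with element tags distinguishing
  particle roles (``CHR`` chromatin, ``ANC`` attractive anchor, ``BRD``
  bridge); lossless to the printed precision and loadable in standard
  molecular viewers;
* an HDF5 container holding float64 coordinates, schedule phases, box,
  annotation and run metadata — bit-lossless round trip, the format of
  record for analysis-only workflows.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import h5py
import numpy as np

from .engine import EngineParams, PullingProtocol, Schedule
from .errors import TrajectoryFormatError
from .forcefield import ForceFieldParams
from .state import CoarseGrainingMap, LoopAnnotation, SimulationState, Trajectory

TAG_CHROMATIN = "CHR"
TAG_ANCHOR = "ANC"
TAG_BRIDGE = "BRD"


def _tags(traj: Trajectory) -> list[str]:
    n = traj.chromatin.shape[1]
    tags = [TAG_CHROMATIN] * n
    for a in traj.annotation.attractive_anchors:
        tags[a] = TAG_ANCHOR
    tags += [TAG_BRIDGE] * traj.bridges.shape[1]
    return tags


def write_xyz(traj: Trajectory, path) -> None:
    tags = _tags(traj)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            coords = np.concatenate([traj.chromatin[f], traj.bridges[f]], axis=0)
            fh.write(f"{len(coords)}\n")
            fh.write(
                f"frame={f} time={int(traj.times[f])} phase={int(traj.phases[f])} "
                f"box={traj.box[0]:.6f},{traj.box[1]:.6f},{traj.box[2]:.6f}\n"
            )
            for tag, (x, y, z) in zip(tags, coords):
                fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path, annotation: Optional[LoopAnnotation] = None) -> Trajectory:
    """Parse an XYZ trajectory written by :func:`write_xyz`.

    If no annotation is supplied, a minimal one-loop annotation is
    reconstructed with the attractive anchors recovered from ``ANC`` tags.
    """
    frames_c, frames_b, times, phases = [], [], [], []
    box = None
    anchor_idx: set[int] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise TrajectoryFormatError(f"frame {frame}: bad atom count line {i + 1}") from err
        if i + 2 + n > len(lines):
            raise TrajectoryFormatError(f"frame {frame}: truncated (expected {n} atoms)")
        comment = lines[i + 1]
        meta = dict(kv.split("=", 1) for kv in comment.split() if "=" in kv)
        times.append(int(meta.get("time", frame)))
        phases.append(int(meta.get("phase", 2)))
        if "box" in meta:
            box = np.array([float(v) for v in meta["box"].split(",")])
        chrom, bridges = [], []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) != 4:
                raise TrajectoryFormatError(f"frame {frame}: malformed atom line {i + 3 + k}")
            tag = parts[0]
            xyz = [float(v) for v in parts[1:]]
            if tag == TAG_BRIDGE:
                bridges.append(xyz)
            else:
                if tag == TAG_ANCHOR and frame == 0:
                    anchor_idx.add(len(chrom))
                chrom.append(xyz)
        frames_c.append(chrom)
        frames_b.append(bridges)
        i += 2 + n
        frame += 1
    if not frames_c:
        raise TrajectoryFormatError("no frames found")
    nc = len(frames_c[0])
    if annotation is None:
        anchors = frozenset(anchor_idx | {0, nc - 1})
        annotation = LoopAnnotation(
            loops=((0, nc),),
            anchor_beads=anchors,
            looping_springs=(),
            attractive_anchors=frozenset(anchor_idx),
        )
    return Trajectory(
        chromatin=np.array(frames_c),
        bridges=np.array(frames_b),
        times=np.array(times, dtype=np.int64),
        phases=np.array(phases, dtype=np.int8),
        annotation=annotation,
        box=box if box is not None else np.full(3, np.inf),
    )


# ---------------------------------------------------------------------------
# HDF5 container


def _annotation_to_group(ann: LoopAnnotation, grp: h5py.Group) -> None:
    grp.create_dataset("loops", data=np.array(ann.loops, dtype=np.int64))
    grp.create_dataset("anchor_beads", data=np.array(sorted(ann.anchor_beads), dtype=np.int64))
    grp.create_dataset(
        "looping_springs", data=np.array(ann.looping_springs, dtype=np.int64).reshape(-1, 2)
    )
    grp.create_dataset(
        "attractive_anchors", data=np.array(sorted(ann.attractive_anchors), dtype=np.int64)
    )
    grp.create_dataset("lesioned_loops", data=np.array(ann.lesioned_loops, dtype=np.int64))
    grp.create_dataset(
        "chain_ranges", data=np.array(ann.chain_ranges, dtype=np.int64).reshape(-1, 2)
    )
    grp.attrs["bp_per_bead"] = ann.cg.bp_per_bead
    grp.attrs["truncated_last"] = ann.truncated_last
    if ann.cg.sigma_nm is not None:
        grp.attrs["sigma_nm"] = ann.cg.sigma_nm


def _annotation_from_group(grp: h5py.Group) -> LoopAnnotation:
    cg = CoarseGrainingMap(
        bp_per_bead=int(grp.attrs["bp_per_bead"]),
        sigma_nm=float(grp.attrs["sigma_nm"]) if "sigma_nm" in grp.attrs else None,
    )
    return LoopAnnotation(
        loops=tuple(map(tuple, grp["loops"][...].tolist())),
        anchor_beads=frozenset(grp["anchor_beads"][...].tolist()),
        looping_springs=tuple(map(tuple, grp["looping_springs"][...].tolist())),
        attractive_anchors=frozenset(grp["attractive_anchors"][...].tolist()),
        cg=cg,
        truncated_last=bool(grp.attrs["truncated_last"]),
        lesioned_loops=tuple(grp["lesioned_loops"][...].tolist()),
        chain_ranges=tuple(map(tuple, grp["chain_ranges"][...].tolist())),
    )


def _metadata_to_json(metadata: dict) -> str:
    out = {}
    for k, v in metadata.items():
        if dataclasses.is_dataclass(v):
            d = dataclasses.asdict(v)
            d["__class__"] = type(v).__name__
            out[k] = d
        elif isinstance(v, (int, float, str, bool, list, dict, type(None))):
            out[k] = v
        else:
            out[k] = str(v)
    return json.dumps(out)


_META_CLASSES = {
    "ForceFieldParams": ForceFieldParams,
    "EngineParams": EngineParams,
    "Schedule": Schedule,
    "PullingProtocol": PullingProtocol,
}


def _metadata_from_json(text: str) -> dict:
    raw = json.loads(text)
    out = {}
    for k, v in raw.items():
        if isinstance(v, dict) and v.get("__class__") in _META_CLASSES:
            cls = _META_CLASSES[v.pop("__class__")]
            if cls is Schedule and isinstance(v.get("pulling"), dict):
                v["pulling"] = PullingProtocol(**_tupled(v["pulling"]))
            out[k] = cls(**_tupled(v))
        else:
            out[k] = v
    return out


def _tupled(d: dict) -> dict:
    return {
        k: tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v
        for k, v in d.items()
    }


def write_h5(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("chromatin", data=traj.chromatin)
        fh.create_dataset("bridges", data=traj.bridges)
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("phases", data=traj.phases)
        fh.create_dataset("box", data=traj.box)
        if traj.extension is not None:
            fh.create_dataset("extension", data=traj.extension)
        _annotation_to_group(traj.annotation, fh.create_group("annotation"))
        fh.attrs["metadata"] = _metadata_to_json(traj.metadata)
        if traj.final_state is not None:
            st = fh.create_group("final_state")
            st.create_dataset("chromatin_coords", data=traj.final_state.chromatin_coords)
            st.create_dataset("bridge_coords", data=traj.final_state.bridge_coords)
            st.create_dataset("chromatin_vel", data=traj.final_state.chromatin_vel)
            st.create_dataset("bridge_vel", data=traj.final_state.bridge_vel)
            st.create_dataset("bonds", data=traj.final_state.bonds)
            st.create_dataset("bond_kinds", data=traj.final_state.bond_kinds)
            st.attrs["time_step_index"] = traj.final_state.time_step_index


def read_h5(path) -> Trajectory:
    try:
        fh = h5py.File(path, "r")
    except OSError as err:
        raise TrajectoryFormatError(f"cannot open {path}: {err}") from err
    with fh:
        annotation = _annotation_from_group(fh["annotation"])
        box = fh["box"][...]
        final_state = None
        if "final_state" in fh:
            st = fh["final_state"]
            final_state = SimulationState(
                chromatin_coords=st["chromatin_coords"][...],
                bridge_coords=st["bridge_coords"][...],
                chromatin_vel=st["chromatin_vel"][...],
                bridge_vel=st["bridge_vel"][...],
                bonds=st["bonds"][...],
                bond_kinds=st["bond_kinds"][...],
                annotation=annotation,
                box=box,
                time_step_index=int(st.attrs["time_step_index"]),
            )
        return Trajectory(
            chromatin=fh["chromatin"][...],
            bridges=fh["bridges"][...],
            times=fh["times"][...],
            phases=fh["phases"][...],
            annotation=annotation,
            box=box,
            metadata=_metadata_from_json(fh.attrs["metadata"]),
            extension=fh["extension"][...] if "extension" in fh else None,
            final_state=final_state,
        )


def write_trajectory(traj: Trajectory, path, format: Optional[str] = None) -> None:
    """Dispatch on ``format`` ("xyz" or "h5"), inferred from the suffix."""
    fmt = format or _infer(path)
    if fmt == "xyz":
        write_xyz(traj, path)
    elif fmt == "h5":
        write_h5(traj, path)
    else:
        raise TrajectoryFormatError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, format: Optional[str] = None, annotation=None) -> Trajectory:
    fmt = format or _infer(path)
    if fmt == "xyz":
        return read_xyz(path, annotation=annotation)
    if fmt == "h5":
        return read_h5(path)
    raise TrajectoryFormatError(f"unknown trajectory format {fmt!r}")


def _infer(path) -> str:
    s = str(path)
    if s.endswith(".xyz"):
        return "xyz"
    if s.endswith((".h5", ".hdf5")):
        return "h5"
    raise TrajectoryFormatError(f"cannot infer format from {s!r}; pass format=")
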