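"""End-to-end experiment recipes.

Each scenario builds, runs and analyses a small replicate set and returns a
:class:`ComparativeReport` with per-replicate observables and replicate
mean/spread aggregates.  Desk-scale defaults (~1200 beads = 2.4 Mbp per
chromatid) keep a wild-type replicate to a few minutes on one core; the
``scale`` multiplier reaches larger systems.

Available scenarios: ``wildtype``, ``sisters``, ``sweep``, ``pull_release``,
``ko_condensin_I``, ``ko_condensin_II``, ``lesion``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import analysis
from .builder import (
    apply_lesion_to_state,
    build_bottlebrush,
    build_sisters,
    knockout_transform,
    lesion_bead_span,
    place_bridges,
)
from .engine import EngineParams, PullingProtocol, Schedule, apply_pulling, run_schedule
from .errors import ConfigError, MitobrushError
from .forcefield import ForceFieldParams
from .state import BottlebrushConfig, Trajectory

SCENARIO_NAMES = (
    "wildtype",
    "sisters",
    "sweep",
    "pull_release",
    "ko_condensin_I",
    "ko_condensin_II",
    "lesion",
)

# Desk-scale study conditions.  The wild-type chromatid is 1000 beads
# (2 Mbp); comparison conditions (topo II sweep, knockouts, lesions) run at
# 600 beads with a shorter phase 2, long enough for the shape observables to
# plateau at that size.
DEFAULT_BASE_CONFIG = BottlebrushConfig(n_beads=1000)
DEFAULT_SCHEDULE = Schedule(phase1_steps=1_000, phase2_steps=150_000, snapshot_every=3_000)
COMPARISON_BASE_CONFIG = BottlebrushConfig(n_beads=600)
COMPARISON_SCHEDULE = Schedule(phase1_steps=1_000, phase2_steps=100_000, snapshot_every=3_000)
# Lesions need flanks large enough to condense into two distinct bodies.
LESION_BASE_CONFIG = BottlebrushConfig(n_beads=1200)
LESION_SCHEDULE = Schedule(phase1_steps=1_000, phase2_steps=120_000, snapshot_every=3_000)
DEFAULT_LESION_K = 3

_CONFIG_KEYS = {f.name for f in dataclasses.fields(BottlebrushConfig)}
_FF_KEYS = {f.name for f in dataclasses.fields(ForceFieldParams)}
_ENGINE_KEYS = {f.name for f in dataclasses.fields(EngineParams)} - {"seed"}
_SCHEDULE_KEYS = {f.name for f in dataclasses.fields(Schedule)}
_SCENARIO_KEYS = {"ko_factors", "lesion_first_loop", "lesion_k", "conditions",
                  "pulling", "centromere_span", "keep_trajectories"}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, reproducible experiment."""

    name: str
    base_config: BottlebrushConfig = DEFAULT_BASE_CONFIG
    forcefield: ForceFieldParams = ForceFieldParams()
    engine: EngineParams = EngineParams()
    schedule: Schedule = DEFAULT_SCHEDULE
    overrides: dict = field(default_factory=dict)
    replicate_seeds: tuple[int, ...] = (1, 2, 3)
    scale: float = 1.0

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ConfigError(f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}")
        if not self.replicate_seeds:
            raise ConfigError("replicate_seeds must be non-empty")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")
        unknown = set(self.overrides) - _CONFIG_KEYS - _FF_KEYS - _ENGINE_KEYS - _SCHEDULE_KEYS - _SCENARIO_KEYS
        if unknown:
            raise ConfigError(f"unknown override keys {sorted(unknown)}")

    def resolved(self) -> tuple[BottlebrushConfig, ForceFieldParams, EngineParams, Schedule]:
        """Apply scale and overrides to the four parameter blocks."""
        cfg = self.base_config
        if self.scale != 1.0:
            cfg = cfg.with_(n_beads=max(1, int(round(cfg.n_beads * self.scale))))
        ov = self.overrides
        cfg_kw = {k: v for k, v in ov.items() if k in _CONFIG_KEYS}
        if "loop_len_range_bp" in cfg_kw:
            cfg_kw["loop_len_range_bp"] = tuple(cfg_kw["loop_len_range_bp"])
        if cfg_kw:
            cfg = cfg.with_(**cfg_kw)
        ff = self.forcefield
        ff_kw = {k: v for k, v in ov.items() if k in _FF_KEYS}
        if ff_kw:
            ff = ff.with_(**ff_kw)
        eng = self.engine
        eng_kw = {k: v for k, v in ov.items() if k in _ENGINE_KEYS}
        if eng_kw:
            eng = eng.with_(**eng_kw)
        sched = self.schedule
        sched_kw = {k: v for k, v in ov.items() if k in _SCHEDULE_KEYS}
        if sched_kw:
            sched = sched.with_(**sched_kw)
        return cfg, ff, eng, sched


@dataclass
class ComparativeReport:
    """Replicate observables plus their means and spreads."""

    scenario: str
    n_beads: int
    replicates: list  # one summary dict per surviving replicate
    aggregate: dict  # metric -> {"mean", "sd", "n"}
    failures: list = field(default_factory=list)  # (seed, error message)
    conditions: Optional[dict] = None  # sweep: label -> ComparativeReport
    manifest: dict = field(default_factory=dict)
    trajectories: Optional[list] = None


def _aggregate(replicates: list[dict]) -> dict:
    keys = [k for k in replicates[0] if isinstance(replicates[0][k], (int, float, np.floating))]
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in replicates if r.get(k) is not None], dtype=float)
        out[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                  "n": int(len(vals))}
    return out


def _phase2_indices(traj: Trajectory) -> np.ndarray:
    idx = np.nonzero(traj.phases == 2)[0]
    return idx if idx.size else np.array([traj.n_frames - 1])


def _summarize_compaction(traj: Trajectory) -> dict:
    """Standard per-replicate observables of a compaction run.

    "phase-2 start" is the snapshot at (or right before) the attraction
    switch-on; "final" values average the last quarter of phase-2 frames to
    damp single-frame shape fluctuations.
    """
    shapes = analysis.shape_series(traj)
    p2 = _phase2_indices(traj)
    final = int(p2[-1])
    p1 = np.nonzero(traj.phases == 1)[0]
    start = int(p1[-1]) if p1.size else int(p2[0])
    tail = p2[-max(1, len(p2) // 4):]
    n_clusters = [analysis.cluster_bridges(traj.bridges[i]).n_clusters for i in tail]
    n_foci, largest_focus, largest_fraction = [], [], []
    for i in tail:
        foci = analysis.bridge_foci(traj.chromatin[i], traj.bridges[i])
        bound = analysis.bridge_foci(traj.chromatin[i], traj.bridges[i], min_size=1)
        n_foci.append(foci.n_clusters)
        largest_focus.append(int(foci.cluster_sizes[0]) if foci.n_clusters else 0)
        n_bound = int(bound.cluster_sizes.sum()) if bound.n_clusters else 0
        largest_fraction.append(largest_focus[-1] / n_bound if n_bound else 0.0)
    profile = analysis.contact_probability(traj, frames=tail)
    try:
        analysis.fit_exponent(profile)
        exponent = profile.fitted_exponent
    except MitobrushError:
        exponent = None
    bb0 = analysis.backbone_metrics(traj.chromatin[0], traj.annotation)
    bb1 = analysis.backbone_metrics(traj.chromatin[final], traj.annotation)
    return {
        "rg_initial": float(shapes.rg[0]),
        "rg_phase2_start": float(shapes.rg[start]),
        "rg_final": float(np.mean(shapes.rg[tail])),
        "acylindricity_phase2_start": float(shapes.acylindricity[start]),
        "acylindricity_final": float(np.mean(shapes.acylindricity[tail])),
        "length_final": float(np.mean(shapes.length[tail])),
        "width_final": float(np.mean(shapes.width[tail])),
        "ps_exponent": exponent,
        "n_bridge_clusters": float(np.mean(n_clusters)),
        "n_bridge_foci": float(np.mean(n_foci)),
        "largest_focus_size": float(np.mean(largest_focus)),
        "largest_focus_fraction": float(np.mean(largest_fraction)),
        "backbone_contour_initial": bb0["contour_length"],
        "backbone_contour_final": bb1["contour_length"],
        "backbone_e2e_initial": bb0["end_to_end"],
        "backbone_e2e_final": bb1["end_to_end"],
        "backbone_straightness_final": bb1["straightness"],
        "seed": int(traj.metadata["seed"]),
    }


def _build_and_run(cfg, ff, eng, sched, seed, sisters=False, centromere_span=None,
                   lesion=None) -> Trajectory:
    cfg = cfg.with_(seed=seed)
    if sisters:
        span = centromere_span or _central_span(cfg.n_beads, 0.05)
        state = build_sisters(cfg, cfg.with_(seed=seed + 10_000), span)
    else:
        state = build_bottlebrush(cfg)
    if lesion is not None:
        state = apply_lesion_to_state(state, lesion[0], lesion[1])
    state = place_bridges(state, cfg.n_bridges, seed=seed)
    return run_schedule(state, ff, eng.with_(seed=seed), sched)


def _central_span(n_beads: int, fraction: float) -> tuple[int, int]:
    half = max(1, int(round(n_beads * fraction / 2)))
    mid = n_beads // 2
    return (mid - half, mid + half)


def run_scenario(spec: ScenarioSpec, keep_trajectories: Optional[bool] = None) -> ComparativeReport:
    """Build, run, analyse and aggregate every replicate of ``spec``.

    Replicate failures are recorded in ``failures`` and the report is
    produced for the survivors.
    """
    cfg, ff, eng, sched = spec.resolved()
    if keep_trajectories is None:
        keep_trajectories = bool(spec.overrides.get("keep_trajectories", False))

    if spec.name == "sweep":
        conditions = spec.overrides.get("conditions")
        if not conditions:
            raise ConfigError("sweep scenario needs overrides['conditions'] = list of override dicts")
        cond_reports = {}
        for i, cond in enumerate(conditions):
            label = cond.get("label", f"cond_{i}")
            sub_ov = {k: v for k, v in cond.items() if k != "label"}
            sub = dataclasses.replace(
                spec, name="wildtype",
                overrides={**{k: v for k, v in spec.overrides.items() if k != "conditions"},
                           **sub_ov},
            )
            cond_reports[label] = run_scenario(sub, keep_trajectories=keep_trajectories)
        return ComparativeReport(
            scenario="sweep", n_beads=cfg.n_beads, replicates=[],
            aggregate={}, conditions=cond_reports, manifest=_manifest(spec, cfg, ff, eng, sched),
        )

    if spec.name in ("ko_condensin_I", "ko_condensin_II"):
        which = spec.name.removeprefix("ko_")
        cfg = knockout_transform(cfg, which, spec.overrides.get("ko_factors"))

    lesion = None
    if spec.name == "lesion":
        # default: DEFAULT_LESION_K loops removed from the middle of the chain
        k = int(spec.overrides.get("lesion_k", DEFAULT_LESION_K))
        first_loop = spec.overrides.get("lesion_first_loop")
        lesion = (first_loop, k)

    replicates, failures, trajs = [], [], []
    for seed in spec.replicate_seeds:
        try:
            if spec.name == "lesion" and lesion[0] is None:
                # centre the lesion per replicate (loop count varies with
                # seed), always leaving at least one intact flanking loop
                probe = build_bottlebrush(cfg.with_(seed=seed))
                n_loops = probe.annotation.n_loops
                first = max(1, min((n_loops - lesion[1]) // 2, n_loops - lesion[1] - 1))
                lesion_here = (first, lesion[1])
            else:
                lesion_here = lesion
            traj = _build_and_run(
                cfg, ff, eng, sched, seed,
                sisters=(spec.name == "sisters"),
                centromere_span=spec.overrides.get("centromere_span"),
                lesion=lesion_here,
            )
            if spec.name == "pull_release":
                protocol = spec.overrides.get("pulling") or PullingProtocol()
                traj = apply_pulling(traj, protocol, engine=eng.with_(seed=seed))
                summary = _summarize_pulling(traj)
            else:
                summary = _summarize_compaction(traj)
            if spec.name == "lesion":
                span = lesion_bead_span(traj.annotation)
                summary["lesion_gap_score"] = lesion_gap_score(traj, span)
            replicates.append(summary)
            if keep_trajectories:
                trajs.append(traj)
        except MitobrushError as err:
            failures.append((seed, str(err)))
    if not replicates:
        raise MitobrushError(
            f"every replicate of scenario {spec.name!r} failed: {failures}"
        )
    return ComparativeReport(
        scenario=spec.name,
        n_beads=cfg.n_beads,
        replicates=replicates,
        aggregate=_aggregate(replicates),
        failures=failures,
        manifest=_manifest(spec, cfg, ff, eng, sched),
        trajectories=trajs if keep_trajectories else None,
    )


def _summarize_pulling(traj: Trajectory) -> dict:
    ext = traj.extension
    pull_frames = np.nonzero(traj.phases == 3)[0]
    release_frames = np.nonzero(traj.phases == 4)[0]
    pre = float(ext[0])
    peak = float(ext[pull_frames].max()) if pull_frames.size else pre
    tail = release_frames[-max(1, len(release_frames) // 4):]
    post = float(ext[tail].mean()) if release_frames.size else pre
    return {
        "extension_pre_pull": pre,
        "extension_peak": peak,
        "extension_post_release": post,
        "stretch_ratio": peak / pre if pre > 0 else float("nan"),
        "recovery_error": abs(post - pre) / pre if pre > 0 else float("nan"),
        "seed": int(traj.metadata["seed"]),
    }


def _manifest(spec, cfg, ff, eng, sched) -> dict:
    from . import __version__

    return {
        "scenario": spec.name,
        "version": __version__,
        "replicate_seeds": list(spec.replicate_seeds),
        "scale": spec.scale,
        "config": dataclasses.asdict(cfg),
        "forcefield": dataclasses.asdict(ff),
        "engine": dataclasses.asdict(eng),
        "schedule": {k: v for k, v in dataclasses.asdict(sched).items() if k != "pulling"},
        "overrides": {k: str(v) for k, v in spec.overrides.items()},
    }


# ---------------------------------------------------------------------------
# cross-condition comparisons


def ko_phenotype(report_wt: ComparativeReport, report_ko: ComparativeReport,
                 dead_band: float = 0.10) -> str:
    """Classify a knockout against wild type from replicate-mean shape.

    Chromosome length is scored on the anchor backbone contour — the axis
    of the chromatid, which is what "shorter"/"longer" refers to; at desk
    scale the whole-cloud extent is dominated by individual loops and does
    not track the axis.  Width is the mean cloud extent along the two
    minor principal axes.  Relative deltas within ``dead_band`` of wild
    type count as unchanged.  Returns ``shorter_wider`` /
    ``longer_thinner`` / ``unchanged``.
    """
    if report_wt.n_beads != report_ko.n_beads:
        raise ConfigError(
            f"cannot compare reports at different scales "
            f"({report_wt.n_beads} vs {report_ko.n_beads} beads)"
        )
    key = "backbone_contour_final"
    if key not in report_ko.aggregate or key not in report_wt.aggregate:
        key = "length_final"
    dl = (report_ko.aggregate[key]["mean"] / report_wt.aggregate[key]["mean"]) - 1.0
    dw = (report_ko.aggregate["width_final"]["mean"] / report_wt.aggregate["width_final"]["mean"]) - 1.0
    shorter_wider = dl <= -dead_band or dw >= dead_band
    longer_thinner = dl >= dead_band or dw <= -dead_band
    if shorter_wider and not longer_thinner:
        return "shorter_wider"
    if longer_thinner and not shorter_wider:
        return "longer_thinner"
    return "unchanged"


def density_gap_score(coords: np.ndarray, window: tuple[float, float],
                      axis: Optional[np.ndarray] = None,
                      flank_width: Optional[float] = None,
                      radial_cutoff: Optional[float] = None) -> float:
    """Linear bead density inside an axial window relative to its flanks.

    ``window`` is an interval of positions along the principal axis
    (centroid-relative).  With ``radial_cutoff`` set, only beads inside a
    tube of that radius around the axis are counted — the microscopy-like
    view in which diffuse, decompacted chromatin does not register.  A
    score near 1 means no gap; values well below 1 mean the window is
    depleted relative to the flanking regions of equal width.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    if axis is None:
        axis = analysis.gyration_tensor(coords)[1]["principal_axis"]
    centered = coords - coords.mean(axis=0)
    t = centered @ axis
    if radial_cutoff is not None:
        radial = np.linalg.norm(centered - t[:, None] * axis[None, :], axis=1)
        keep = radial <= radial_cutoff
        t = t[keep]
    lo, hi = sorted(window)
    width = max(hi - lo, 1.0)
    mid = 0.5 * (lo + hi)
    lo, hi = mid - width / 2, mid + width / 2
    fw = flank_width or width
    inside = np.count_nonzero((t >= lo) & (t < hi)) / width
    left = np.count_nonzero((t >= lo - fw) & (t < lo)) / fw
    right = np.count_nonzero((t >= hi) & (t < hi + fw)) / fw
    flank = 0.5 * (left + right)
    if flank == 0:
        return float("nan")
    return float(inside / flank)


def lesion_gap_score(traj: Trajectory, lesion_span: tuple[int, int],
                     frames="final_quarter") -> float:
    """Gap depth at a lesion, averaged over the selected frames.

    The two non-lesioned chain segments flanking the lesion condense into
    two bodies; the score compares the chromatin linear density in the
    central slab midway between their centroids (along the axis joining
    them) with the density in equal-width slabs centred on the bodies
    themselves.  A broken chromatid — dense flanks spanned only by the
    diffuse, spring-free lesioned coil — scores below 1; a uniform
    chromatid scores near 1.
    """
    lo_bead, hi_bead = lesion_span
    n = traj.chromatin.shape[1]
    if not (0 <= lo_bead < hi_bead <= n):
        raise ConfigError(f"lesion span {lesion_span} outside chain of {n} beads")
    if lo_bead == 0 or hi_bead == n:
        raise ConfigError("lesion span must leave a flanking segment on both sides")
    idx = traj.select_frames(frames)
    scores = []
    for i in idx:
        coords = traj.chromatin[i]
        c_left = coords[:lo_bead].mean(axis=0)
        c_right = coords[hi_bead:].mean(axis=0)
        axis = c_right - c_left
        sep = float(np.linalg.norm(axis))
        if sep < 1e-9:
            scores.append(1.0)
            continue
        axis /= sep
        t = (coords - c_left) @ axis
        # narrow slabs resolve the neck between the two bodies
        w = max(sep / 5.0, 2.0)

        def slab_density(centre):
            return np.count_nonzero(np.abs(t - centre) <= w / 2) / w

        mid = slab_density(sep / 2.0)
        flank = 0.5 * (slab_density(0.0) + slab_density(sep))
        scores.append(mid / flank if flank > 0 else float("nan"))
    return float(np.nanmean(scores))
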