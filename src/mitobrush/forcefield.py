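"""Interaction potentials.

Four non-bonded pair classes:

``chromatin-chromatin``
    Purely repulsive soft-core potential ``U(r) = A (1 + cos(pi r / rc))``
    truncated at ``rc``.  The barrier to full overlap is finite (``2A`` at
    ``r = 0``), so chromatin strands can cross each other at a rate set by
    ``A`` in units of k_B*T.  This is the topoisomerase-II proxy: low ``A``
    means frequent strand passage (high enzyme activity), large ``A``
    approaches an uncrossable fiber.

``bridge-chromatin`` / ``bridge-anchor``
    In phase 2, truncated-and-shifted Lennard-Jones wells normalised so the
    minimum depth is exactly ``eps_weak`` / ``eps_strong`` (k_B*T) at
    ``r = 2^(1/6) sigma``.  In phase 1 both collapse to a purely steric WCA
    term of strength ``bridge_excluded_volume``.

``bridge-bridge``
    Always purely steric (WCA).  Bridge clustering in this model is an
    emergent bridging-induced attraction; no direct bridge-bridge
    attraction term exists anywhere in the energy.

Bonds (backbone and looping springs) use a rest-length-shifted finitely
extensible (FENE-like) potential that diverges at ``|r - r0| = R0``, so no
pulling force can detach a loop; centromere cross-links are harmonic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError

PAIR_CLASSES = ("chromatin-chromatin", "bridge-chromatin", "bridge-anchor", "bridge-bridge")

_WCA_CUT = 2.0 ** (1.0 / 6.0)
# depth of a 4[(1/r)^12-(1/r)^6] well truncated-and-shifted at rc=1.8
def _lj_ts_depth(rc: float) -> float:
    u_rc = 4.0 * (rc ** -12 - rc ** -6)
    return 1.0 - abs(u_rc) if u_rc < 0 else 1.0


@dataclass(frozen=True)
class ForceFieldParams:
    """All interaction constants, energies in k_B*T, lengths in bead diameters."""

    A: float = 4.0  # chromatin-chromatin soft repulsion strength (topo II proxy)
    eps_weak: float = 3.0  # bridge <-> generic chromatin well depth
    eps_strong: float = 8.0  # bridge <-> attractive loop anchor well depth
    bond_k: float = 30.0  # FENE spring constant
    bond_r0: float = 1.0  # bond rest length
    bond_maxext: float = 0.9  # divergence at |r - r0| = bond_maxext
    bridge_excluded_volume: float = 1.0  # WCA strength; 0 disables phase-1 sterics
    centromere_k: float = 10.0  # harmonic sister cross-link constant
    cutoff_cc: float = _WCA_CUT  # chromatin-chromatin soft cutoff
    cutoff_attr: float = 1.8  # attractive LJ cutoff
    cutoff_bb: float = _WCA_CUT  # bridge-bridge WCA cutoff

    def __post_init__(self):
        if self.A < 0:
            raise ConfigError(f"A must be >= 0, got {self.A}")
        if not (self.eps_strong > self.eps_weak >= 0):
            raise ConfigError(
                f"need eps_strong > eps_weak >= 0, got {self.eps_strong}, {self.eps_weak}"
            )
        for name in ("cutoff_cc", "cutoff_attr", "cutoff_bb"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.bond_maxext <= 0 or self.bond_k <= 0:
            raise ConfigError("bond constants must be positive")

    @property
    def crossing_barrier(self) -> float:
        """Energy barrier for two chromatin beads to pass through each other."""
        return 2.0 * self.A

    @property
    def bond_maxlen(self) -> float:
        """Hard upper bound on any FENE bond length."""
        return self.bond_r0 + self.bond_maxext

    @property
    def max_cutoff(self) -> float:
        return max(self.cutoff_cc, self.cutoff_attr, self.cutoff_bb)

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


def _soft(r: float, A: float, rc: float) -> tuple[float, float]:
    if r >= rc:
        return 0.0, 0.0
    e = A * (1.0 + math.cos(math.pi * r / rc))
    f = A * math.pi / rc * math.sin(math.pi * r / rc)  # -dU/dr
    return e, f


def _wca(r: float, eps: float, rc: float) -> tuple[float, float]:
    if r >= rc or eps == 0.0:
        return 0.0, 0.0
    inv6 = r ** -6
    e = 4.0 * eps * (inv6 * inv6 - inv6) + eps
    f = 4.0 * eps * (12.0 * inv6 * inv6 - 6.0 * inv6) / r
    return e, f


def _lj_ts(r: float, eps: float, rc: float) -> tuple[float, float]:
    if r >= rc or eps == 0.0:
        return 0.0, 0.0
    scale = eps / _lj_ts_depth(rc)
    u_rc = 4.0 * (rc ** -12 - rc ** -6)
    inv6 = r ** -6
    e = scale * (4.0 * (inv6 * inv6 - inv6) - u_rc)
    f = scale * 4.0 * (12.0 * inv6 * inv6 - 6.0 * inv6) / r
    return e, f


def pair_potential(
    pair_class: str, r: float, params: ForceFieldParams, phase: int = 2
) -> tuple[float, float]:
    """Energy and radial force magnitude for one pair class at separation ``r``.

    The force is ``-dU/dr``: positive values push the pair apart.  Phase 1
    (pre-attraction) replaces the bridge attraction wells with sterics.
    """
    if r <= 0:
        raise ConfigError(f"pair separation must be positive, got {r}")
    if phase not in (1, 2):
        raise ConfigError(f"phase must be 1 or 2, got {phase}")
    if pair_class == "chromatin-chromatin":
        return _soft(r, params.A, params.cutoff_cc)
    if pair_class == "bridge-bridge":
        return _wca(r, params.bridge_excluded_volume, params.cutoff_bb)
    if pair_class == "bridge-chromatin":
        if phase == 1:
            return _wca(r, params.bridge_excluded_volume, params.cutoff_bb)
        return _lj_ts(r, params.eps_weak, params.cutoff_attr)
    if pair_class == "bridge-anchor":
        if phase == 1:
            return _wca(r, params.bridge_excluded_volume, params.cutoff_bb)
        return _lj_ts(r, params.eps_strong, params.cutoff_attr)
    raise ConfigError(f"unknown pair class {pair_class!r}; expected one of {PAIR_CLASSES}")


def bond_potential(
    r: float, params: ForceFieldParams, kind: str = "fene"
) -> tuple[float, float]:
    """Bond energy and radial force magnitude (``-dU/dr``, positive = repulsive).

    ``fene``: shifted finitely extensible spring centred on ``bond_r0``.
    ``harmonic``: centromere cross-link.
    """
    if r <= 0:
        raise ConfigError(f"bond length must be positive, got {r}")
    if kind == "harmonic":
        e = 0.5 * params.centromere_k * (r - params.bond_r0) ** 2
        f = -params.centromere_k * (r - params.bond_r0)
        return e, f
    if kind != "fene":
        raise ConfigError(f"unknown bond kind {kind!r}")
    x = r - params.bond_r0
    R0 = params.bond_maxext
    if abs(x) >= R0:
        raise ConfigError(f"bond length {r} outside admissible range |r-r0| < {R0}")
    e = -0.5 * params.bond_k * R0 * R0 * math.log(1.0 - (x / R0) ** 2)
    f = -params.bond_k * x / (1.0 - (x / R0) ** 2)
    return e, f


# ---------------------------------------------------------------------------
# tabulated class parameters consumed by the numba kernel

KIND_NONE = 0
KIND_SOFT = 1
KIND_WCA = 2
KIND_LJTS = 3


def class_table(params: ForceFieldParams, phase: int) -> np.ndarray:
    """(3, 3, 4) table mapping particle-type pairs to kernel parameters.

    Row per (type_i, type_j): [kind, strength, cutoff, shift-or-scale].
    Types: 0 chromatin, 1 attractive anchor, 2 bridge.
    """
    tab = np.zeros((3, 3, 4))

    def setrow(ti, tj, row):
        tab[ti, tj] = row
        tab[tj, ti] = row

    soft = (KIND_SOFT, params.A, params.cutoff_cc, 0.0)
    setrow(0, 0, soft)
    setrow(0, 1, soft)
    setrow(1, 1, soft)
    wca = (KIND_WCA, params.bridge_excluded_volume, params.cutoff_bb, 0.0)
    setrow(2, 2, wca)
    if phase == 1:
        setrow(0, 2, wca)
        setrow(1, 2, wca)
    else:
        depth = _lj_ts_depth(params.cutoff_attr)
        u_rc = 4.0 * (params.cutoff_attr ** -12 - params.cutoff_attr ** -6)
        setrow(0, 2, (KIND_LJTS, params.eps_weak / depth, params.cutoff_attr, u_rc))
        setrow(1, 2, (KIND_LJTS, params.eps_strong / depth, params.cutoff_attr, u_rc))
    return tab


def bond_table(params: ForceFieldParams) -> np.ndarray:
    """(3, 4) table per bond kind: [is_harmonic, k, r0, R0]."""
    fene = (0.0, params.bond_k, params.bond_r0, params.bond_maxext)
    harm = (1.0, params.centromere_k, params.bond_r0, 0.0)
    return np.array([fene, fene, harm])
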