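"""Numba inner loops for the non-bonded and bonded force evaluation.

All kernels use the minimum-image convention with an orthorhombic box and
accumulate forces in-place into a caller-provided buffer, returning the
corresponding potential energy.  Pair-class dispatch goes through the
(3, 3, 4) table built by :func:`mitobrush.forcefield.class_table`.
"""

import numba
import numpy as np

from .forcefield import KIND_LJTS, KIND_SOFT, KIND_WCA


@numba.njit(cache=True, fastmath=True)
def nonbonded_kernel(pos, types, pairs, tab, box, forces):
    energy = 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        kind = int(tab[types[i], types[j], 0])
        strength = tab[types[i], types[j], 1]
        rc = tab[types[i], types[j], 2]
        if kind == 0 or strength == 0.0 or r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        if r < 1e-9:
            r = 1e-9
        if kind == KIND_SOFT:
            arg = np.pi * r / rc
            energy += strength * (1.0 + np.cos(arg))
            fmag = strength * np.pi / rc * np.sin(arg)
        elif kind == KIND_WCA:
            inv6 = 1.0 / (r2 * r2 * r2)
            energy += 4.0 * strength * (inv6 * inv6 - inv6) + strength
            fmag = 4.0 * strength * (12.0 * inv6 * inv6 - 6.0 * inv6) / r
        else:  # KIND_LJTS; tab[...,3] holds the unshifted energy at the cutoff
            shift = tab[types[i], types[j], 3]
            inv6 = 1.0 / (r2 * r2 * r2)
            energy += strength * (4.0 * (inv6 * inv6 - inv6) - shift)
            fmag = strength * 4.0 * (12.0 * inv6 * inv6 - 6.0 * inv6) / r
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy


@numba.njit(cache=True, fastmath=True)
def bond_kernel(pos, bonds, kinds, btab, box, forces):
    """Returns (energy, max FENE extension ratio |r - r0| / R0)."""
    energy = 0.0
    worst = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-9:
            r = 1e-9
        harmonic = btab[kinds[b], 0]
        k = btab[kinds[b], 1]
        r0 = btab[kinds[b], 2]
        if harmonic > 0.5:
            energy += 0.5 * k * (r - r0) * (r - r0)
            fmag = -k * (r - r0)
        else:
            R0 = btab[kinds[b], 3]
            x = r - r0
            ratio = abs(x) / R0
            if ratio > worst:
                worst = ratio
            if ratio >= 0.999:
                x = np.sign(x) * 0.999 * R0
                ratio = 0.999
            energy += -0.5 * k * R0 * R0 * np.log(1.0 - (x / R0) * (x / R0))
            fmag = -k * x / (1.0 - (x / R0) * (x / R0))
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, worst
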