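"""Numba-accelerated scoring kernels (optional fast path).

The docking objective is evaluated tens of thousands of times per search;
these flat-loop kernels replace the vectorized numpy evaluation when numba
is importable. Results are bit-for-bit reproducible against the numpy
path within floating-point associativity (< 1e-12), which the test suite
checks; fastmath stays off.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def pose_coords(ref, parents, childs, moved_flat, moved_off, torsions,
                R, center, position, out):
    """Torsion rotations (ancestors first) then rigid placement."""
    n = ref.shape[0]
    for i in range(n):
        out[i, 0] = ref[i, 0]
        out[i, 1] = ref[i, 1]
        out[i, 2] = ref[i, 2]
    for b in range(parents.shape[0]):
        ang = torsions[b]
        if ang == 0.0:
            continue
        c = childs[b]
        px, py, pz = out[c, 0], out[c, 1], out[c, 2]
        ax = px - out[parents[b], 0]
        ay = py - out[parents[b], 1]
        az = pz - out[parents[b], 2]
        an = np.sqrt(ax * ax + ay * ay + az * az)
        ax, ay, az = ax / an, ay / an, az / an
        ca = np.cos(ang)
        sa = np.sin(ang)
        t = 1.0 - ca
        for k in range(moved_off[b], moved_off[b + 1]):
            m = moved_flat[k]
            vx = out[m, 0] - px
            vy = out[m, 1] - py
            vz = out[m, 2] - pz
            dot = ax * vx + ay * vy + az * vz
            cx = ay * vz - az * vy
            cy = az * vx - ax * vz
            cz = ax * vy - ay * vx
            out[m, 0] = px + vx * ca + cx * sa + ax * dot * t
            out[m, 1] = py + vy * ca + cy * sa + ay * dot * t
            out[m, 2] = pz + vz * ca + cz * sa + az * dot * t
    for i in range(n):
        x = out[i, 0] - center[0]
        y = out[i, 1] - center[1]
        z = out[i, 2] - center[2]
        out[i, 0] = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z + position[0]
        out[i, 1] = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z + position[1]
        out[i, 2] = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z + position[2]


@njit(cache=False)
def pose_gradient(coords, dcoords, position, parents, childs,
                  moved_flat, moved_off, gout):
    """Chain rule: cartesian gradient -> (translation, torque, torsions)."""
    n = coords.shape[0]
    tx = ty = tz = 0.0
    rx = ry = rz = 0.0
    for i in range(n):
        gx, gy, gz = dcoords[i, 0], dcoords[i, 1], dcoords[i, 2]
        tx += gx
        ty += gy
        tz += gz
        vx = coords[i, 0] - position[0]
        vy = coords[i, 1] - position[1]
        vz = coords[i, 2] - position[2]
        rx += vy * gz - vz * gy
        ry += vz * gx - vx * gz
        rz += vx * gy - vy * gx
    gout[0], gout[1], gout[2] = tx, ty, tz
    gout[3], gout[4], gout[5] = rx, ry, rz
    for b in range(parents.shape[0]):
        c = childs[b]
        ax = coords[c, 0] - coords[parents[b], 0]
        ay = coords[c, 1] - coords[parents[b], 1]
        az = coords[c, 2] - coords[parents[b], 2]
        an = np.sqrt(ax * ax + ay * ay + az * az)
        ax, ay, az = ax / an, ay / an, az / an
        acc = 0.0
        for k in range(moved_off[b], moved_off[b + 1]):
            m = moved_flat[k]
            vx = coords[m, 0] - coords[c, 0]
            vy = coords[m, 1] - coords[c, 1]
            vz = coords[m, 2] - coords[c, 2]
            gx, gy, gz = dcoords[m, 0], dcoords[m, 1], dcoords[m, 2]
            acc += ax * (vy * gz - vz * gy)
            acc += ay * (vz * gx - vx * gz)
            acc += az * (vx * gy - vy * gx)
        gout[6 + b] = acc


@njit(cache=False)
def energy_inter(rec, lig, rsum, phob, hb, cutoff,
                 w_g1, w_g2, w_rep, w_phob, w_hb):
    """Intermolecular energy over all receptor x ligand heavy pairs."""
    e = 0.0
    for i in range(rec.shape[0]):
        for j in range(lig.shape[0]):
            dx = lig[j, 0] - rec[i, 0]
            dy = lig[j, 1] - rec[i, 1]
            dz = lig[j, 2] - rec[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > cutoff:
                continue
            d = r - rsum[i, j]
            e += w_g1 * np.exp(-(d / 0.5) ** 2)
            e += w_g2 * np.exp(-(((d - 3.0) / 2.0) ** 2))
            if d < 0.0:
                e += w_rep * d * d
            if phob[i, j]:
                if d <= 0.5:
                    e += w_phob
                elif d < 1.5:
                    e += w_phob * (1.5 - d)
            if hb[i, j]:
                if d <= -0.7:
                    e += w_hb
                elif d < 0.0:
                    e += w_hb * (d / -0.7)
    return e


@njit(cache=False)
def energy_grad_inter(rec, lig, rsum, phob, hb, cutoff,
                      w_g1, w_g2, w_rep, w_phob, w_hb, grad):
    """Intermolecular energy plus accumulation of dE/d(lig coords)."""
    e = 0.0
    for i in range(rec.shape[0]):
        for j in range(lig.shape[0]):
            dx = lig[j, 0] - rec[i, 0]
            dy = lig[j, 1] - rec[i, 1]
            dz = lig[j, 2] - rec[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > cutoff:
                continue
            d = r - rsum[i, j]
            g1 = np.exp(-(d / 0.5) ** 2)
            g2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
            e += w_g1 * g1 + w_g2 * g2
            dv = w_g1 * g1 * (-8.0 * d) + w_g2 * g2 * (-0.5 * (d - 3.0))
            if d < 0.0:
                e += w_rep * d * d
                dv += w_rep * 2.0 * d
            if phob[i, j]:
                if d <= 0.5:
                    e += w_phob
                elif d < 1.5:
                    e += w_phob * (1.5 - d)
                    dv += -w_phob
            if hb[i, j]:
                if d <= -0.7:
                    e += w_hb
                elif d < 0.0:
                    e += w_hb * (d / -0.7)
                    dv += w_hb / -0.7
            if r > 1e-9:
                s = dv / r
                grad[j, 0] += s * dx
                grad[j, 1] += s * dy
                grad[j, 2] += s * dz
    return e


@njit(cache=False)
def energy_intra(lig, ii, jj, rsum, phob, hb, cutoff,
                 w_g1, w_g2, w_rep, w_phob, w_hb):
    """Intramolecular energy over the precomputed flexible pair list."""
    e = 0.0
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        dx = lig[j, 0] - lig[i, 0]
        dy = lig[j, 1] - lig[i, 1]
        dz = lig[j, 2] - lig[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > cutoff:
            continue
        d = r - rsum[k]
        e += w_g1 * np.exp(-(d / 0.5) ** 2)
        e += w_g2 * np.exp(-(((d - 3.0) / 2.0) ** 2))
        if d < 0.0:
            e += w_rep * d * d
        if phob[k]:
            if d <= 0.5:
                e += w_phob
            elif d < 1.5:
                e += w_phob * (1.5 - d)
        if hb[k]:
            if d <= -0.7:
                e += w_hb
            elif d < 0.0:
                e += w_hb * (d / -0.7)
    return e


@njit(cache=False)
def energy_grad_intra(lig, ii, jj, rsum, phob, hb, cutoff,
                      w_g1, w_g2, w_rep, w_phob, w_hb, grad):
    e = 0.0
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        dx = lig[j, 0] - lig[i, 0]
        dy = lig[j, 1] - lig[i, 1]
        dz = lig[j, 2] - lig[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > cutoff:
            continue
        d = r - rsum[k]
        g1 = np.exp(-(d / 0.5) ** 2)
        g2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
        e += w_g1 * g1 + w_g2 * g2
        dv = w_g1 * g1 * (-8.0 * d) + w_g2 * g2 * (-0.5 * (d - 3.0))
        if d < 0.0:
            e += w_rep * d * d
            dv += w_rep * 2.0 * d
        if phob[k]:
            if d <= 0.5:
                e += w_phob
            elif d < 1.5:
                e += w_phob * (1.5 - d)
                dv += -w_phob
        if hb[k]:
            if d <= -0.7:
                e += w_hb
            elif d < 0.0:
                e += w_hb * (d / -0.7)
                dv += w_hb / -0.7
        if r > 1e-9:
            s = dv / r
            grad[j, 0] += s * dx
            grad[j, 1] += s * dy
            grad[j, 2] += s * dz
            grad[i, 0] -= s * dx
            grad[i, 1] -= s * dy
            grad[i, 2] -= s * dz
    return e
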