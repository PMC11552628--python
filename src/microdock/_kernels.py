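"""Optional numba-compiled hot loops.

The samplers evaluate the score and its gradient tens of thousands of times
per run on small systems, where numpy's per-call overhead dominates. These
kernels mirror the reference numpy implementations exactly (same arithmetic,
no fastmath reassociation, so results are bit-compatible); the package falls
back to the numpy paths when numba is unavailable. Tests assert agreement
between the two routes.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def vina_score_grad(lig, rec, idx_l, idx_r, rsum, phob, hb,
                    intra_i, intra_j, rsum_intra, phob_intra, hb_intra,
                    w, cutoff, ph_lo, ph_hi, hb_lo, hb_hi, include_intra):
    """Fused five-term score + coordinate gradients over heavy-atom pairs."""
    n_l = lig.shape[0]
    n_r = rec.shape[0]
    g_lig = np.zeros((n_l, 3))
    g_rec = np.zeros((n_r, 3))
    total = 0.0
    inv_ph = 1.0 / (ph_hi - ph_lo)
    inv_hb = 1.0 / (hb_hi - hb_lo)
    for a in range(idx_l.shape[0]):
        i = idx_l[a]
        xi = lig[i, 0]
        yi = lig[i, 1]
        zi = lig[i, 2]
        for b in range(idx_r.shape[0]):
            j = idx_r[b]
            dx = xi - rec[j, 0]
            dy = yi - rec[j, 1]
            dz = zi - rec[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > cutoff:
                continue
            s = d - rsum[a, b]
            g1 = np.exp(-(s / 0.5) ** 2)
            g2 = np.exp(-((s - 3.0) / 2.0) ** 2)
            e = w[0] * g1 + w[1] * g2
            dEds = w[0] * (-8.0 * s * g1) + w[1] * (-0.5 * (s - 3.0) * g2)
            if s < 0.0:
                e += w[2] * s * s
                dEds += w[2] * 2.0 * s
            if phob[a, b]:
                if s <= ph_lo:
                    e += w[3]
                elif s < ph_hi:
                    e += w[3] * (ph_hi - s) * inv_ph
                    dEds += -w[3] * inv_ph
            if hb[a, b]:
                if s <= hb_lo:
                    e += w[4]
                elif s < hb_hi:
                    e += w[4] * (hb_hi - s) * inv_hb
                    dEds += -w[4] * inv_hb
            total += e
            if d > 1e-9:
                c = dEds / d
                gx = c * dx
                gy = c * dy
                gz = c * dz
                g_lig[i, 0] += gx
                g_lig[i, 1] += gy
                g_lig[i, 2] += gz
                g_rec[j, 0] -= gx
                g_rec[j, 1] -= gy
                g_rec[j, 2] -= gz
    if include_intra:
        for p in range(intra_i.shape[0]):
            i = intra_i[p]
            j = intra_j[p]
            dx = lig[i, 0] - lig[j, 0]
            dy = lig[i, 1] - lig[j, 1]
            dz = lig[i, 2] - lig[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > cutoff:
                continue
            s = d - rsum_intra[p]
            g1 = np.exp(-(s / 0.5) ** 2)
            g2 = np.exp(-((s - 3.0) / 2.0) ** 2)
            e = w[0] * g1 + w[1] * g2
            dEds = w[0] * (-8.0 * s * g1) + w[1] * (-0.5 * (s - 3.0) * g2)
            if s < 0.0:
                e += w[2] * s * s
                dEds += w[2] * 2.0 * s
            if phob_intra[p]:
                if s <= ph_lo:
                    e += w[3]
                elif s < ph_hi:
                    e += w[3] * (ph_hi - s) * inv_ph
                    dEds += -w[3] * inv_ph
            if hb_intra[p]:
                if s <= hb_lo:
                    e += w[4]
                elif s < hb_hi:
                    e += w[4] * (hb_hi - s) * inv_hb
                    dEds += -w[4] * inv_hb
            total += e
            if d > 1e-9:
                c = dEds / d
                gx = c * dx
                gy = c * dy
                gz = c * dz
                g_lig[i, 0] += gx
                g_lig[i, 1] += gy
                g_lig[i, 2] += gz
                g_lig[j, 0] -= gx
                g_lig[j, 1] -= gy
                g_lig[j, 2] -= gz
    return total, g_lig, g_rec


@njit(cache=True)
def expand_pose(ref, center, translation, orientation, torsions,
                branch_parent, branch_child, moved_flat, moved_start):
    """Torsions root-outward, then rotate about the root reference point by
    the axis-angle orientation, then translate. Mirrors pose_to_cartesian."""
    n = ref.shape[0]
    coords = ref.copy()
    for t in range(torsions.shape[0]):
        ang = torsions[t]
        if ang == 0.0:
            continue
        pa = branch_parent[t]
        ca = branch_child[t]
        ox = coords[pa, 0]
        oy = coords[pa, 1]
        oz = coords[pa, 2]
        ax = coords[ca, 0] - ox
        ay = coords[ca, 1] - oy
        az = coords[ca, 2] - oz
        an = np.sqrt(ax * ax + ay * ay + az * az)
        ax /= an
        ay /= an
        az /= an
        c = np.cos(ang)
        s = np.sin(ang)
        for q in range(moved_start[t], moved_start[t + 1]):
            m = moved_flat[q]
            vx = coords[m, 0] - ox
            vy = coords[m, 1] - oy
            vz = coords[m, 2] - oz
            cx = ay * vz - az * vy
            cy = az * vx - ax * vz
            cz = ax * vy - ay * vx
            dot = ax * vx + ay * vy + az * vz
            coords[m, 0] = ox + vx * c + cx * s + ax * dot * (1.0 - c)
            coords[m, 1] = oy + vy * c + cy * s + ay * dot * (1.0 - c)
            coords[m, 2] = oz + vz * c + cz * s + az * dot * (1.0 - c)
    theta = np.sqrt(orientation[0] ** 2 + orientation[1] ** 2
                    + orientation[2] ** 2)
    if theta > 1e-12:
        ax = orientation[0] / theta
        ay = orientation[1] / theta
        az = orientation[2] / theta
        c = np.cos(theta)
        s = np.sin(theta)
        for m in range(n):
            vx = coords[m, 0] - center[0]
            vy = coords[m, 1] - center[1]
            vz = coords[m, 2] - center[2]
            cx = ay * vz - az * vy
            cy = az * vx - ax * vz
            cz = ax * vy - ay * vx
            dot = ax * vx + ay * vy + az * vz
            coords[m, 0] = (center[0] + translation[0]
                            + vx * c + cx * s + ax * dot * (1.0 - c))
            coords[m, 1] = (center[1] + translation[1]
                            + vy * c + cy * s + ay * dot * (1.0 - c))
            coords[m, 2] = (center[2] + translation[2]
                            + vz * c + cz * s + az * dot * (1.0 - c))
    else:
        for m in range(n):
            coords[m, 0] += translation[0]
            coords[m, 1] += translation[1]
            coords[m, 2] += translation[2]
    return coords


@njit(cache=True)
def chain_ligand_gradient(lig, g_lig, center_t, torsions_k,
                          branch_parent, branch_child, moved_flat, moved_start):
    """Translation sum, world-frame torque, and per-torsion projections.
    The orientation torque still needs the left-Jacobian transpose applied by
    the caller."""
    out = np.zeros(6 + torsions_k)
    tx = 0.0
    ty = 0.0
    tz = 0.0
    qx = 0.0
    qy = 0.0
    qz = 0.0
    for i in range(lig.shape[0]):
        gx = g_lig[i, 0]
        gy = g_lig[i, 1]
        gz = g_lig[i, 2]
        tx += gx
        ty += gy
        tz += gz
        rx = lig[i, 0] - center_t[0]
        ry = lig[i, 1] - center_t[1]
        rz = lig[i, 2] - center_t[2]
        qx += ry * gz - rz * gy
        qy += rz * gx - rx * gz
        qz += rx * gy - ry * gx
    out[0] = tx
    out[1] = ty
    out[2] = tz
    out[3] = qx
    out[4] = qy
    out[5] = qz
    for t in range(torsions_k):
        pa = branch_parent[t]
        ca = branch_child[t]
        ax = lig[ca, 0] - lig[pa, 0]
        ay = lig[ca, 1] - lig[pa, 1]
        az = lig[ca, 2] - lig[pa, 2]
        an = np.sqrt(ax * ax + ay * ay + az * az)
        ax /= an
        ay /= an
        az /= an
        acc = 0.0
        for q in range(moved_start[t], moved_start[t + 1]):
            m = moved_flat[q]
            rx = lig[m, 0] - lig[pa, 0]
            ry = lig[m, 1] - lig[pa, 1]
            rz = lig[m, 2] - lig[pa, 2]
            acc += ((ay * rz - az * ry) * g_lig[m, 0]
                    + (az * rx - ax * rz) * g_lig[m, 1]
                    + (ax * ry - ay * rx) * g_lig[m, 2])
        out[6 + t] = acc
    return out
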