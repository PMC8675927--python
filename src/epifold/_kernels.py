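"""Numba-compiled inner loops for the reaction-diffusion and vertex-mechanics solvers.

Everything here operates on plain ndarrays so the kernels stay cacheable and
free of Python-object overhead.  The public modules (`polarity`, `mechanics`)
wrap these with validated, documented interfaces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Index layout of the biochemical parameter vector passed to the RD kernels.
# Order: D_A, D_P, D_B, kon_A, koff_A, kAB, kAP, kon_P, koff_P, kPA,
#        kon_B, koff_B, kBA, kBP, alpha, beta, gamma, zeta, eps
NPAR = 19


@njit(cache=True)
def reaction_terms(A, P, B, Ac, Pc, Bc, par, RA, RP, RB):
    """Nodewise membrane association/dissociation rates for the A-B-P network."""
    kon_A, koff_A, kAB, kAP = par[3], par[4], par[5], par[6]
    kon_P, koff_P, kPA = par[7], par[8], par[9]
    kon_B, koff_B, kBA, kBP = par[10], par[11], par[12], par[13]
    alpha, beta, gamma, zeta, eps = par[14], par[15], par[16], par[17], par[18]
    for i in range(A.shape[0]):
        RA[i] = kon_A * (1.0 + kAB * B[i] ** eps) * Ac - koff_A * A[i] - kAP * P[i] ** alpha * A[i]
        RP[i] = kon_P * Pc - koff_P * P[i] - kPA * A[i] ** beta * P[i]
        RB[i] = kon_B * Bc - koff_B * B[i] - kBA * A[i] ** gamma * B[i] - kBP * P[i] ** zeta * B[i]


@njit(cache=True)
def rd_run(A, P, B, Atot, Ptot, Btot, L, psi, dt, n_steps, par, periodic,
           strict_cyto=True):
    """FTCS integration of the membrane reaction-diffusion system, in place.

    The cytosolic pool is recomputed from mass conservation before every step
    (from the pre-step field).  Negative nodal concentrations produced by the
    explicit step are clamped to zero.  With ``strict_cyto`` a negative
    cytosolic pool aborts with return value 1 (caller must handle); without
    it the negative pool is kept, so net dissociation restores the balance
    (this happens transiently when a shortening cell concentrates its
    membrane pool).  Returns 0 on success.
    """
    n = A.shape[0]
    ds = L / n
    DA, DP, DB = par[0], par[1], par[2]
    cA = DA * dt / ds ** 2
    cP = DP * dt / ds ** 2
    cB = DB * dt / ds ** 2
    An = np.empty(n)
    Pn = np.empty(n)
    Bn = np.empty(n)
    RA = np.empty(n)
    RP = np.empty(n)
    RB = np.empty(n)
    for _ in range(n_steps):
        Ac = Atot - psi * A.mean()
        Pc = Ptot - psi * P.mean()
        Bc = Btot - psi * B.mean()
        if strict_cyto and (Ac < 0.0 or Pc < 0.0 or Bc < 0.0):
            return 1
        reaction_terms(A, P, B, Ac, Pc, Bc, par, RA, RP, RB)
        for i in range(n):
            if periodic:
                ip = i + 1 if i < n - 1 else 0
                im = i - 1 if i > 0 else n - 1
            else:  # reflecting ends (mirror-symmetric half of the closed loop)
                ip = i + 1 if i < n - 1 else n - 1
                im = i - 1 if i > 0 else 0
            An[i] = A[i] + cA * (A[ip] - 2.0 * A[i] + A[im]) + dt * RA[i]
            Pn[i] = P[i] + cP * (P[ip] - 2.0 * P[i] + P[im]) + dt * RP[i]
            Bn[i] = B[i] + cB * (B[ip] - 2.0 * B[i] + B[im]) + dt * RB[i]
        for i in range(n):
            A[i] = An[i] if An[i] > 0.0 else 0.0
            P[i] = Pn[i] if Pn[i] > 0.0 else 0.0
            B[i] = Bn[i] if Bn[i] > 0.0 else 0.0
    return 0


@njit(cache=True)
def rd_run_cells(A, P, B, Atot, Ptot, Btot, L, psi, dt, n_steps, par, periodic,
                 strict_cyto=False):
    """Advance the RD system of every cell: A, P, B are (n_cells, n_nodes)."""
    status = 0
    for c in range(A.shape[0]):
        st = rd_run(A[c], P[c], B[c], Atot[c], Ptot[c], Btot[c], L[c], psi[c],
                    dt, n_steps, par, periodic, strict_cyto)
        if st != 0:
            status = 1
    return status


# ---------------------------------------------------------------------------
# vertex mechanics
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _tri_area(ax, ay, az, bx, by, bz):
    cx = ay * bz - az * by
    cy = az * bx - ax * bz
    cz = ax * by - ay * bx
    return 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)


@njit(cache=True)
def face_area(pos, face):
    """Area of a (possibly non-planar) quad by fan triangulation about its centroid."""
    cx = cy = cz = 0.0
    for k in range(4):
        cx += pos[face[k], 0]
        cy += pos[face[k], 1]
        cz += pos[face[k], 2]
    cx *= 0.25
    cy *= 0.25
    cz *= 0.25
    area = 0.0
    for k in range(4):
        i = face[k]
        j = face[(k + 1) % 4]
        area += _tri_area(
            pos[i, 0] - cx, pos[i, 1] - cy, pos[i, 2] - cz,
            pos[j, 0] - cx, pos[j, 1] - cy, pos[j, 2] - cz,
        )
    return area


@njit(cache=True)
def loop_area(pos, loop):
    """Area of a 6-vertex polygon face by fan triangulation about its centroid."""
    cx = cy = cz = 0.0
    for k in range(6):
        cx += pos[loop[k], 0]
        cy += pos[loop[k], 1]
        cz += pos[loop[k], 2]
    cx /= 6.0
    cy /= 6.0
    cz /= 6.0
    area = 0.0
    for k in range(6):
        i = loop[k]
        j = loop[(k + 1) % 6]
        area += _tri_area(
            pos[i, 0] - cx, pos[i, 1] - cy, pos[i, 2] - cz,
            pos[j, 0] - cx, pos[j, 1] - cy, pos[j, 2] - cz,
        )
    return area


@njit(cache=True)
def loop_perimeter(pos, loop):
    per = 0.0
    for k in range(6):
        i = loop[k]
        j = loop[(k + 1) % 6]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        per += np.sqrt(dx * dx + dy * dy + dz * dz)
    return per


@njit(cache=True, inline="always")
def _tet6(c, p1, p2, p3):
    """Six times the signed volume of tetrahedron (c, p1, p2, p3)."""
    ax = p1[0] - c[0]
    ay = p1[1] - c[1]
    az = p1[2] - c[2]
    bx = p2[0] - c[0]
    by = p2[1] - c[1]
    bz = p2[2] - c[2]
    dx = p3[0] - c[0]
    dy = p3[1] - c[1]
    dz = p3[2] - c[2]
    return (
        ax * (by * dz - bz * dy)
        - ay * (bx * dz - bz * dx)
        + az * (bx * dy - by * dx)
    )


@njit(cache=True)
def cell_volume(pos, ap, bp):
    """Volume of a prismatic cell by tetrahedral decomposition about the cell centroid.

    The surface is fan-triangulated: apical and basal hexagons about their
    centroids, each lateral quad about its own centroid.  All triangles are
    oriented outward; no face planarity is assumed.
    """
    cc = np.zeros(3)
    for k in range(6):
        for d in range(3):
            cc[d] += pos[ap[k], d] + pos[bp[k], d]
    for d in range(3):
        cc[d] /= 12.0

    ca = np.zeros(3)
    cb = np.zeros(3)
    for k in range(6):
        for d in range(3):
            ca[d] += pos[ap[k], d]
            cb[d] += pos[bp[k], d]
    for d in range(3):
        ca[d] /= 6.0
        cb[d] /= 6.0

    vol6 = 0.0
    # apical face: loop is CCW seen from outside (+z side) -> outward fan
    for k in range(6):
        i = ap[k]
        j = ap[(k + 1) % 6]
        vol6 += _tet6(cc, ca, pos[i], pos[j])
    # basal face: reversed winding gives the outward (-z side) orientation
    for k in range(6):
        i = bp[k]
        j = bp[(k + 1) % 6]
        vol6 += _tet6(cc, cb, pos[j], pos[i])
    # lateral quads (a_k, a_k+1, b_k+1, b_k), fanned about the quad centroid
    cq = np.zeros(3)
    for k in range(6):
        k1 = (k + 1) % 6
        q0 = pos[ap[k]]
        q1 = pos[ap[k1]]
        q2 = pos[bp[k1]]
        q3 = pos[bp[k]]
        for d in range(3):
            cq[d] = 0.25 * (q0[d] + q1[d] + q2[d] + q3[d])
        vol6 += _tet6(cc, cq, q1, q0)
        vol6 += _tet6(cc, cq, q2, q1)
        vol6 += _tet6(cc, cq, q3, q2)
        vol6 += _tet6(cc, cq, q0, q3)
    return abs(vol6) / 6.0


@njit(cache=True)
def cell_energy(pos, ap, bp, Ka, Po, lam_b, KV, Vo):
    """Per-cell energy terms: apical perimeter elasticity + basal tension + volume elasticity.

    Lateral-face tension is accounted per registered face, not per cell.
    """
    per = loop_perimeter(pos, ap)
    Ab = loop_area(pos, bp)
    V = cell_volume(pos, ap, bp)
    return Ka * (per - Po) ** 2 + lam_b * Ab + KV * (V - Vo) ** 2


@njit(cache=True)
def total_potential(pos, apical, basal, faces, face_lam, Ka, Po, lam_b, KV, Vo):
    U = 0.0
    for c in range(apical.shape[0]):
        U += cell_energy(pos, apical[c], basal[c], Ka[c], Po[c], lam_b[c], KV[c], Vo[c])
    for f in range(faces.shape[0]):
        U += face_lam[f] * face_area(pos, faces[f])
    return U


@njit(cache=True)
def _local_energy(pos, v, apical, basal, faces, face_lam, Ka, Po, lam_b, KV, Vo,
                  vc_ptr, vc_idx, vf_ptr, vf_idx):
    """Energy of all terms that involve vertex v (cells and faces incident on it)."""
    e = 0.0
    for t in range(vc_ptr[v], vc_ptr[v + 1]):
        c = vc_idx[t]
        e += cell_energy(pos, apical[c], basal[c], Ka[c], Po[c], lam_b[c], KV[c], Vo[c])
    for t in range(vf_ptr[v], vf_ptr[v + 1]):
        f = vf_idx[t]
        e += face_lam[f] * face_area(pos, faces[f])
    return e


@njit(cache=True)
def forces_fd(pos, apical, basal, faces, face_lam, Ka, Po, lam_b, KV, Vo,
              vc_ptr, vc_idx, vf_ptr, vf_idx, step):
    """Central-finite-difference vertex forces F_j = -dU/dr_j.

    Only the energy terms incident on the perturbed vertex are recomputed,
    which makes the cost linear in the number of vertices.
    """
    nV = pos.shape[0]
    F = np.zeros((nV, 3))
    for v in range(nV):
        for d in range(3):
            orig = pos[v, d]
            pos[v, d] = orig + step
            up = _local_energy(pos, v, apical, basal, faces, face_lam, Ka, Po,
                               lam_b, KV, Vo, vc_ptr, vc_idx, vf_ptr, vf_idx)
            pos[v, d] = orig - step
            um = _local_energy(pos, v, apical, basal, faces, face_lam, Ka, Po,
                               lam_b, KV, Vo, vc_ptr, vc_idx, vf_ptr, vf_idx)
            pos[v, d] = orig
            F[v, d] = -(up - um) / (2.0 * step)
    return F


@njit(cache=True)
def relax(pos, apical, basal, faces, face_lam, Ka, Po, lam_b, KV, Vo,
          vc_ptr, vc_idx, vf_ptr, vf_idx, fd_step, dt_over_eta, tol, max_steps,
          zmask):
    """Overdamped gradient descent until max |F| < tol.  Returns steps taken (-1 if not converged)."""
    for it in range(max_steps):
        F = forces_fd(pos, apical, basal, faces, face_lam, Ka, Po, lam_b, KV, Vo,
                      vc_ptr, vc_idx, vf_ptr, vf_idx, fd_step)
        fmax = 0.0
        for v in range(pos.shape[0]):
            if zmask[v]:
                F[v, 2] = 0.0
            for d in range(3):
                a = abs(F[v, d])
                if a > fmax:
                    fmax = a
        if fmax < tol:
            return it
        for v in range(pos.shape[0]):
            for d in range(3):
                pos[v, d] += dt_over_eta * F[v, d]
    return -1


@njit(cache=True)
def forces_fd_subset(pos, verts, apical, basal, faces, face_lam, Ka, Po, lam_b,
                     KV, Vo, vc_ptr, vc_idx, vf_ptr, vf_idx, step):
    """Central-difference forces for the listed vertices only."""
    F = np.zeros((verts.shape[0], 3))
    for t in range(verts.shape[0]):
        v = verts[t]
        for d in range(3):
            orig = pos[v, d]
            pos[v, d] = orig + step
            up = _local_energy(pos, v, apical, basal, faces, face_lam, Ka, Po,
                               lam_b, KV, Vo, vc_ptr, vc_idx, vf_ptr, vf_idx)
            pos[v, d] = orig - step
            um = _local_energy(pos, v, apical, basal, faces, face_lam, Ka, Po,
                               lam_b, KV, Vo, vc_ptr, vc_idx, vf_ptr, vf_idx)
            pos[v, d] = orig
            F[t, d] = -(up - um) / (2.0 * step)
    return F


@njit(cache=True)
def cell_summaries(pos, apical, basal, out):
    """Per-cell geometry: columns a, b, ell, L, A_total, V, psi."""
    nC = apical.shape[0]
    for c in range(nC):
        ap = apical[c]
        bp = basal[c]
        cax = cay = caz = cbx = cby = cbz = 0.0
        for k in range(6):
            cax += pos[ap[k], 0]
            cay += pos[ap[k], 1]
            caz += pos[ap[k], 2]
            cbx += pos[bp[k], 0]
            cby += pos[bp[k], 1]
            cbz += pos[bp[k], 2]
        cax /= 6.0; cay /= 6.0; caz /= 6.0
        cbx /= 6.0; cby /= 6.0; cbz /= 6.0
        a = 0.0
        b = 0.0
        ell = 0.0
        for k in range(6):
            dx = pos[ap[k], 0] - cax; dy = pos[ap[k], 1] - cay; dz = pos[ap[k], 2] - caz
            a += np.sqrt(dx * dx + dy * dy + dz * dz)
            dx = pos[bp[k], 0] - cbx; dy = pos[bp[k], 1] - cby; dz = pos[bp[k], 2] - cbz
            b += np.sqrt(dx * dx + dy * dy + dz * dz)
            dx = pos[ap[k], 0] - pos[bp[k], 0]
            dy = pos[ap[k], 1] - pos[bp[k], 1]
            dz = pos[ap[k], 2] - pos[bp[k], 2]
            ell += np.sqrt(dx * dx + dy * dy + dz * dz)
        a /= 6.0; b /= 6.0; ell /= 6.0
        A = loop_area(pos, ap) + loop_area(pos, bp)
        face = np.empty(4, dtype=np.int64)
        for k in range(6):
            k1 = (k + 1) % 6
            face[0] = ap[k]; face[1] = ap[k1]; face[2] = bp[k1]; face[3] = bp[k]
            A += face_area(pos, face)
        V = cell_volume(pos, ap, bp)
        out[c, 0] = a
        out[c, 1] = b
        out[c, 2] = ell
        out[c, 3] = a + b + ell
        out[c, 4] = A
        out[c, 5] = V
        out[c, 6] = A / V
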