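"""Numba-compiled inner loops of the Cellular-Potts engine.

These kernels are the single source of truth for the incremental energy
change of a pixel copy: the public ``delta_h`` and the Monte-Carlo sweep both
call ``attempt_delta_h``, so the audited formula and the hot path cannot
drift apart.

Convention: a copy attempt takes the index at source site ``y`` and writes it
over the destination neighbor ``z``.  Index 0 is medium; medium has no
volume/surface constraint and does not chemotax.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _contact_j(a, b, j_cm, j_cc):
    if a == b:
        return 0.0
    if a > 0 and b > 0:
        return j_cc
    return j_cm


@njit(cache=True)
def attempt_delta_h(sigma, field, vol, surf, y0, y1, z0, z1,
                    lam_v, v_t, lam_s, s_t, s_scale, j_cm, j_cc,
                    lam_chem, s_sat, c_off, s_off):
    """Energy change of copying sigma[y] onto neighbor z.

    Returns (delta_h, dS_source_cell, dS_dest_cell); the two boundary-count
    increments are reused by the update path on acceptance.  Only the source
    and destination cells' surface counts change: a third cell adjacent to z
    keeps every heterotypic contact because the new index still differs from
    its own.
    """
    H, W = sigma.shape
    a = sigma[y0, y1]
    b = sigma[z0, z1]

    dh = 0.0
    # Contact term: every neighbor pair involving z, counted once.
    for m in range(c_off.shape[0]):
        n0 = (z0 + c_off[m, 0]) % H
        n1 = (z1 + c_off[m, 1]) % W
        s_n = sigma[n0, n1]
        dh += _contact_j(a, s_n, j_cm, j_cc) - _contact_j(b, s_n, j_cm, j_cc)

    # Volume constraint (quadratic, cells only).
    if a > 0:
        va = vol[a]
        dh += lam_v * ((va + 1.0 - v_t) ** 2 - (va - v_t) ** 2)
    if b > 0:
        vb = vol[b]
        dh += lam_v * ((vb - 1.0 - v_t) ** 2 - (vb - v_t) ** 2)

    # Surface constraint on the scaled boundary-contact count.
    n_same_a = 0
    n_same_b = 0
    for m in range(s_off.shape[0]):
        n0 = (z0 + s_off[m, 0]) % H
        n1 = (z1 + s_off[m, 1]) % W
        s_n = sigma[n0, n1]
        if s_n == a:
            n_same_a += 1
        if s_n == b:
            n_same_b += 1
    zs = s_off.shape[0]
    d_s_a = zs - 2 * n_same_a
    d_s_b = 2 * n_same_b - zs
    if a > 0:
        sa = s_scale * surf[a]
        dh += lam_s * ((sa + s_scale * d_s_a - s_t) ** 2 - (sa - s_t) ** 2)
    if b > 0:
        sb = s_scale * surf[b]
        dh += lam_s * ((sb + s_scale * d_s_b - s_t) ** 2 - (sb - s_t) ** 2)

    # Saturating chemotaxis, applied when the invading index is a cell:
    # moving up-gradient lowers the energy.
    if a > 0:
        cd = field[z0, z1]
        cs = field[y0, y1]
        dh += -lam_chem * (cd / (s_sat * cd + 1.0) - cs / (s_sat * cs + 1.0))

    return dh, d_s_a, d_s_b


@njit(cache=True)
def run_attempts(sigma, field, vol, surf, sites, neis, us,
                 lam_v, v_t, lam_s, s_t, s_scale, j_cm, j_cc,
                 lam_chem, s_sat, temperature, c_off, s_off):
    """Execute a pre-drawn sequence of copy attempts in place.

    ``sites``/``neis``/``us`` hold the flat source-site index, the neighbor
    offset index and the acceptance uniform for each attempt (one triple is
    consumed per attempt whether or not it is a no-op).  Returns the number
    of accepted copies.
    """
    H, W = sigma.shape
    accepted = 0
    for t in range(sites.shape[0]):
        y0 = sites[t] // W
        y1 = sites[t] % W
        o = neis[t]
        z0 = (y0 + c_off[o, 0]) % H
        z1 = (y1 + c_off[o, 1]) % W
        a = sigma[y0, y1]
        b = sigma[z0, z1]
        if a == b:
            continue
        dh, d_s_a, d_s_b = attempt_delta_h(
            sigma, field, vol, surf, y0, y1, z0, z1,
            lam_v, v_t, lam_s, s_t, s_scale, j_cm, j_cc,
            lam_chem, s_sat, c_off, s_off)
        if dh <= 0.0 or us[t] < math.exp(-dh / temperature):
            sigma[z0, z1] = a
            if a > 0:
                vol[a] += 1
                surf[a] += d_s_a
            if b > 0:
                vol[b] -= 1
                surf[b] += d_s_b
            accepted += 1
    return accepted


@njit(cache=True)
def pde_steps(field, sigma, d_diff, k_decay, secretion, dt, n_sub):
    """n_sub forward-Euler secretion-diffusion-decay substeps, periodic 5-point
    Laplacian, negative concentrations clipped to zero.  Returns the field
    (a new array; the input is not modified)."""
    H, W = field.shape
    cur = field.copy()
    out = np.empty_like(cur)
    for _ in range(n_sub):
        for i in range(H):
            im = H - 1 if i == 0 else i - 1
            ip = 0 if i == H - 1 else i + 1
            for j in range(W):
                jm = W - 1 if j == 0 else j - 1
                jp = 0 if j == W - 1 else j + 1
                c = cur[i, j]
                lap = cur[im, j] + cur[ip, j] + cur[i, jm] + cur[i, jp] - 4.0 * c
                v = c + dt * (d_diff * lap - k_decay * c)
                if sigma[i, j] > 0:
                    v += dt * secretion
                out[i, j] = v if v > 0.0 else 0.0
        cur, out = out, cur
    return cur
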