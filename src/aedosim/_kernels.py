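"""Numba-compiled inner loops of the FDTD solver.

The update kernels implement the standard Yee leapfrog with a
conductivity term (semi-implicit) and a stretched-coordinate perfectly
matched layer in convolutional form: auxiliary psi accumulators are
touched only where the layer's grading coefficient is nonzero, so the
interior pays no PML cost.
"""

import numba
import numpy as np

__all__ = ["update_e", "update_h", "absorbed_power_instantaneous", "max_abs_e"]


@numba.njit(cache=True, fastmath=True)
def update_e(
    ex, ey, ez, hx, hy, hz,
    psi_exy, psi_exz, psi_eyz, psi_eyx, psi_ezx, psi_ezy,
    ca_x, cb_x, ca_y, cb_y, ca_z, cb_z,
    be_x, ce_x, be_y, ce_y, be_z, ce_z,
    inv_h,
):
    nx, ny, nz = ex.shape
    for i in range(nx):
        for j in range(1, ny):
            bey = be_y[j]
            cey = ce_y[j]
            for k in range(1, nz):
                dhz = (hz[i, j, k] - hz[i, j - 1, k]) * inv_h
                dhy = (hy[i, j, k] - hy[i, j, k - 1]) * inv_h
                if cey != 0.0:
                    p = bey * psi_exy[i, j, k] + cey * dhz
                    psi_exy[i, j, k] = p
                    dhz += p
                if ce_z[k] != 0.0:
                    p = be_z[k] * psi_exz[i, j, k] + ce_z[k] * dhy
                    psi_exz[i, j, k] = p
                    dhy += p
                ex[i, j, k] = ca_x[i, j, k] * ex[i, j, k] + cb_x[i, j, k] * (dhz - dhy)
    for i in range(1, nx):
        bexi = be_x[i]
        cexi = ce_x[i]
        for j in range(ny):
            for k in range(1, nz):
                dhx = (hx[i, j, k] - hx[i, j, k - 1]) * inv_h
                dhz = (hz[i, j, k] - hz[i - 1, j, k]) * inv_h
                if ce_z[k] != 0.0:
                    p = be_z[k] * psi_eyz[i, j, k] + ce_z[k] * dhx
                    psi_eyz[i, j, k] = p
                    dhx += p
                if cexi != 0.0:
                    p = bexi * psi_eyx[i, j, k] + cexi * dhz
                    psi_eyx[i, j, k] = p
                    dhz += p
                ey[i, j, k] = ca_y[i, j, k] * ey[i, j, k] + cb_y[i, j, k] * (dhx - dhz)
    for i in range(1, nx):
        bexi = be_x[i]
        cexi = ce_x[i]
        for j in range(1, ny):
            bey = be_y[j]
            cey = ce_y[j]
            for k in range(nz):
                dhy = (hy[i, j, k] - hy[i - 1, j, k]) * inv_h
                dhx = (hx[i, j, k] - hx[i, j - 1, k]) * inv_h
                if cexi != 0.0:
                    p = bexi * psi_ezx[i, j, k] + cexi * dhy
                    psi_ezx[i, j, k] = p
                    dhy += p
                if cey != 0.0:
                    p = bey * psi_ezy[i, j, k] + cey * dhx
                    psi_ezy[i, j, k] = p
                    dhx += p
                ez[i, j, k] = ca_z[i, j, k] * ez[i, j, k] + cb_z[i, j, k] * (dhy - dhx)


@numba.njit(cache=True, fastmath=True)
def update_h(
    ex, ey, ez, hx, hy, hz,
    psi_hxy, psi_hxz, psi_hyz, psi_hyx, psi_hzx, psi_hzy,
    bh_x, ch_x, bh_y, ch_y, bh_z, ch_z,
    dt_mu, inv_h,
):
    nx, ny, nz = ex.shape
    for i in range(nx):
        for j in range(ny - 1):
            bhy = bh_y[j]
            chy = ch_y[j]
            for k in range(nz - 1):
                dez = (ez[i, j + 1, k] - ez[i, j, k]) * inv_h
                dey = (ey[i, j, k + 1] - ey[i, j, k]) * inv_h
                if chy != 0.0:
                    p = bhy * psi_hxy[i, j, k] + chy * dez
                    psi_hxy[i, j, k] = p
                    dez += p
                if ch_z[k] != 0.0:
                    p = bh_z[k] * psi_hxz[i, j, k] + ch_z[k] * dey
                    psi_hxz[i, j, k] = p
                    dey += p
                hx[i, j, k] -= dt_mu * (dez - dey)
    for i in range(nx - 1):
        bhxi = bh_x[i]
        chxi = ch_x[i]
        for j in range(ny):
            for k in range(nz - 1):
                dex = (ex[i, j, k + 1] - ex[i, j, k]) * inv_h
                dez = (ez[i + 1, j, k] - ez[i, j, k]) * inv_h
                if ch_z[k] != 0.0:
                    p = bh_z[k] * psi_hyz[i, j, k] + ch_z[k] * dex
                    psi_hyz[i, j, k] = p
                    dex += p
                if chxi != 0.0:
                    p = bhxi * psi_hyx[i, j, k] + chxi * dez
                    psi_hyx[i, j, k] = p
                    dez += p
                hy[i, j, k] -= dt_mu * (dex - dez)
    for i in range(nx - 1):
        bhxi = bh_x[i]
        chxi = ch_x[i]
        for j in range(ny - 1):
            bhy = bh_y[j]
            chy = ch_y[j]
            for k in range(nz):
                dey = (ey[i + 1, j, k] - ey[i, j, k]) * inv_h
                dex = (ex[i, j + 1, k] - ex[i, j, k]) * inv_h
                if chxi != 0.0:
                    p = bhxi * psi_hzx[i, j, k] + chxi * dey
                    psi_hzx[i, j, k] = p
                    dey += p
                if chy != 0.0:
                    p = bhy * psi_hzy[i, j, k] + chy * dex
                    psi_hzy[i, j, k] = p
                    dex += p
                hz[i, j, k] -= dt_mu * (dey - dex)


@numba.njit(cache=True, fastmath=True)
def absorbed_power_instantaneous(ex, ey, ez, ii, jj, kk, sx, sy, sz, cell_volume):
    """sum over listed edges of sigma_c * E_c(t)^2 * h^3 (W)."""
    total = 0.0
    for n in range(ii.size):
        i, j, k = ii[n], jj[n], kk[n]
        total += (
            sx[n] * ex[i, j, k] ** 2
            + sy[n] * ey[i, j, k] ** 2
            + sz[n] * ez[i, j, k] ** 2
        )
    return total * cell_volume


@numba.njit(cache=True, fastmath=True)
def max_abs_e(ex, ey, ez):
    m = 0.0
    for v in (ex, ey, ez):
        fv = v.ravel()
        for n in range(fv.size):
            a = abs(fv[n])
            if a > m:
                m = a
    return m
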