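"""Fused inner-loop kernel for scenario runs.

The module-level operations in :mod:`hydro`, :mod:`transport` and
:mod:`compartments` are the canonical (and tested) definitions of one
coupled step.  For month-long scenario runs the same arithmetic is fused
into a single numba-compiled kernel operating in place on the state
arrays; the pure-numpy loop remains available as a fallback and as a
consistency oracle (the two paths are required to agree by the test
suite).

The kernel mirrors, in order: the boundary-concentration override, upwind
face fluxes shared by continuity and tracer mass, the water-level update
with inflow volume source and Dirichlet tide override, momentum with
upwind advection / Coriolis / eddy viscosity / semi-implicit quadratic
friction, concentration recovery ``c = m / h``, direct source injection,
and the exact affine compartment exchange on wet interior cells.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def coupled_step(zeta, u, v, m, c, Sl, Ss, Pl,
                 bed, nman, active, bcmask, interior, age,
                 dt, dx, dy, g, f, K, rho, h_dry, Dx, Dy, c_bc,
                 tide_cells, tide_level, inflow_cells, q_cell,
                 src_cells, src_grams,
                 M3, w3, gam_coef, exchange_on):
    ny, nx = zeta.shape
    A = dx * dy
    exported = 0.0

    # imposed concentration in tide-boundary cells (inflow condition)
    for nb in range(tide_cells.shape[0]):
        j, i = tide_cells[nb, 0], tide_cells[nb, 1]
        h0 = bed[j, i] + zeta[j, i]
        if h0 < 0.0:
            h0 = 0.0
        c[j, i] = c_bc
        m[j, i] = c_bc * h0

    dz = np.zeros((ny, nx))
    dm = np.zeros((ny, nx))

    # x-directed interior faces
    for j in range(ny):
        for ii in range(1, nx):
            iL = ii - 1
            if not (active[j, iL] and active[j, ii]):
                continue
            zbL = -bed[j, iL]
            zbR = -bed[j, ii]
            zbm = zbL if zbL > zbR else zbR
            zl = zeta[j, iL]
            zr = zeta[j, ii]
            zmx = zl if zl > zr else zr
            hf = zmx - zbm
            if hf <= h_dry:
                continue
            uf = u[j, ii]
            zup = zl if uf > 0.0 else zr
            hq = zup - zbm
            if hq < 0.0:
                hq = 0.0
            F = uf * hq * dy
            cup = c[j, iL] if F > 0.0 else c[j, ii]
            Mf = F * cup
            bcL = bcmask[j, iL]
            bcR = bcmask[j, ii]
            if not (bcL or bcR):
                Mf += -Dx * hf * (c[j, ii] - c[j, iL]) / dx * dy
            dz[j, ii] += F
            dz[j, iL] -= F
            dm[j, ii] += Mf
            dm[j, iL] -= Mf
            if bcR and not bcL:
                exported += Mf * dt
            elif bcL and not bcR:
                exported -= Mf * dt

    # y-directed interior faces
    for jj in range(1, ny):
        jL = jj - 1
        for i in range(nx):
            if not (active[jL, i] and active[jj, i]):
                continue
            zbL = -bed[jL, i]
            zbR = -bed[jj, i]
            zbm = zbL if zbL > zbR else zbR
            zl = zeta[jL, i]
            zr = zeta[jj, i]
            zmx = zl if zl > zr else zr
            hf = zmx - zbm
            if hf <= h_dry:
                continue
            vf = v[jj, i]
            zup = zl if vf > 0.0 else zr
            hq = zup - zbm
            if hq < 0.0:
                hq = 0.0
            F = vf * hq * dx
            cup = c[jL, i] if F > 0.0 else c[jj, i]
            Mf = F * cup
            bcL = bcmask[jL, i]
            bcR = bcmask[jj, i]
            if not (bcL or bcR):
                Mf += -Dy * hf * (c[jj, i] - c[jL, i]) / dy * dx
            dz[jj, i] += F
            dz[jL, i] -= F
            dm[jj, i] += Mf
            dm[jL, i] -= Mf
            if bcR and not bcL:
                exported += Mf * dt
            elif bcL and not bcR:
                exported -= Mf * dt

    # continuity, inflow volume source, tide override
    zeta_new = np.empty((ny, nx))
    for j in range(ny):
        for i in range(nx):
            zeta_new[j, i] = zeta[j, i] + dt * dz[j, i] / A
            m[j, i] += dt * dm[j, i] / A
    for nb in range(inflow_cells.shape[0]):
        j, i = inflow_cells[nb, 0], inflow_cells[nb, 1]
        zeta_new[j, i] += q_cell * dt / A
    for nb in range(tide_cells.shape[0]):
        j, i = tide_cells[nb, 0], tide_cells[nb, 1]
        zeta_new[j, i] = tide_level

    # u momentum
    u_new = np.zeros((ny, nx + 1))
    for j in range(ny):
        for ii in range(1, nx):
            iL = ii - 1
            if not (active[j, iL] and active[j, ii]):
                continue
            zbL = -bed[j, iL]
            zbR = -bed[j, ii]
            zbm = zbL if zbL > zbR else zbR
            zl = zeta_new[j, iL]
            zr = zeta_new[j, ii]
            zmx = zl if zl > zr else zr
            hf = zmx - zbm
            if hf <= h_dry:
                continue
            U = u[j, ii]
            vcL = 0.5 * (v[j, iL] + v[j + 1, iL])
            vcR = 0.5 * (v[j, ii] + v[j + 1, ii])
            vbar = 0.5 * (vcL + vcR)
            dzdx = (zr - zl) / dx
            uL2 = u[j, ii - 1]
            uR2 = u[j, ii + 1]
            if U > 0.0:
                adv_x = U * (U - uL2) / dx
            else:
                adv_x = U * (uR2 - U) / dx
            uUp = u[j - 1, ii] if j > 0 else U
            uDn = u[j + 1, ii] if j < ny - 1 else U
            if vbar > 0.0:
                adv_y = vbar * (U - uUp) / dy
            else:
                adv_y = vbar * (uDn - U) / dy
            lap = (uL2 - 2.0 * U + uR2) / (dx * dx) + (uUp - 2.0 * U + uDn) / (dy * dy)
            h_eff = hf if hf > h_dry else h_dry
            nf = 0.5 * (nman[j, iL] + nman[j, ii])
            rhs = -g * dzdx - adv_x - adv_y + f * vbar + K * lap
            speed = (U * U + vbar * vbar) ** 0.5
            fric = dt * g * nf * nf * speed / h_eff ** (4.0 / 3.0)
            u_new[j, ii] = (U + dt * rhs) / (1.0 + fric)

    # v momentum
    v_new = np.zeros((ny + 1, nx))
    for jj in range(1, ny):
        jL = jj - 1
        for i in range(nx):
            if not (active[jL, i] and active[jj, i]):
                continue
            zbL = -bed[jL, i]
            zbR = -bed[jj, i]
            zbm = zbL if zbL > zbR else zbR
            zl = zeta_new[jL, i]
            zr = zeta_new[jj, i]
            zmx = zl if zl > zr else zr
            hf = zmx - zbm
            if hf <= h_dry:
                continue
            V = v[jj, i]
            ucL = 0.5 * (u[jL, i] + u[jL, i + 1])
            ucR = 0.5 * (u[jj, i] + u[jj, i + 1])
            ubar = 0.5 * (ucL + ucR)
            dzdy = (zr - zl) / dy
            vD2 = v[jj - 1, i]
            vU2 = v[jj + 1, i]
            if V > 0.0:
                adv_y = V * (V - vD2) / dy
            else:
                adv_y = V * (vU2 - V) / dy
            vLt = v[jj, i - 1] if i > 0 else V
            vRt = v[jj, i + 1] if i < nx - 1 else V
            if ubar > 0.0:
                adv_x = ubar * (V - vLt) / dx
            else:
                adv_x = ubar * (vRt - V) / dx
            lap = (vLt - 2.0 * V + vRt) / (dx * dx) + (vD2 - 2.0 * V + vU2) / (dy * dy)
            h_eff = hf if hf > h_dry else h_dry
            nf = 0.5 * (nman[jL, i] + nman[jj, i])
            rhs = -g * dzdy - adv_x - adv_y - f * ubar + K * lap
            speed = (V * V + ubar * ubar) ** 0.5
            fric = dt * g * nf * nf * speed / h_eff ** (4.0 / 3.0)
            v_new[jj, i] = (V + dt * rhs) / (1.0 + fric)

    # concentration recovery; dry cells pond their mass (faces are closed)
    for j in range(ny):
        for i in range(nx):
            if not active[j, i]:
                continue
            hn = bed[j, i] + zeta_new[j, i]
            if bcmask[j, i]:
                c[j, i] = c_bc
            elif hn > 1e-12:
                c[j, i] = m[j, i] / hn
            else:
                c[j, i] = 0.0

    # direct source injection (ponded in the mass field while dry)
    for ns in range(src_cells.shape[0]):
        grams = src_grams[ns]
        if grams <= 0.0:
            continue
        j, i = src_cells[ns, 0], src_cells[ns, 1]
        m[j, i] += grams / A
        hn = bed[j, i] + zeta_new[j, i]
        if hn > h_dry:
            c[j, i] += grams / (hn * A)

    # compartment exchange on wet interior cells (exact affine update)
    if exchange_on:
        for j in range(ny):
            for i in range(nx):
                if not interior[j, i]:
                    continue
                hn = bed[j, i] + zeta_new[j, i]
                if hn <= h_dry:
                    continue
                a = age[j, i]
                x0 = Sl[j, i]
                x1 = Ss[j, i]
                x2 = Pl[j, i]
                cc = c[j, i]
                y0 = M3[a, 0, 0] * x0 + M3[a, 0, 1] * x1 + M3[a, 0, 2] * x2 + w3[a, 0] * cc
                y1 = M3[a, 1, 0] * x0 + M3[a, 1, 1] * x1 + M3[a, 1, 2] * x2 + w3[a, 1] * cc
                y2 = M3[a, 2, 0] * x0 + M3[a, 2, 1] * x1 + M3[a, 2, 2] * x2 + w3[a, 2] * cc
                dmass = (y0 + y1 + y2 - x0 - x1 - x2) * gam_coef
                m[j, i] -= dmass
                c[j, i] = m[j, i] / hn
                Sl[j, i] = y0
                Ss[j, i] = y1
                Pl[j, i] = y2

    for j in range(ny):
        for i in range(nx):
            zeta[j, i] = zeta_new[j, i]
    for j in range(ny):
        for i in range(nx + 1):
            u[j, i] = u_new[j, i]
    for j in range(ny + 1):
        for i in range(nx):
            v[j, i] = v_new[j, i]

    return exported
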