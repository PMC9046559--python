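"""Numba kernels for the mapped-grid fractional-step flow solver.

Discretization summary
----------------------
The vessel interior is mapped onto a rectangle with axial coordinate ``x``
(uniform spacing ``dx``) and transverse coordinate ``eta = y / r(x)`` in
[0, 1] (0 = centerline/axis, 1 = wall), where ``r(x)`` is the local radius
(axisymmetric) or half-height (planar).  Chain rule:

    d/dx|phys = d/dx|eta - (eta r'/r) d/deta,      d/dy = (1/r) d/deta.

Staggered layout in computational space: axial velocity ``u`` at
(x-face, eta-center), transverse velocity ``v`` at (x-center, eta-face),
pressure at cell centers.  Advection uses a third-order upwind-biased
scheme on the mapped advecting velocities (u, eta_dot); the full
variable-viscosity stress divergence is evaluated explicitly and stabilized
by a Douglas-Gunn ADI solve of the principal (grid-aligned) diffusion plus
first-order upwind advection of the increment.  The projection kernels
(``divergence``, ``correct``) define the discrete operators that
solver._Domain composes into the exact sparse projection matrix.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# rheology (scalar, inlined)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always", fastmath=True)
def _quemada(g, mu_p, k0, kinf, gc, H, gfloor):
    gg = g if g > gfloor else gfloor
    s = np.sqrt(gg / gc)
    k = (k0 + kinf * s) / (1.0 + s)
    b = 1.0 - 0.5 * k * H
    return mu_p / (b * b)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always", fastmath=True)
def _dudeta(u, i, j, ec, Ny):
    """Nonuniform central eta-derivative of u (x-face, eta-center field).

    Mirror condition at the centerline (symmetry), wall value 0 at eta = 1.
    """
    if j == 0:
        if Ny == 1:
            return (0.0 - u[i, 0]) / (1.0 - ec[0])
        sm = 2.0 * ec[0]
        sp = ec[1] - ec[0]
        um = u[i, 0]
        up = u[i, 1]
    elif j == Ny - 1:
        sm = ec[j] - ec[j - 1]
        sp = 1.0 - ec[j]
        um = u[i, j - 1]
        up = 0.0
    else:
        sm = ec[j] - ec[j - 1]
        sp = ec[j + 1] - ec[j]
        um = u[i, j - 1]
        up = u[i, j + 1]
    u0 = u[i, j]
    return (sm / (sp * (sm + sp))) * (up - u0) + (sp / (sm * (sm + sp))) * (u0 - um)


@njit(cache=True, inline="always", fastmath=True)
def _deta_center(f, i, j, ec, Ny):
    """Nonuniform central eta-derivative of a cell-centered field (mirror/one-sided)."""
    if j == 0:
        if Ny == 1:
            return 0.0
        return (f[i, 1] - f[i, 0]) / (ec[1] - ec[0])
    if j == Ny - 1:
        return (f[i, j] - f[i, j - 1]) / (ec[j] - ec[j - 1])
    sm = ec[j] - ec[j - 1]
    sp = ec[j + 1] - ec[j]
    return (sm / (sp * (sm + sp))) * (f[i, j + 1] - f[i, j]) + \
        (sp / (sm * (sm + sp))) * (f[i, j] - f[i, j - 1])


@njit(cache=True, fastmath=True)
def _thomas(a, b, c, d, n):
    """In-place Thomas solve of a tridiagonal system; result left in d."""
    for k in range(1, n):
        m = a[k] / b[k - 1]
        b[k] -= m * c[k - 1]
        d[k] -= m * d[k - 1]
    d[n - 1] /= b[n - 1]
    for k in range(n - 2, -1, -1):
        d[k] = (d[k] - c[k] * d[k + 1]) / b[k]


# ---------------------------------------------------------------------------
# viscosity / shear-rate field update
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def update_viscosity(u, v, muc, mun, gdc, dx, ec, ef, dec, rf, rc, drf, drc,
                     axisym, model, mu_newt, mu_p, k0, kinf, gc, H, gfloor):
    Nx = rc.shape[0]
    Ny = ec.shape[0]
    # center strain components
    for i in range(Nx):
        for j in range(Ny):
            dde = 0.5 * (_dudeta(u, i, j, ec, Ny) + _dudeta(u, i + 1, j, ec, Ny))
            dudx = (u[i + 1, j] - u[i, j]) / dx - (ec[j] * drc[i] / rc[i]) * dde
            dvdy = (v[i, j + 1] - v[i, j]) / (rc[i] * dec[j])
            # shear part at center: average the four surrounding corner values
            dudy = 0.25 * (_corner_dudy(u, i, j, ec, rf, Ny) +
                           _corner_dudy(u, i + 1, j, ec, rf, Ny) +
                           _corner_dudy(u, i, j + 1, ec, rf, Ny) +
                           _corner_dudy(u, i + 1, j + 1, ec, rf, Ny))
            dvdx = _center_dvdx(v, i, j, dx, ec, ef, rc, drc, Nx, Ny)
            hoop = 0.0
            if axisym == 1:
                vc = 0.5 * (v[i, j] + v[i, j + 1])
                hoop = vc / (ec[j] * rc[i])
            g2 = 2.0 * (dudx * dudx + dvdy * dvdy + hoop * hoop) + (dudy + dvdx) ** 2
            g = np.sqrt(g2)
            gdc[i, j] = g
            if model == 0:
                muc[i, j] = mu_newt
            else:
                muc[i, j] = _quemada(g, mu_p, k0, kinf, gc, H, gfloor)
    # corner viscosity: evaluate the law at the corner shear rate; near the
    # wall that is |du/dy| (where it controls the wall flux), elsewhere the
    # interpolated cell invariant dominates
    for i in range(Nx + 1):
        for j in range(Ny + 1):
            if model == 0:
                mun[i, j] = mu_newt
                continue
            g = abs(_corner_dudy(u, i, j, ec, rf, Ny))
            il = i - 1 if i > 0 else 0
            ir = i if i < Nx else Nx - 1
            jl = j - 1 if j > 0 else 0
            jr = j if j < Ny else Ny - 1
            gn = 0.25 * (gdc[il, jl] + gdc[il, jr] + gdc[ir, jl] + gdc[ir, jr])
            if gn > g:
                g = gn
            mun[i, j] = _quemada(g, mu_p, k0, kinf, gc, H, gfloor)


@njit(cache=True, inline="always", fastmath=True)
def _corner_dudy(u, i, j, ec, rf, Ny):
    """du/dy at corner (x-face i, eta-face j); symmetry at axis, no-slip wall."""
    if j == 0:
        return 0.0
    if j == Ny:
        return (0.0 - u[i, Ny - 1]) / (rf[i] * (1.0 - ec[Ny - 1]))
    return (u[i, j] - u[i, j - 1]) / (rf[i] * (ec[j] - ec[j - 1]))


@njit(cache=True, inline="always", fastmath=True)
def _vface_deta(v, i, j, ef, Ny):
    """eta-derivative of v (x-center, eta-face field) at eta-face j."""
    if j == 0:
        return (v[i, 1] - v[i, 0]) / (ef[1] - ef[0])
    if j == Ny:
        return (v[i, Ny] - v[i, Ny - 1]) / (ef[Ny] - ef[Ny - 1])
    return (v[i, j + 1] - v[i, j - 1]) / (ef[j + 1] - ef[j - 1])


@njit(cache=True, inline="always", fastmath=True)
def _center_dvdx(v, i, j, dx, ec, ef, rc, drc, Nx, Ny):
    """dv/dx (physical) interpolated to cell center (i, j)."""
    # dv/dx at the two bounding eta-faces, then average to the center
    tot = 0.0
    for jj in range(j, j + 2):
        if i == 0:
            dvdxi = (v[1, jj] - v[0, jj]) / dx if Nx > 1 else 0.0
        elif i == Nx - 1:
            dvdxi = (v[i, jj] - v[i - 1, jj]) / dx
        else:
            dvdxi = (v[i + 1, jj] - v[i - 1, jj]) / (2.0 * dx)
        dvde = _vface_deta(v, i, jj, ef, Ny)
        dvdxi -= (ef[jj] * drc[i] / rc[i]) * dvde
        tot += dvdxi
    return 0.5 * tot


# ---------------------------------------------------------------------------
# explicit RHS: advection + full viscous stress divergence + pressure gradient
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def explicit_rhs(u, v, p, muc, mun, rho, dt, dx, ec, ef, dec, rf, rc, drf, drc,
                 axisym, rhs_u, rhs_v):
    Nx = rc.shape[0]
    Ny = ec.shape[0]

    # --- stress components ---
    txx = np.empty((Nx, Ny))
    tyy = np.empty((Nx, Ny))
    tth = np.zeros((Nx, Ny))
    for i in range(Nx):
        for j in range(Ny):
            dde = 0.5 * (_dudeta(u, i, j, ec, Ny) + _dudeta(u, i + 1, j, ec, Ny))
            dudx = (u[i + 1, j] - u[i, j]) / dx - (ec[j] * drc[i] / rc[i]) * dde
            dvdy = (v[i, j + 1] - v[i, j]) / (rc[i] * dec[j])
            txx[i, j] = 2.0 * muc[i, j] * dudx
            tyy[i, j] = 2.0 * muc[i, j] * dvdy
            if axisym == 1:
                vc = 0.5 * (v[i, j] + v[i, j + 1])
                tth[i, j] = 2.0 * muc[i, j] * vc / (ec[j] * rc[i])

    txy = np.empty((Nx + 1, Ny + 1))
    for i in range(Nx + 1):
        for j in range(Ny + 1):
            dudy = _corner_dudy(u, i, j, ec, rf, Ny)
            if j == 0 or j == Ny:
                dvdx = 0.0
            elif i == 0:
                dvdx = 2.0 * v[0, j] / dx - (ef[j] * drf[0] / rf[0]) * _vface_deta(v, 0, j, ef, Ny)
            elif i == Nx:
                dvdx = 0.0 - (ef[j] * drf[Nx] / rf[Nx]) * _vface_deta(v, Nx - 1, j, ef, Ny)
            else:
                dvde = 0.5 * (_vface_deta(v, i - 1, j, ef, Ny) + _vface_deta(v, i, j, ef, Ny))
                dvdx = (v[i, j] - v[i - 1, j]) / dx - (ef[j] * drf[i] / rf[i]) * dvde
            txy[i, j] = mun[i, j] * (dudy + dvdx)

    # --- u equation: interior x-faces i = 1..Nx-1 ---
    for i in range(1, Nx):
        for j in range(Ny):
            # advection in mapped coordinates; third-order upwind-biased in x
            ax = u[i, j]
            vbar = 0.25 * (v[i - 1, j] + v[i - 1, j + 1] + v[i, j] + v[i, j + 1])
            ae = (vbar - u[i, j] * ec[j] * drf[i]) / rf[i]
            dudxi = _dx_upwind3(u, i, j, dx, Nx + 1, ax)
            dude = _dudeta(u, i, j, ec, Ny)
            adv = ax * dudxi + ae * dude

            # pressure gradient (full metric form)
            dpde = 0.5 * (_deta_center(p, i - 1, j, ec, Ny) + _deta_center(p, i, j, ec, Ny))
            gpx = (p[i, j] - p[i - 1, j]) / dx - (ec[j] * drf[i] / rf[i]) * dpde

            # viscous: d(txx)/dx + (1/w) d(w txy)/dy at the u-node
            dtde = 0.5 * (_deta_center(txx, i - 1, j, ec, Ny) + _deta_center(txx, i, j, ec, Ny))
            dtxxdx = (txx[i, j] - txx[i - 1, j]) / dx - (ec[j] * drf[i] / rf[i]) * dtde
            if axisym == 1:
                tang = (ef[j + 1] * txy[i, j + 1] - ef[j] * txy[i, j]) / (ec[j] * rf[i] * dec[j])
            else:
                tang = (txy[i, j + 1] - txy[i, j]) / (rf[i] * dec[j])
            rhs_u[i, j] = dt * (-adv + (-gpx + dtxxdx + tang) / rho)

    # --- v equation: interior eta-faces j = 1..Ny-1 ---
    for i in range(Nx):
        for j in range(1, Ny):
            ubar = 0.25 * (u[i, j - 1] + u[i, j] + u[i + 1, j - 1] + u[i + 1, j])
            ax = ubar
            ae = (v[i, j] - ubar * ef[j] * drc[i]) / rc[i]
            if i == 0:
                dvdxi = (v[1, j] - v[0, j]) / dx if Nx > 1 else 0.0
            elif i == Nx - 1:
                dvdxi = (v[i, j] - v[i - 1, j]) / dx
            else:
                dvdxi = _dx_upwind3(v, i, j, dx, Nx, ax)
            sm = ef[j] - ef[j - 1]
            sp = ef[j + 1] - ef[j]
            dvde = (sm / (sp * (sm + sp))) * (v[i, j + 1] - v[i, j]) + \
                (sp / (sm * (sm + sp))) * (v[i, j] - v[i, j - 1])
            adv = ax * dvdxi + ae * dvde

            gpy = (p[i, j] - p[i, j - 1]) / (rc[i] * (ec[j] - ec[j - 1]))

            # viscous: d(txy)/dx + (1/w) d(w tyy)/dy  (- hoop term, axisym)
            dtde_l = (txy[i, j + 1] - txy[i, j - 1]) / (ef[j + 1] - ef[j - 1])
            dtde_r = (txy[i + 1, j + 1] - txy[i + 1, j - 1]) / (ef[j + 1] - ef[j - 1])
            dtxydx = (txy[i + 1, j] - txy[i, j]) / dx - \
                (ef[j] * drc[i] / rc[i]) * 0.5 * (dtde_l + dtde_r)
            if axisym == 1:
                norm = (ec[j] * tyy[i, j] - ec[j - 1] * tyy[i, j - 1]) / \
                    (ef[j] * rc[i] * (ec[j] - ec[j - 1]))
                norm -= 0.5 * (tth[i, j - 1] + tth[i, j]) / (ef[j] * rc[i])
            else:
                norm = (tyy[i, j] - tyy[i, j - 1]) / (rc[i] * (ec[j] - ec[j - 1]))
            rhs_v[i, j] = dt * (-adv + (-gpy + dtxydx + norm) / rho)


@njit(cache=True, inline="always", fastmath=True)
def _dx_upwind3(f, i, j, dx, nI, a):
    """Third-order upwind-biased x-derivative of f[:, j] at row i.

    Falls back to second-order central (or one-sided) where the upwind
    stencil leaves the domain.  The explicit use of this scheme is stabilized
    by the first-order upwind advection of the increment inside the ADI
    solves (deferred correction).
    """
    if a >= 0.0:
        if i >= 2:
            return (2.0 * f[i + 1, j] + 3.0 * f[i, j] - 6.0 * f[i - 1, j]
                    + f[i - 2, j]) / (6.0 * dx)
        return (f[i + 1, j] - f[i - 1, j]) / (2.0 * dx)
    if i <= nI - 3:
        return -(2.0 * f[i - 1, j] + 3.0 * f[i, j] - 6.0 * f[i + 1, j]
                 + f[i + 2, j]) / (6.0 * dx)
    return (f[i + 1, j] - f[i - 1, j]) / (2.0 * dx)


# ---------------------------------------------------------------------------
# ADI solves of the principal diffusion operator
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def adi_u(u, v, muc, mun, rhs_u, rho, dt, dx, ec, ef, dec, rf, rc, drf, axisym):
    """Solve (I - dt Ax)(I - dt Ae) w = rhs_u and apply u += w (interior faces).

    Ax/Ae hold the principal grid-aligned diffusion plus first-order upwind
    advection of the increment (deferred-correction stabilization of the
    higher-order explicit advection in the RHS).
    """
    Nx = rc.shape[0]
    Ny = ec.shape[0]
    n = Nx - 1
    if n < 1:
        return
    a = np.empty(max(Nx, Ny) + 1)
    b = np.empty(max(Nx, Ny) + 1)
    c = np.empty(max(Nx, Ny) + 1)
    d = np.empty(max(Nx, Ny) + 1)
    w = np.empty((Nx + 1, Ny))
    # stage 1: x-direction, rows j
    for j in range(Ny):
        for k in range(n):
            i = k + 1
            if axisym == 1:
                Wu = ec[j] * rf[i] * rf[i]
                cW = ec[j] * rc[i - 1] * rc[i - 1] * 2.0 * muc[i - 1, j]
                cE = ec[j] * rc[i] * rc[i] * 2.0 * muc[i, j]
            else:
                Wu = rf[i]
                cW = rc[i - 1] * 2.0 * muc[i - 1, j]
                cE = rc[i] * 2.0 * muc[i, j]
            fw = dt * cW / (rho * Wu * dx * dx)
            fe = dt * cE / (rho * Wu * dx * dx)
            ax = u[i, j]
            upw = dt * (ax if ax > 0.0 else 0.0) / dx
            upe = dt * (-ax if ax < 0.0 else 0.0) / dx
            a[k] = -fw - upw
            c[k] = -fe - upe
            b[k] = 1.0 + fw + fe + upw + upe
            d[k] = rhs_u[i, j]
        _thomas(a, b, c, d, n)
        for k in range(n):
            w[k + 1, j] = d[k]
    # stage 2: eta-direction, columns i
    for i in range(1, Nx):
        for j in range(Ny):
            if axisym == 1:
                Wu = ec[j] * rf[i] * rf[i]
                WN = ef[j + 1] * rf[i] * rf[i]
                WS = ef[j] * rf[i] * rf[i]
            else:
                Wu = rf[i]
                WN = rf[i]
                WS = rf[i]
            r2 = rf[i] * rf[i]
            if j == Ny - 1:
                fN = dt * WN * mun[i, Ny] / (rho * Wu * r2 * (1.0 - ec[j]) * dec[j])
                cN = 0.0
                dN = fN  # Dirichlet 0 at wall -> diagonal only
            else:
                fN = dt * WN * mun[i, j + 1] / (rho * Wu * r2 * (ec[j + 1] - ec[j]) * dec[j])
                cN = fN
                dN = fN
            if j == 0:
                fS = 0.0  # symmetry: zero flux
                cS = 0.0
                dS = 0.0
            else:
                fS = dt * WS * mun[i, j] / (rho * Wu * r2 * (ec[j] - ec[j - 1]) * dec[j])
                cS = fS
                dS = fS
            # increment upwinding on the mapped transverse velocity
            vbar = 0.25 * (v[i - 1, j] + v[i - 1, j + 1] + v[i, j] + v[i, j + 1])
            ae = (vbar - u[i, j] * ec[j] * drf[i]) / rf[i]
            aS = cS
            cNl = cN
            diag = 1.0 + dN + dS
            if ae > 0.0 and j > 0:
                upn = dt * ae / (ec[j] - ec[j - 1])
                aS += upn
                diag += upn
            elif ae < 0.0:
                sp = (1.0 - ec[j]) if j == Ny - 1 else (ec[j + 1] - ec[j])
                upn = -dt * ae / sp
                diag += upn
                if j < Ny - 1:
                    cNl += upn
            a[j] = -aS
            c[j] = -cNl
            b[j] = diag
            d[j] = w[i, j]
        _thomas(a, b, c, d, Ny)
        for j in range(Ny):
            w[i, j] = d[j]
    for i in range(1, Nx):
        for j in range(Ny):
            u[i, j] += w[i, j]


@njit(cache=True, fastmath=True)
def adi_v(v, u, muc, mun, rhs_v, rho, dt, dx, ec, ef, dec, rf, rc, drc, axisym):
    """Solve the factored principal operator for v and apply the increment."""
    Nx = rc.shape[0]
    Ny = ec.shape[0]
    m = Ny - 1
    if m < 1:
        return
    a = np.empty(max(Nx, Ny) + 1)
    b = np.empty(max(Nx, Ny) + 1)
    c = np.empty(max(Nx, Ny) + 1)
    d = np.empty(max(Nx, Ny) + 1)
    w = np.empty((Nx, Ny + 1))
    # stage 1: x-direction
    for j in range(1, Ny):
        for i in range(Nx):
            if axisym == 1:
                Wv = ef[j] * rc[i] * rc[i]
                WW = ef[j] * rf[i] * rf[i]
                WE = ef[j] * rf[i + 1] * rf[i + 1]
            else:
                Wv = rc[i]
                WW = rf[i]
                WE = rf[i + 1]
            if i == 0:
                fW = dt * WW * mun[0, j] / (rho * Wv * dx * 0.5 * dx)
                aW = 0.0
                dW = fW  # inlet: v = 0 at the face (Dirichlet)
            else:
                fW = dt * WW * mun[i, j] / (rho * Wv * dx * dx)
                aW = fW
                dW = fW
            if i == Nx - 1:
                fE = 0.0  # outlet: zero-gradient
                cE = 0.0
                dE = 0.0
            else:
                fE = dt * WE * mun[i + 1, j] / (rho * Wv * dx * dx)
                cE = fE
                dE = fE
            ubar = 0.25 * (u[i, j - 1] + u[i, j] + u[i + 1, j - 1] + u[i + 1, j])
            upw = dt * (ubar if ubar > 0.0 else 0.0) / dx
            upe = dt * (-ubar if ubar < 0.0 else 0.0) / dx
            if i == 0:
                upw = 0.0
            if i == Nx - 1:
                upe = 0.0
            a[i] = -aW - upw
            c[i] = -cE - upe
            b[i] = 1.0 + dW + dE + upw + upe
            d[i] = rhs_v[i, j]
        _thomas(a, b, c, d, Nx)
        for i in range(Nx):
            w[i, j] = d[i]
    # stage 2: eta-direction (Dirichlet v=0 at axis and wall)
    for i in range(Nx):
        for k in range(m):
            j = k + 1
            if axisym == 1:
                Wv = ef[j] * rc[i] * rc[i]
                WS = ec[j - 1] * rc[i] * rc[i]
                WN = ec[j] * rc[i] * rc[i]
            else:
                Wv = rc[i]
                WS = rc[i]
                WN = rc[i]
            r2 = rc[i] * rc[i]
            fS = dt * WS * 2.0 * muc[i, j - 1] / (rho * Wv * r2 * dec[j - 1] * (ec[j] - ec[j - 1]))
            fN = dt * WN * 2.0 * muc[i, j] / (rho * Wv * r2 * dec[j] * (ec[j] - ec[j - 1]))
            ubar = 0.25 * (u[i, j - 1] + u[i, j] + u[i + 1, j - 1] + u[i + 1, j])
            ae = (v[i, j] - ubar * ef[j] * drc[i]) / rc[i]
            ups = dt * (ae if ae > 0.0 else 0.0) / (ef[j] - ef[j - 1])
            upn = dt * (-ae if ae < 0.0 else 0.0) / (ef[j + 1] - ef[j])
            a[k] = (-fS - ups) if k > 0 else 0.0
            c[k] = (-fN - upn) if k < m - 1 else 0.0
            diag = 1.0 + fS + fN + ups + upn
            if axisym == 1:
                rv = ef[j] * rc[i]
                mu_v = 0.5 * (muc[i, j - 1] + muc[i, j])
                diag += dt * 2.0 * mu_v / (rho * rv * rv)
            b[k] = diag
            d[k] = w[i, j]
        _thomas(a, b, c, d, m)
        for k in range(m):
            w[i, k + 1] = d[k]
    for i in range(Nx):
        for k in range(m):
            v[i, k + 1] += w[i, k + 1]


# ---------------------------------------------------------------------------
# projection pieces
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def divergence(u, v, dx, ec, ef, dec, rf, rc, drc, axisym, div):
    Nx = rc.shape[0]
    Ny = ec.shape[0]
    for i in range(Nx):
        for j in range(Ny):
            if axisym == 1:
                ax = (rf[i + 1] * rf[i + 1] * u[i + 1, j] - rf[i] * rf[i] * u[i, j]) / dx
                gN = _gflux(u, v, i, j + 1, ec, ef, drc, Ny)
                gS = _gflux(u, v, i, j, ec, ef, drc, Ny)
                tr = rc[i] * (ef[j + 1] * gN - ef[j] * gS) / dec[j]
                div[i, j] = (ec[j] * ax + tr) / (ec[j] * rc[i] * rc[i])
            else:
                ax = (rf[i + 1] * u[i + 1, j] - rf[i] * u[i, j]) / dx
                gN = _gflux(u, v, i, j + 1, ec, ef, drc, Ny)
                gS = _gflux(u, v, i, j, ec, ef, drc, Ny)
                div[i, j] = (ax + (gN - gS) / dec[j]) / rc[i]


@njit(cache=True, inline="always", fastmath=True)
def _gflux(u, v, i, j, ec, ef, drc, Ny):
    """Mapped transverse flux G = v - ubar * eta * r' at (x-center i, eta-face j)."""
    if j == 0 or j == Ny:
        return 0.0
    ubar = 0.25 * (u[i, j - 1] + u[i, j] + u[i + 1, j - 1] + u[i + 1, j])
    return v[i, j] - ubar * ef[j] * drc[i]


@njit(cache=True, fastmath=True)
def correct(u, v, phi, dtorho, dx, ec, ef, rf, rc, drf, axisym):
    """Apply the full metric pressure-gradient correction from potential phi."""
    Nx = rc.shape[0]
    Ny = ec.shape[0]
    for i in range(1, Nx):
        for j in range(Ny):
            dpde = 0.5 * (_deta_center(phi, i - 1, j, ec, Ny) + _deta_center(phi, i, j, ec, Ny))
            u[i, j] -= dtorho * ((phi[i, j] - phi[i - 1, j]) / dx -
                                 (ec[j] * drf[i] / rf[i]) * dpde)
    for j in range(Ny):  # outlet face: Dirichlet phi = 0 at the boundary
        u[Nx, j] -= dtorho * (0.0 - phi[Nx - 1, j]) * 2.0 / dx
    for i in range(Nx):
        for j in range(1, Ny):
            v[i, j] -= dtorho * (phi[i, j] - phi[i, j - 1]) / (rc[i] * (ec[j] - ec[j - 1]))
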