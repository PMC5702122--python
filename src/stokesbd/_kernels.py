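"""Numba-compiled particle stepping kernels.

These mirror the readable per-step logic in :mod:`stokesbd.engine`
(``advance_particle`` / ``handle_collision``) but run the whole trajectory of
every particle inside nopython code, which is what makes ensembles of
thousands of particles over 1e4 s horizons tractable. Each particle gets its
own RNG stream (numba's legacy generator seeded per particle), so results do
not depend on simulation order.

Status codes: 0 = mobile at the horizon, 1 = captured, 2 = exited through the
open right edge.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_MOBILE = 0
STATUS_CAPTURED = 1
STATUS_EXITED = 2

# velocity-field modes
FIELD_ZERO = 0
FIELD_UNIFORM = 1
FIELD_GRID = 2


@njit(cache=True, inline="always")
def _field_velocity(x, y, fmode, ufx, ufy, gxs, gys, gvx, gvy):
    if fmode == FIELD_ZERO:
        return 0.0, 0.0
    if fmode == FIELD_UNIFORM:
        return ufx, ufy
    # bilinear interpolation on a uniform grid
    dx = gxs[1] - gxs[0]
    dy = gys[1] - gys[0]
    fx = (x - gxs[0]) / dx
    fy = (y - gys[0]) / dy
    if fx < 0.0:
        fx = 0.0
    if fy < 0.0:
        fy = 0.0
    if fx > gxs.size - 1.000001:
        fx = gxs.size - 1.000001
    if fy > gys.size - 1.000001:
        fy = gys.size - 1.000001
    i = int(fx)
    j = int(fy)
    tx = fx - i
    ty = fy - j
    vx = (
        gvx[j, i] * (1 - tx) * (1 - ty)
        + gvx[j, i + 1] * tx * (1 - ty)
        + gvx[j + 1, i] * (1 - tx) * ty
        + gvx[j + 1, i + 1] * tx * ty
    )
    vy = (
        gvy[j, i] * (1 - tx) * (1 - ty)
        + gvy[j, i + 1] * tx * (1 - ty)
        + gvy[j + 1, i] * (1 - tx) * ty
        + gvy[j + 1, i + 1] * tx * ty
    )
    return vx, vy


@njit(cache=True, inline="always")
def _nearest_solid_distance(x, y, H, cx, cy, rc):
    """Distance to the nearest of inlet, bottom/top walls, and cell rims."""
    R = x  # Ω1
    if y < R:
        R = y  # Ω2
    if H - y < R:
        R = H - y  # Ω3
    if cx.size:
        # all cells share one radius, so the nearest rim is the nearest center
        md2 = 1e300
        for k in range(cx.size):
            dx = x - cx[k]
            dy = y - cy[k]
            d2 = dx * dx + dy * dy
            if d2 < md2:
                md2 = d2
        d = np.sqrt(md2) - rc
        if d < R:
            R = d
    return R


@njit(cache=True, inline="always")
def _nearest_cell(x, y, cx, cy):
    """Index of the nearest cell center and the center distance."""
    jmin = -1
    md2 = 1e300
    for k in range(cx.size):
        dx = x - cx[k]
        dy = y - cy[k]
        d2 = dx * dx + dy * dy
        if d2 < md2:
            md2 = d2
            jmin = k
    return jmin, np.sqrt(md2)


@njit(cache=True, inline="always")
def _solve_dt_intermediate(gap, vmag, D):
    """Positive root of |v|·dt + sqrt(4 D dt) = gap, as dt.

    Uses the cancellation-free form of the quadratic root so tiny speeds
    degrade gracefully to the pure-diffusion limit (and D = 0 to the pure
    advection limit)."""
    s4d = np.sqrt(4.0 * D)
    u = 2.0 * gap / (s4d + np.sqrt(s4d * s4d + 4.0 * vmag * gap))
    return u * u


@njit(cache=True)
def run_adaptive_particle(
    x0,
    y0,
    seed,
    a,
    D,
    rho,
    dt_max,
    dt_min,
    t_end,
    W,
    H,
    cx,
    cy,
    rc,
    fmode,
    ufx,
    ufy,
    gxs,
    gys,
    gvx,
    gvy,
):
    """Advance one particle with the three-tier adaptive scheme until capture,
    exit, or the time horizon. Returns
    (x, y, t, status, collisions, capture_cell, n_tier1, n_tier2, n_tier3)."""
    np.random.seed(seed)
    x = x0
    y = y0
    t = 0.0
    ncol = 0
    cap = -1
    status = STATUS_MOBILE
    n1 = 0
    n2 = 0
    n3 = 0
    contact = rc + a  # center-to-cell-center contact distance

    while t < t_end - 1e-15:
        vx, vy = _field_velocity(x, y, fmode, ufx, ufy, gxs, gys, gvx, gvy)
        vmag = np.hypot(vx, vy)
        R = _nearest_solid_distance(x, y, H, cx, cy, rc)
        rem = t_end - t

        # --- tier 1: largest permissible step ---------------------------
        dt1 = dt_max if dt_max < rem else rem
        th = 2.0 * np.pi * np.random.random()
        sd = np.sqrt(4.0 * D * dt1)
        Sx = vx * dt1 + sd * np.cos(th)
        Sy = vy * dt1 + sd * np.sin(th)
        if np.hypot(Sx, Sy) < R - a:
            x += Sx
            y += Sy
            t += dt1
            n1 += 1
            if x > W:
                status = STATUS_EXITED
                break
            continue

        # --- tier 2: gap-limited intermediate step ----------------------
        if R - a > 0.0 and (D > 0.0 or vmag > 0.0):
            dta = _solve_dt_intermediate(R - a, vmag, D)
            if dta > rem:
                dta = rem
            th = 2.0 * np.pi * np.random.random()
            sd = np.sqrt(4.0 * D * dta)
            Sx = vx * dta + sd * np.cos(th)
            Sy = vy * dta + sd * np.sin(th)
            if np.hypot(Sx, Sy) > 4.0 * a:
                x += Sx
                y += Sy
                t += dta
                n2 += 1
                if x > W:
                    status = STATUS_EXITED
                    break
                continue

        # --- tier 3: finest fixed step, contact resolution --------------
        dts = dt_min if dt_min < rem else rem
        th = 2.0 * np.pi * np.random.random()
        sd = np.sqrt(4.0 * D * dts)
        nx = x + vx * dts + sd * np.cos(th)
        ny = y + vy * dts + sd * np.sin(th)
        t += dts
        n3 += 1

        # specular reflection off the three solid edges (particle is a
        # finite circle: the center stays at least one radius away)
        if nx < a:
            nx = 2.0 * a - nx
        if ny < a:
            ny = 2.0 * a - ny
        if ny > H - a:
            ny = 2.0 * (H - a) - ny
        if nx > W:
            x = nx
            y = ny
            status = STATUS_EXITED
            break

        # nearest penetrated cell, if any
        jmin, dcen = _nearest_cell(nx, ny, cx, cy)
        if jmin >= 0 and dcen - rc < a:
            # collision with cell jmin
            ncol += 1
            ccx = cx[jmin]
            ccy = cy[jmin]
            # first contact point along the attempted move segment
            dxs = nx - x
            dys = ny - y
            px = x - ccx
            py = y - ccy
            A = dxs * dxs + dys * dys
            Bq = 2.0 * (dxs * px + dys * py)
            Cq = px * px + py * py - contact * contact
            disc = Bq * Bq - 4.0 * A * Cq
            ok = False
            qx = 0.0
            qy = 0.0
            if disc >= 0.0 and A > 0.0:
                s = (-Bq - np.sqrt(disc)) / (2.0 * A)
                if 0.0 <= s <= 1.0:
                    qx = x + s * dxs
                    qy = y + s * dys
                    ok = True
            if not ok:
                # start already within contact or tangential numerical miss:
                # project the endpoint radially back to the contact circle
                dn = np.hypot(nx - ccx, ny - ccy)
                if dn == 0.0:
                    continue  # degenerate: reject the move outright
                qx = ccx + contact * (nx - ccx) / dn
                qy = ccy + contact * (ny - ccy) / dn
            if np.random.random() < rho:
                x = qx
                y = qy
                cap = jmin
                status = STATUS_CAPTURED
                break
            # reflected: mirror the penetrating remainder about the local
            # tangent (cell rim treated as a flat wall at the contact point)
            nrx = (qx - ccx) / contact
            nry = (qy - ccy) / contact
            rx = nx - qx
            ry = ny - qy
            dot = rx * nrx + ry * nry
            mx = qx + rx - 2.0 * dot * nrx
            my = qy + ry - 2.0 * dot * nry
            # accept the mirrored position only if it is itself valid
            valid = a <= mx <= W and a <= my <= H - a
            if valid:
                c2 = contact * contact
                for k in range(cx.size):
                    ddx = mx - cx[k]
                    ddy = my - cy[k]
                    if ddx * ddx + ddy * ddy < c2:
                        valid = False
                        break
            if valid:
                x = mx
                y = my
            # else: move rejected, particle stays (time already advanced)
        else:
            x = nx
            y = ny

    return x, y, t, status, ncol, cap, n1, n2, n3


@njit(cache=True)
def run_fixed_particle(
    x0,
    y0,
    seed,
    a,
    D,
    rho,
    dt,
    layer,
    t_end,
    W,
    H,
    cx,
    cy,
    rc,
    fmode,
    ufx,
    ufy,
    gxs,
    gys,
    gvx,
    gvy,
):
    """Non-adaptive reference engine: constant time step, moves overlapping a
    cell rejected, capture attempted with probability rho on arrival within
    the interaction layer around a cell."""
    np.random.seed(seed)
    x = x0
    y = y0
    t = 0.0
    ncol = 0
    cap = -1
    status = STATUS_MOBILE
    contact = rc + a

    while t < t_end - 1e-15:
        rem = t_end - t
        dte = dt if dt < rem else rem
        vx, vy = _field_velocity(x, y, fmode, ufx, ufy, gxs, gys, gvx, gvy)
        th = 2.0 * np.pi * np.random.random()
        sd = np.sqrt(4.0 * D * dte)
        nx = x + vx * dte + sd * np.cos(th)
        ny = y + vy * dte + sd * np.sin(th)
        t += dte
        if nx < a:
            nx = 2.0 * a - nx
        if ny < a:
            ny = 2.0 * a - ny
        if ny > H - a:
            ny = 2.0 * (H - a) - ny
        if nx > W:
            x = nx
            y = ny
            status = STATUS_EXITED
            break
        jmin, dmin = _nearest_cell(nx, ny, cx, cy)
        if jmin >= 0 and dmin < contact:
            continue  # conflict with a cell interior: move rejected
        if jmin >= 0 and dmin < contact + layer:
            ncol += 1
            if np.random.random() < rho:
                # captured in the layer; park the center at contact distance
                x = cx[jmin] + contact * (nx - cx[jmin]) / dmin
                y = cy[jmin] + contact * (ny - cy[jmin]) / dmin
                cap = jmin
                status = STATUS_CAPTURED
                break
        x = nx
        y = ny

    return x, y, t, status, ncol, cap


@njit(cache=True)
def simulate_adaptive(
    x0s, y0s, seeds, a, D, rho, dt_max, dt_min, t_end,
    W, H, cx, cy, rc, fmode, ufx, ufy, gxs, gys, gvx, gvy,
):
    n = x0s.size
    xf = np.empty(n)
    yf = np.empty(n)
    tf = np.empty(n)
    status = np.empty(n, np.int64)
    ncol = np.empty(n, np.int64)
    cap = np.empty(n, np.int64)
    tiers = np.empty((n, 3), np.int64)
    for i in range(n):
        (
            xf[i], yf[i], tf[i], status[i], ncol[i], cap[i],
            tiers[i, 0], tiers[i, 1], tiers[i, 2],
        ) = run_adaptive_particle(
            x0s[i], y0s[i], seeds[i], a, D, rho, dt_max, dt_min, t_end,
            W, H, cx, cy, rc, fmode, ufx, ufy, gxs, gys, gvx, gvy,
        )
    return xf, yf, tf, status, ncol, cap, tiers


@njit(cache=True)
def simulate_fixed(
    x0s, y0s, seeds, a, D, rho, dt, layer, t_end,
    W, H, cx, cy, rc, fmode, ufx, ufy, gxs, gys, gvx, gvy,
):
    n = x0s.size
    xf = np.empty(n)
    yf = np.empty(n)
    tf = np.empty(n)
    status = np.empty(n, np.int64)
    ncol = np.empty(n, np.int64)
    cap = np.empty(n, np.int64)
    for i in range(n):
        xf[i], yf[i], tf[i], status[i], ncol[i], cap[i] = run_fixed_particle(
            x0s[i], y0s[i], seeds[i], a, D, rho, dt, layer, t_end,
            W, H, cx, cy, rc, fmode, ufx, ufy, gxs, gys, gvx, gvy,
        )
    return xf, yf, tf, status, ncol, cap
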