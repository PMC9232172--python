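"""Inner simulation loop on flat arrays.

The mesh is compiled to compact arrays (see ``_arrays``) and integrated here
with explicit Euler steps.  The chunk runner returns control to Python as
soon as a topological event candidate appears (short edge, small cell, or a
division trigger); mesh surgery is done at the Python level and the arrays
are recompiled.

All functions are plain loops so that the same code runs jitted under numba
(preferred) or as pure Python (slow fallback, used only on tiny meshes).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# container spring constant; penetration depth ~ pressure / WALL_STIFFNESS
WALL_STIFFNESS = 50.0

# bound on |area pressure| (A - A0): a mitotic cell jammed below its division
# criterion otherwise inflates its target without limit and the runaway force
# folds the mesh; the bound is far above any pressure reached in normal growth
PRESSURE_CAP = 3.0

# chunk stop codes
DONE = 0
T1_CANDIDATE = 1
T2_CANDIDATE = 2
DIVISION_TRIGGER = 3


@njit(cache=True)
def geometry(pos, cstart, cverts, areas, perims):
    C = cstart.shape[0] - 1
    for c in range(C):
        s, e = cstart[c], cstart[c + 1]
        a = 0.0
        per = 0.0
        for i in range(s, e):
            j = i + 1 if i + 1 < e else s
            v1 = cverts[i]
            v2 = cverts[j]
            x1, y1 = pos[v1, 0], pos[v1, 1]
            x2, y2 = pos[v2, 0], pos[v2, 1]
            a += 0.5 * (x1 * y2 - x2 * y1)
            per += math.sqrt((x2 - x1) ** 2 + (y2 - y1) ** 2)
        areas[c] = a
        perims[c] = per


@njit(cache=True)
def target_areas(t, entry_time, growth_b, a0):
    for c in range(a0.shape[0]):
        if t >= entry_time[c]:
            a0[c] = 1.0 + growth_b * (t - entry_time[c])
        else:
            a0[c] = 1.0


@njit(cache=True)
def forces_into(pos, cstart, cverts, gamma_c, areas, perims, a0, edge_v, edge_lam, out):
    """out <- -dU/dr (analytic gradients of area, perimeter and tension terms)."""
    out[:] = 0.0
    C = cstart.shape[0] - 1
    for c in range(C):
        s, e = cstart[c], cstart[c + 1]
        n = e - s
        press = areas[c] - a0[c]
        gl = gamma_c[c] * perims[c]
        for i in range(s, e):
            vi = cverts[i]
            vp = cverts[i - 1] if i > s else cverts[e - 1]
            vn = cverts[i + 1] if i + 1 < e else cverts[s]
            # d(area)/dr_i = 0.5 * (y_n - y_p, x_p - x_n)
            out[vi, 0] -= press * 0.5 * (pos[vn, 1] - pos[vp, 1])
            out[vi, 1] -= press * 0.5 * (pos[vp, 0] - pos[vn, 0])
            # d(perimeter)/dr_i = unit(r_i - r_p) + unit(r_i - r_n)
            dxp = pos[vi, 0] - pos[vp, 0]
            dyp = pos[vi, 1] - pos[vp, 1]
            lp = math.sqrt(dxp * dxp + dyp * dyp)
            dxn = pos[vi, 0] - pos[vn, 0]
            dyn = pos[vi, 1] - pos[vn, 1]
            ln = math.sqrt(dxn * dxn + dyn * dyn)
            if lp > 0.0:
                out[vi, 0] -= gl * dxp / lp
                out[vi, 1] -= gl * dyp / lp
            if ln > 0.0:
                out[vi, 0] -= gl * dxn / ln
                out[vi, 1] -= gl * dyn / ln
    E = edge_v.shape[0]
    for k in range(E):
        v1 = edge_v[k, 0]
        v2 = edge_v[k, 1]
        dx = pos[v2, 0] - pos[v1, 0]
        dy = pos[v2, 1] - pos[v1, 1]
        ll = math.sqrt(dx * dx + dy * dy)
        if ll > 0.0:
            fx = edge_lam[k] * dx / ll
            fy = edge_lam[k] * dy / ll
            out[v1, 0] += fx
            out[v1, 1] += fy
            out[v2, 0] -= fx
            out[v2, 1] -= fy


@njit(cache=True)
def energy_arrays(pos, cstart, cverts, gamma_c, a0, edge_v, edge_lam):
    C = cstart.shape[0] - 1
    areas = np.empty(C)
    perims = np.empty(C)
    geometry(pos, cstart, cverts, areas, perims)
    u = 0.0
    for c in range(C):
        u += 0.5 * (areas[c] - a0[c]) ** 2 + 0.5 * gamma_c[c] * perims[c] ** 2
    for k in range(edge_v.shape[0]):
        dx = pos[edge_v[k, 1], 0] - pos[edge_v[k, 0], 0]
        dy = pos[edge_v[k, 1], 1] - pos[edge_v[k, 0], 1]
        u += edge_lam[k] * math.sqrt(dx * dx + dy * dy)
    return u


@njit(cache=True)
def _fused_step(pos, cstart, cverts, gamma_c, a0, edge_v, edge_lam, areas, perims, ex, ey, el, out):
    """Single pass: areas, perimeters and forces, one sqrt per cell loop edge."""
    out[:] = 0.0
    C = cstart.shape[0] - 1
    for c in range(C):
        s, e = cstart[c], cstart[c + 1]
        a = 0.0
        per = 0.0
        for i in range(s, e):
            j = i + 1 if i + 1 < e else s
            v1 = cverts[i]
            v2 = cverts[j]
            dx = pos[v2, 0] - pos[v1, 0]
            dy = pos[v2, 1] - pos[v1, 1]
            ll = math.sqrt(dx * dx + dy * dy)
            ex[i] = dx
            ey[i] = dy
            el[i] = ll
            a += 0.5 * (pos[v1, 0] * pos[v2, 1] - pos[v2, 0] * pos[v1, 1])
            per += ll
        areas[c] = a
        perims[c] = per
        press = a - a0[c]
        if press < -PRESSURE_CAP:
            press = -PRESSURE_CAP
        elif press > PRESSURE_CAP:
            press = PRESSURE_CAP
        gl = gamma_c[c] * per
        for i in range(s, e):
            j = i + 1 if i + 1 < e else s
            ip = i - 1 if i > s else e - 1
            vi = cverts[i]
            vj = cverts[j]
            # area term: dA/dr_i = 0.5 * (y_{i+1} - y_{i-1}, x_{i-1} - x_{i+1})
            out[vi, 0] -= press * 0.5 * (ey[i] + ey[ip])
            out[vi, 1] += press * 0.5 * (ex[i] + ex[ip])
            # perimeter term via this edge: dl/dr_vi = -u, dl/dr_vj = +u
            if el[i] > 0.0:
                ux = ex[i] / el[i]
                uy = ey[i] / el[i]
                out[vi, 0] += gl * ux
                out[vi, 1] += gl * uy
                out[vj, 0] -= gl * ux
                out[vj, 1] -= gl * uy
    for k in range(edge_v.shape[0]):
        v1 = edge_v[k, 0]
        v2 = edge_v[k, 1]
        dx = pos[v2, 0] - pos[v1, 0]
        dy = pos[v2, 1] - pos[v1, 1]
        ll = math.sqrt(dx * dx + dy * dy)
        if ll > 0.0:
            fx = edge_lam[k] * dx / ll
            fy = edge_lam[k] * dy / ll
            out[v1, 0] += fx
            out[v1, 1] += fy
            out[v2, 0] -= fx
            out[v2, 1] -= fy


@njit(cache=True)
def run_chunk(
    pos,
    mobile,
    cstart,
    cverts,
    gamma_c,
    abn,
    entry_time,
    area_entry,
    rule_code,
    delta_a,
    growth_b,
    div_not_before,
    t2_not_before,
    edge_v,
    edge_lam,
    edge_interior,
    edge_ok_time,
    theta_t1,
    theta_t2,
    wall_radius,
    t0,
    dt,
    max_steps,
    check_every,
    sample_dt,
    next_sample_t,
    samp_t,
    samp_n,
    samp_a_abn,
    samp_a_tot,
    n_samp0,
):
    """Integrate until an event candidate appears or max_steps elapse.

    Returns (steps_done, stop_code, index, t, n_samples, next_sample_t).
    ``index`` is the compact cell index (T2/division) or edge index (T1) of
    the candidate.  ``area_entry`` is filled in-place the first time a cell
    is seen past its mitosis entry time.  Sampling is clocked on absolute
    time (every ``sample_dt``) so it stays uniform across event interrupts.
    ``wall_radius`` > 0 adds a rigid circular container about the origin:
    vertices are radially clamped to it (free tangential sliding).
    """
    V = pos.shape[0]
    C = cstart.shape[0] - 1
    areas = np.empty(C)
    perims = np.empty(C)
    a0 = np.empty(C)
    frc = np.empty((V, 2))
    nloop = cverts.shape[0]
    ex = np.empty(nloop)
    ey = np.empty(nloop)
    el = np.empty(nloop)
    t = t0
    steps = 0
    n_samp = n_samp0
    while True:
        target_areas(t, entry_time, growth_b, a0)
        _fused_step(pos, cstart, cverts, gamma_c, a0, edge_v, edge_lam, areas, perims, ex, ey, el, frc)
        if steps % check_every == 0:
            for c in range(C):
                if t >= entry_time[c]:
                    if math.isnan(area_entry[c]):
                        area_entry[c] = areas[c]
                    trig = 2.0 * area_entry[c] if rule_code == 0 else area_entry[c] + delta_a
                    if areas[c] >= trig and t >= div_not_before[c]:
                        return steps, DIVISION_TRIGGER, c, t, n_samp, next_sample_t
                if areas[c] < theta_t2 and t >= t2_not_before[c]:
                    return steps, T2_CANDIDATE, c, t, n_samp, next_sample_t
            for k in range(edge_v.shape[0]):
                if edge_interior[k] and t >= edge_ok_time[k]:
                    dx = pos[edge_v[k, 1], 0] - pos[edge_v[k, 0], 0]
                    dy = pos[edge_v[k, 1], 1] - pos[edge_v[k, 0], 1]
                    if dx * dx + dy * dy < theta_t1 * theta_t1:
                        return steps, T1_CANDIDATE, k, t, n_samp, next_sample_t
        if sample_dt > 0 and t >= next_sample_t - 1e-12 and n_samp < samp_t.shape[0]:
            na = 0
            aa = 0.0
            at = 0.0
            for c in range(C):
                at += areas[c]
                if abn[c]:
                    na += 1
                    aa += areas[c]
            samp_t[n_samp] = t
            samp_n[n_samp] = na
            samp_a_abn[n_samp] = aa
            samp_a_tot[n_samp] = at
            n_samp += 1
            next_sample_t += sample_dt
        if steps >= max_steps:
            return steps, DONE, -1, t, n_samp, next_sample_t
        if wall_radius > 0.0:
            # soft container: stiff radial spring outside R keeps the update
            # a gradient flow (a hard projection destabilizes wall cells)
            for v in range(V):
                rr = math.sqrt(pos[v, 0] ** 2 + pos[v, 1] ** 2)
                if rr > wall_radius:
                    coef = WALL_STIFFNESS * (rr - wall_radius) / rr
                    frc[v, 0] -= coef * pos[v, 0]
                    frc[v, 1] -= coef * pos[v, 1]
        for v in range(V):
            if mobile[v]:
                pos[v, 0] += dt * frc[v, 0]
                pos[v, 1] += dt * frc[v, 1]
        t += dt
        steps += 1
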