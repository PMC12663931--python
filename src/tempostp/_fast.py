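"""Numba-compiled numerical core.

Everything latency-critical lives here: event-based localization of the
membrane-potential maximum, the Tsodyks-Markram state recursions with
their parameter partials, per-model voltage gradients, and the online
training loops.  The public modules wrap these kernels with validated
dataclass interfaces; the functions here operate on flat arrays only.

Voltage maximization uses the standard double-exponential trick: between
input spikes the unreset voltage is ``v0 * (A e^{-s/tau_m} - B e^{-s/tau_s})``
with running sums A, B updated by decay-and-add at each spike, so the
stationary point of every inter-spike interval has a closed form and the
global maximum is found exactly in O(n_spikes).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Parameter projection bounds applied after every TM learning update.
U_MIN = 1e-3
U_MAX = 1.0
TAU_MIN = 1e-3
TAU_MAX = 10.0

STATIC = 0
TM = 1


@njit(cache=True, inline="always")
def kernel_value(dt, tau_m, tau_s, v0):
    """Causal unit-amplitude PSP kernel."""
    if dt <= 0.0:
        return 0.0
    return v0 * (np.exp(-dt / tau_m) - np.exp(-dt / tau_s))


@njit(cache=True)
def vmax_tmax(ts, ws, tau_m, tau_s, v0, t_end):
    """Global maximum of the unreset voltage on [0, t_end].

    ``ts`` are sorted input spike times with efficacies ``ws``.  Returns
    ``(v_max, t_max)``; ties resolve to the earliest maximizer.  The
    candidates are every spike arrival after the first, every interior
    stationary point, and t_end; the flat segment before the first spike
    is excluded so that even an everywhere-nonpositive voltage yields a
    gradient point with input spikes before it (the voltage maximum that
    anchors learning).
    """
    n = ts.size
    if n == 0:
        return 0.0, 0.0
    best_v = -1.0e300
    best_t = t_end
    A = 0.0
    B = 0.0
    t_prev = 0.0
    c = tau_m * tau_s / (tau_m - tau_s)
    for k in range(n):
        t_k = ts[k]
        if t_k > t_end:
            break
        d = t_k - t_prev
        A *= np.exp(-d / tau_m)
        B *= np.exp(-d / tau_s)
        if k > 0:
            v_here = v0 * (A - B)
            if v_here > best_v:
                best_v = v_here
                best_t = t_k
        A += ws[k]
        B += ws[k]
        t_prev = t_k
        t_next = ts[k + 1] if k + 1 < n else t_end
        if t_next > t_end:
            t_next = t_end
        # interior stationary point (a maximum only when A, B > 0 and the
        # voltage rises at the interval start, i.e. B*tau_m > A*tau_s)
        if A > 0.0 and B > 0.0 and B * tau_m > A * tau_s:
            s = c * np.log(B * tau_m / (A * tau_s))
            if 0.0 < s < t_next - t_k:
                v = v0 * (A * np.exp(-s / tau_m) - B * np.exp(-s / tau_s))
                if v > best_v:
                    best_v = v
                    best_t = t_k + s
    # endpoint of the window
    d = t_end - t_prev
    if d > 0.0:
        v = v0 * (A * np.exp(-d / tau_m) - B * np.exp(-d / tau_s))
        if v > best_v:
            best_v = v
            best_t = t_end
    return best_v, best_t


@njit(cache=True)
def tm_ux(ts, aff, n_aff, U, tau_rec, tau_fac, u_out, x_out):
    """TM facilitation/depression state (u, x) for every spike of a pattern.

    Spikes arrive time-sorted with afferent indices ``aff``; the recursion
    runs independently per afferent (first spike starts at the unit
    baseline u=x=1).  State is reset at pattern onset.
    """
    last_t = np.zeros(n_aff)
    last_u = np.zeros(n_aff)
    last_x = np.zeros(n_aff)
    seen = np.zeros(n_aff, dtype=np.uint8)
    for k in range(ts.size):
        i = aff[k]
        if seen[i] == 0:
            u = 1.0
            x = 1.0
            seen[i] = 1
        else:
            dt = ts[k] - last_t[i]
            ef = np.exp(-dt / tau_fac[i])
            er = np.exp(-dt / tau_rec[i])
            u = last_u[i] * (1.0 - U[i]) * ef + 1.0
            x = last_x[i] * (1.0 - U[i] * last_u[i]) * er + 1.0 - er
        u_out[k] = u
        x_out[k] = x
        last_t[i] = ts[k]
        last_u[i] = u
        last_x[i] = x


@njit(cache=True)
def tm_ux_partials(ts, aff, n_aff, U, tau_rec, tau_fac,
                   u_out, x_out, du_dU, dx_dU, dx_dr, du_df, dx_df):
    """TM state plus the five partial-derivative recursions per spike.

    Partials of (u, x) with respect to U, tau_rec and tau_fac; first-spike
    partials are zero because the baseline does not depend on the
    parameters.
    """
    last_t = np.zeros(n_aff)
    last_u = np.zeros(n_aff)
    last_x = np.zeros(n_aff)
    p_du_dU = np.zeros(n_aff)
    p_dx_dU = np.zeros(n_aff)
    p_dx_dr = np.zeros(n_aff)
    p_du_df = np.zeros(n_aff)
    p_dx_df = np.zeros(n_aff)
    seen = np.zeros(n_aff, dtype=np.uint8)
    for k in range(ts.size):
        i = aff[k]
        if seen[i] == 0:
            u = 1.0
            x = 1.0
            a_du_dU = 0.0
            a_dx_dU = 0.0
            a_dx_dr = 0.0
            a_du_df = 0.0
            a_dx_df = 0.0
            seen[i] = 1
        else:
            dt = ts[k] - last_t[i]
            Ui = U[i]
            tr = tau_rec[i]
            tf = tau_fac[i]
            ef = np.exp(-dt / tf)
            er = np.exp(-dt / tr)
            up = last_u[i]
            xp = last_x[i]
            u = up * (1.0 - Ui) * ef + 1.0
            x = xp * (1.0 - Ui * up) * er + 1.0 - er
            a_du_dU = ef * ((1.0 - Ui) * p_du_dU[i] - up)
            a_dx_dU = er * ((1.0 - Ui * up) * p_dx_dU[i]
                            - xp * (up + Ui * p_du_dU[i]))
            a_dx_dr = er * ((1.0 - Ui * up) * (p_dx_dr[i] + xp * dt / (tr * tr))
                            - dt / (tr * tr))
            a_du_df = (1.0 - Ui) * ef * (p_du_df[i] + up * dt / (tf * tf))
            a_dx_df = er * ((1.0 - Ui * up) * p_dx_df[i] - Ui * xp * p_du_df[i])
        u_out[k] = u
        x_out[k] = x
        du_dU[k] = a_du_dU
        dx_dU[k] = a_dx_dU
        dx_dr[k] = a_dx_dr
        du_df[k] = a_du_df
        dx_df[k] = a_dx_df
        last_t[i] = ts[k]
        last_u[i] = u
        last_x[i] = x
        p_du_dU[i] = a_du_dU
        p_dx_dU[i] = a_dx_dU
        p_dx_dr[i] = a_dx_dr
        p_du_df[i] = a_du_df
        p_dx_df[i] = a_dx_df


@njit(cache=True)
def grad_static(ts, widx, t_max, tau_m, tau_s, v0, g):
    """dV(t_max)/d(omega_i): kernel-weighted count of spikes before t_max.

    ``widx`` maps each spike to its weight index (afferent index for static
    synapses, afferent*nspikes+rank for ordinal ones).
    """
    g[:] = 0.0
    for k in range(ts.size):
        if ts[k] >= t_max:
            break
        g[widx[k]] += kernel_value(t_max - ts[k], tau_m, tau_s, v0)


@njit(cache=True)
def grad_signcon(ts, aff, rank, t_max, tau_m, tau_s, v0,
                 omega, z, z1, g_omega, g_z, active):
    """Gradients of V(t_max) for the sign-constrained ordinal synapse.

    dV/d(omega_i) = (1/||z_i||_1) sum_{t<tmax} z_ij K(tmax - t_ij);
    dV/d(z_ij)    = (omega_i/||z_i||_1) (K(tmax - t_ij) - dV/d(omega_i)),
    the second term arising from the L1 normalization (so z entries of an
    active afferent have nonzero gradients even for spikes after tmax).
    """
    g_omega[:] = 0.0
    g_z[:, :] = 0.0
    active[:] = False
    n = ts.size
    for k in range(n):
        if ts[k] >= t_max:
            break
        i = aff[k]
        kv = kernel_value(t_max - ts[k], tau_m, tau_s, v0)
        g_omega[i] += z[i, rank[k]] / z1[i] * kv
        g_z[i, rank[k]] += omega[i] / z1[i] * kv
        active[i] = True
    for i in range(omega.size):
        if active[i]:
            for j in range(z.shape[1]):
                g_z[i, j] -= omega[i] / z1[i] * g_omega[i]


@njit(cache=True)
def grad_tm(ts, aff, n_aff, t_max, tau_m, tau_s, v0,
            omega, U, tau_rec, tau_fac,
            g_w, g_U, g_r, g_f, active):
    """Four-component TM gradient of V(t_max).

    Each component is a K(tmax - t_ij)-weighted sum over spikes before tmax
    with the spike-specific dynamic factor: u*x for omega; u*dx/dU + x*du/dU
    for U; u*dx/dtau_rec for tau_rec; u*dx/dtau_fac + x*du/dtau_fac for
    tau_fac (the latter three scaled by omega_i).  ``active`` flags
    afferents with at least one spike before tmax.
    """
    n = ts.size
    u = np.empty(n)
    x = np.empty(n)
    du_dU = np.empty(n)
    dx_dU = np.empty(n)
    dx_dr = np.empty(n)
    du_df = np.empty(n)
    dx_df = np.empty(n)
    tm_ux_partials(ts, aff, n_aff, U, tau_rec, tau_fac,
                   u, x, du_dU, dx_dU, dx_dr, du_df, dx_df)
    g_w[:] = 0.0
    g_U[:] = 0.0
    g_r[:] = 0.0
    g_f[:] = 0.0
    active[:] = False
    for k in range(n):
        if ts[k] >= t_max:
            break
        i = aff[k]
        kv = kernel_value(t_max - ts[k], tau_m, tau_s, v0)
        g_w[i] += u[k] * x[k] * kv
        g_U[i] += omega[i] * kv * (u[k] * dx_dU[k] + x[k] * du_dU[k])
        g_r[i] += omega[i] * kv * u[k] * dx_dr[k]
        g_f[i] += omega[i] * kv * (u[k] * dx_df[k] + x[k] * du_df[k])
        active[i] = True


@njit(cache=True, inline="always")
def _project_tm(U, tau_rec, tau_fac, i):
    if U[i] < U_MIN:
        U[i] = U_MIN
    elif U[i] > U_MAX:
        U[i] = U_MAX
    if tau_rec[i] < TAU_MIN:
        tau_rec[i] = TAU_MIN
    elif tau_rec[i] > TAU_MAX:
        tau_rec[i] = TAU_MAX
    if tau_fac[i] < TAU_MIN:
        tau_fac[i] = TAU_MIN
    elif tau_fac[i] > TAU_MAX:
        tau_fac[i] = TAU_MAX


@njit(cache=True)
def _tm_weights_into(ts, aff, n_aff, omega, U, tau_rec, tau_fac, u, x, w):
    tm_ux(ts, aff, n_aff, U, tau_rec, tau_fac, u, x)
    for k in range(ts.size):
        w[k] = omega[aff[k]] * u[k] * x[k]


@njit(cache=True)
def tm_update_step(ts, aff, n_aff, t_max, sign, tau_m, tau_s, v0,
                   omega, U, tau_rec, tau_fac,
                   prev_w, prev_U, prev_r, prev_f,
                   eta_w, eta_U, eta_r, eta_f,
                   mu_w, mu_U, mu_r, mu_f,
                   train_w, train_U, train_r, train_f,
                   g_w, g_U, g_r, g_f, active):
    """One TM tempotron error-trial update (gradient + momentum + projection).

    The momentum heuristic is invoked for all four parameters of every
    afferent that is active (has a spike) before tmax, independently of
    whether that parameter's gradient contribution is nonzero this trial.
    """
    grad_tm(ts, aff, n_aff, t_max, tau_m, tau_s, v0,
            omega, U, tau_rec, tau_fac, g_w, g_U, g_r, g_f, active)
    for i in range(n_aff):
        if not active[i]:
            continue
        if train_w:
            d = sign * eta_w * g_w[i] + mu_w * prev_w[i]
            omega[i] += d
            prev_w[i] = d
        if train_U:
            d = sign * eta_U * g_U[i] + mu_U * prev_U[i]
            U[i] += d
            prev_U[i] = d
        if train_r:
            d = sign * eta_r * g_r[i] + mu_r * prev_r[i]
            tau_rec[i] += d
            prev_r[i] = d
        if train_f:
            d = sign * eta_f * g_f[i] + mu_f * prev_f[i]
            tau_fac[i] += d
            prev_f[i] = d
        _project_tm(U, tau_rec, tau_fac, i)


@njit(cache=True)
def static_update_step(ts, widx, t_max, sign, tau_m, tau_s, v0,
                       omega, prev, eta, mu, g):
    """One static/ordinal tempotron update.

    Momentum is invoked only where the gradient contribution is nonzero;
    otherwise the weight and its previous update stay untouched.
    """
    grad_static(ts, widx, t_max, tau_m, tau_s, v0, g)
    for i in range(omega.size):
        if g[i] != 0.0:
            d = sign * eta * g[i] + mu * prev[i]
            omega[i] += d
            prev[i] = d


@njit(cache=True)
def signcon_update_step(ts, aff, rank, t_max, sign, tau_m, tau_s, v0,
                        omega, z, z1, prev_w, prev_z,
                        eta_w, eta_z, mu_w, mu_z,
                        g_w, g_z, active):
    """One sign-constrained-ordinal update; z floored at 0 afterwards.

    If flooring would zero out an afferent's entire z vector (undefined
    normalization) that afferent's z update is reverted.
    """
    grad_signcon(ts, aff, rank, t_max, tau_m, tau_s, v0,
                 omega, z, z1, g_w, g_z, active)
    R = z.shape[1]
    for i in range(omega.size):
        if not active[i]:
            continue
        if g_w[i] != 0.0:
            d = sign * eta_w * g_w[i] + mu_w * prev_w[i]
            omega[i] += d
            prev_w[i] = d
        s = 0.0
        for j in range(R):
            if g_z[i, j] != 0.0:
                d = sign * eta_z * g_z[i, j] + mu_z * prev_z[i, j]
                nz = z[i, j] + d
                if nz < 0.0:
                    nz = 0.0
                s += nz - z[i, j]
                z[i, j] = nz
                prev_z[i, j] = d
            else:
                s += 0.0
        new_z1 = z1[i] + s
        # recompute exactly to avoid drift, and guard the degenerate case
        tot = 0.0
        for j in range(R):
            tot += z[i, j]
        if tot <= 0.0:
            # revert this afferent's z step entirely
            for j in range(R):
                z[i, j] -= prev_z[i, j]
                if z[i, j] < 0.0:
                    z[i, j] = 0.0
            tot = 0.0
            for j in range(R):
                tot += z[i, j]
        z1[i] = tot


@njit(cache=True)
def train_static_nb(times, widx, labels, omega, prev,
                    eta, mu, l_max, seed,
                    tau_m, tau_s, v0, theta, t_end, err_hist):
    """Online tempotron training of static/ordinal weights until convergence.

    ``times``/``widx`` are (p, S) arrays of sorted spike times and weight
    indices.  Presentation order is a fresh random permutation every epoch.
    Returns the number of epochs that contained at least one error before
    the first clean pass (== convergence time in batch iterations), or
    l_max if the cutoff was hit.
    """
    p, S = times.shape
    g = np.empty(omega.size)
    for epoch in range(l_max):
        np.random.seed((seed + epoch) & 0x7FFFFFFF)
        order = np.random.permutation(p)
        errs = 0
        for q in range(p):
            m = order[q]
            ts = times[m]
            wi = widx[m]
            w_s = np.empty(S)
            for k in range(S):
                w_s[k] = omega[wi[k]]
            vmax, tmax = vmax_tmax(ts, w_s, tau_m, tau_s, v0, t_end)
            fired = vmax >= theta
            want = labels[m] == 1
            if fired != want:
                errs += 1
                sign = 1.0 if want else -1.0
                static_update_step(ts, wi, tmax, sign, tau_m, tau_s, v0,
                                   omega, prev, eta, mu, g)
        err_hist[epoch] = errs
        if errs == 0:
            return epoch
    return l_max


@njit(cache=True)
def train_signcon_nb(times, affs, ranks, labels, omega, z, prev_w, prev_z,
                     eta_w, eta_z, mu_w, mu_z, l_max, seed,
                     tau_m, tau_s, v0, theta, t_end, err_hist):
    """Online training of the sign-constrained ordinal synapse."""
    p, S = times.shape
    n_aff = omega.size
    R = z.shape[1]
    z1 = np.empty(n_aff)
    for i in range(n_aff):
        tot = 0.0
        for j in range(R):
            tot += z[i, j]
        z1[i] = tot
    g_w = np.empty(n_aff)
    g_z = np.empty((n_aff, R))
    active = np.empty(n_aff, dtype=np.bool_)
    for epoch in range(l_max):
        np.random.seed((seed + epoch) & 0x7FFFFFFF)
        order = np.random.permutation(p)
        errs = 0
        for q in range(p):
            m = order[q]
            ts = times[m]
            af = affs[m]
            rk = ranks[m]
            w_s = np.empty(S)
            for k in range(S):
                i = af[k]
                w_s[k] = omega[i] * z[i, rk[k]] / z1[i]
            vmax, tmax = vmax_tmax(ts, w_s, tau_m, tau_s, v0, t_end)
            fired = vmax >= theta
            want = labels[m] == 1
            if fired != want:
                errs += 1
                sign = 1.0 if want else -1.0
                signcon_update_step(ts, af, rk, tmax, sign, tau_m, tau_s, v0,
                                    omega, z, z1, prev_w, prev_z,
                                    eta_w, eta_z, mu_w, mu_z,
                                    g_w, g_z, active)
        err_hist[epoch] = errs
        if errs == 0:
            return epoch
    return l_max


@njit(cache=True)
def train_tm_nb(times, affs, labels, omega, U, tau_rec, tau_fac,
                prev_w, prev_U, prev_r, prev_f,
                eta_w, eta_U, eta_r, eta_f,
                mu_w, mu_U, mu_r, mu_f,
                train_w, train_U, train_r, train_f,
                l_max, seed, tau_m, tau_s, v0, theta, t_end, err_hist):
    """Online training of Tsodyks-Markram synapse parameters."""
    p, S = times.shape
    n_aff = omega.size
    u = np.empty(S)
    x = np.empty(S)
    w_s = np.empty(S)
    g_w = np.empty(n_aff)
    g_U = np.empty(n_aff)
    g_r = np.empty(n_aff)
    g_f = np.empty(n_aff)
    active = np.empty(n_aff, dtype=np.bool_)
    for epoch in range(l_max):
        np.random.seed((seed + epoch) & 0x7FFFFFFF)
        order = np.random.permutation(p)
        errs = 0
        for q in range(p):
            m = order[q]
            ts = times[m]
            af = affs[m]
            _tm_weights_into(ts, af, n_aff, omega, U, tau_rec, tau_fac, u, x, w_s)
            vmax, tmax = vmax_tmax(ts, w_s, tau_m, tau_s, v0, t_end)
            fired = vmax >= theta
            want = labels[m] == 1
            if fired != want:
                errs += 1
                sign = 1.0 if want else -1.0
                tm_update_step(ts, af, n_aff, tmax, sign, tau_m, tau_s, v0,
                               omega, U, tau_rec, tau_fac,
                               prev_w, prev_U, prev_r, prev_f,
                               eta_w, eta_U, eta_r, eta_f,
                               mu_w, mu_U, mu_r, mu_f,
                               train_w, train_U, train_r, train_f,
                               g_w, g_U, g_r, g_f, active)
        err_hist[epoch] = errs
        if errs == 0:
            return epoch
    return l_max


# ---------------------------------------------------------------------------
# noise-robustness protocol: templates corrupted independently per presentation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _corrupt_into(ts, af, T, noise_mode, sigma, p_del, bg_rate,
                  out_ts, out_af):
    """Draw one corruption of a template into preallocated buffers.

    noise_mode: 0 jitter, 1 delete, 2 delete+background.  Returns the number
    of spikes written (sorted by time).
    """
    S = ts.size
    n = 0
    if noise_mode == 0:
        for k in range(S):
            t = ts[k] + np.random.normal(0.0, sigma)
            if t < 0.0:
                t = 0.0
            elif t > T:
                t = T
            out_ts[n] = t
            out_af[n] = af[k]
            n += 1
    else:
        for k in range(S):
            if np.random.random() >= p_del:
                out_ts[n] = ts[k]
                out_af[n] = af[k]
                n += 1
        if noise_mode == 2 and bg_rate > 0.0:
            n_aff = 0
            for k in range(S):
                if af[k] + 1 > n_aff:
                    n_aff = af[k] + 1
            cap = out_ts.size
            for i in range(n_aff):
                n_bg = np.random.poisson(bg_rate)
                for _ in range(n_bg):
                    if n < cap:
                        out_ts[n] = np.random.uniform(0.0, T)
                        out_af[n] = i
                        n += 1
    order = np.argsort(out_ts[:n], kind="mergesort")
    tmp_t = out_ts[:n][order].copy()
    tmp_a = out_af[:n][order].copy()
    for k in range(n):
        out_ts[k] = tmp_t[k]
        out_af[k] = tmp_a[k]
    return n


@njit(cache=True)
def train_robust_nb(times, affs, labels, model_kind,
                    omega, U, tau_rec, tau_fac,
                    prev_w, prev_U, prev_r, prev_f,
                    eta_w, eta_U, eta_r, eta_f,
                    mu_w, mu_U, mu_r, mu_f,
                    noise_mode, sigma, p_del, bg_rate, T,
                    n_cycles, eval_stride, n_eval, seed,
                    tau_m, tau_s, v0, theta, t_end,
                    train_err, eval_err):
    """Template-corruption training protocol.

    Template patterns are never shown directly; each presentation corrupts
    its template with fresh noise.  Every ``eval_stride`` cycles the
    generalization error is measured over ``n_eval`` freshly corrupted
    presentations without learning.  ``model_kind``: 0 static, 1 TM.
    Returns the number of evaluation points written into ``eval_err``.
    """
    p, S = times.shape
    n_aff = omega.size
    cap = S + 16 * (int(np.max(affs)) + 1) if noise_mode == 2 else S
    buf_t = np.empty(cap)
    buf_a = np.empty(cap, dtype=np.int64)
    g = np.empty(n_aff)
    g_U = np.empty(n_aff)
    g_r = np.empty(n_aff)
    g_f = np.empty(n_aff)
    active = np.empty(n_aff, dtype=np.bool_)
    np.random.seed(seed & 0x7FFFFFFF)
    n_evals = 0
    for cycle in range(n_cycles):
        order = np.random.permutation(p)
        errs = 0
        for q in range(p):
            m = order[q]
            n = _corrupt_into(times[m], affs[m], T, noise_mode, sigma,
                              p_del, bg_rate, buf_t, buf_a)
            ts = buf_t[:n]
            af = buf_a[:n]
            w_s = np.empty(n)
            if model_kind == TM:
                u = np.empty(n)
                x = np.empty(n)
                _tm_weights_into(ts, af, n_aff, omega, U, tau_rec, tau_fac,
                                 u, x, w_s)
            else:
                for k in range(n):
                    w_s[k] = omega[af[k]]
            vmax, tmax = vmax_tmax(ts, w_s, tau_m, tau_s, v0, t_end)
            fired = vmax >= theta
            want = labels[m] == 1
            if fired != want:
                errs += 1
                sign = 1.0 if want else -1.0
                if model_kind == TM:
                    tm_update_step(ts, af, n_aff, tmax, sign, tau_m, tau_s, v0,
                                   omega, U, tau_rec, tau_fac,
                                   prev_w, prev_U, prev_r, prev_f,
                                   eta_w, eta_U, eta_r, eta_f,
                                   mu_w, mu_U, mu_r, mu_f,
                                   True, True, True, True,
                                   g, g_U, g_r, g_f, active)
                else:
                    static_update_step(ts, af, tmax, sign, tau_m, tau_s, v0,
                                       omega, prev_w, eta_w, mu_w, g)
        train_err[cycle] = errs
        if (cycle + 1) % eval_stride == 0 or cycle + 1 == n_cycles:
            wrong = 0
            for e in range(n_eval):
                m = e % p
                n = _corrupt_into(times[m], affs[m], T, noise_mode, sigma,
                                  p_del, bg_rate, buf_t, buf_a)
                ts = buf_t[:n]
                af = buf_a[:n]
                w_s = np.empty(n)
                if model_kind == TM:
                    u = np.empty(n)
                    x = np.empty(n)
                    _tm_weights_into(ts, af, n_aff, omega, U, tau_rec,
                                     tau_fac, u, x, w_s)
                else:
                    for k in range(n):
                        w_s[k] = omega[af[k]]
                vmax, _ = vmax_tmax(ts, w_s, tau_m, tau_s, v0, t_end)
                if (vmax >= theta) != (labels[m] == 1):
                    wrong += 1
            eval_err[n_evals] = wrong / n_eval
            n_evals += 1
    return n_evals


# ---------------------------------------------------------------------------
# spatiotemporal correlation tasks (pairing / delay / XOR), online generation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _make_pair_pattern(n_aff, pairing, delta, first_window, out_ts, out_af):
    """One paired-synchrony pattern: N/2 pairs firing at t and t+delta."""
    half = n_aff // 2
    n = 0
    for k in range(half):
        if pairing == 1:
            a = 2 * k
            b = 2 * k + 1
        else:
            a = k
            b = k + half
        t0 = np.random.uniform(0.0, first_window)
        out_ts[n] = t0
        out_af[n] = a
        n += 1
        out_ts[n] = t0
        out_af[n] = b
        n += 1
        t1 = t0 + delta
        out_ts[n] = t1
        out_af[n] = a
        n += 1
        out_ts[n] = t1
        out_af[n] = b
        n += 1
    order = np.argsort(out_ts[:n], kind="mergesort")
    tmp_t = out_ts[:n][order].copy()
    tmp_a = out_af[:n][order].copy()
    for k in range(n):
        out_ts[k] = tmp_t[k]
        out_af[k] = tmp_a[k]
    return n


@njit(cache=True, inline="always")
def _corr_target(task_id, pairing, is_short):
    """Task contingency map.  task_id: 0 pairing, 1 short-delay, 2 long-delay, 3 XOR."""
    if task_id == 0:
        return pairing == 1
    if task_id == 1:
        return is_short
    if task_id == 2:
        return not is_short
    return (pairing == 1) == is_short


@njit(cache=True)
def train_corr_nb(model_kind, n_aff,
                  omega, U, tau_rec, tau_fac,
                  prev_w, prev_U, prev_r, prev_f,
                  eta_w, eta_U, eta_r, eta_f,
                  mu_w, mu_U, mu_r, mu_f,
                  task_id, delta_short, delta_long, delta_sd,
                  first_window, n_pres, block, seed,
                  tau_m, tau_s, v0, theta, t_end, err_blocks):
    """Online training on a spatiotemporal correlation task.

    Every presentation draws pairing and delay uniformly, adds Gaussian
    delay noise (SD ``delta_sd``), labels the pattern per the task map and
    applies a tempotron update on errors.  Running training-error rates are
    recorded per ``block`` presentations.
    """
    S = 2 * n_aff
    buf_t = np.empty(S)
    buf_a = np.empty(S, dtype=np.int64)
    g = np.empty(n_aff)
    g_U = np.empty(n_aff)
    g_r = np.empty(n_aff)
    g_f = np.empty(n_aff)
    active = np.empty(n_aff, dtype=np.bool_)
    np.random.seed(seed & 0x7FFFFFFF)
    errs = 0
    bi = 0
    for pres in range(n_pres):
        pairing = 1 if np.random.random() < 0.5 else 2
        is_short = np.random.random() < 0.5
        base = delta_short if is_short else delta_long
        d = base + np.random.normal(0.0, delta_sd) if delta_sd > 0.0 else base
        if d < 1e-4:
            d = 1e-4
        n = _make_pair_pattern(n_aff, pairing, d, first_window, buf_t, buf_a)
        ts = buf_t[:n]
        af = buf_a[:n]
        w_s = np.empty(n)
        if model_kind == TM:
            u = np.empty(n)
            x = np.empty(n)
            _tm_weights_into(ts, af, n_aff, omega, U, tau_rec, tau_fac,
                             u, x, w_s)
        else:
            for k in range(n):
                w_s[k] = omega[af[k]]
        vmax, tmax = vmax_tmax(ts, w_s, tau_m, tau_s, v0, t_end)
        fired = vmax >= theta
        want = _corr_target(task_id, pairing, is_short)
        if fired != want:
            errs += 1
            sign = 1.0 if want else -1.0
            if model_kind == TM:
                tm_update_step(ts, af, n_aff, tmax, sign, tau_m, tau_s, v0,
                               omega, U, tau_rec, tau_fac,
                               prev_w, prev_U, prev_r, prev_f,
                               eta_w, eta_U, eta_r, eta_f,
                               mu_w, mu_U, mu_r, mu_f,
                               True, True, True, True,
                               g, g_U, g_r, g_f, active)
            else:
                static_update_step(ts, af, tmax, sign, tau_m, tau_s, v0,
                                   omega, prev_w, eta_w, mu_w, g)
        if (pres + 1) % block == 0:
            err_blocks[bi] = errs / block
            errs = 0
            bi += 1
    return bi


@njit(cache=True)
def eval_corr_nb(model_kind, n_aff, omega, U, tau_rec, tau_fac,
                 pairing, delta, first_window, n_test, seed,
                 tau_m, tau_s, v0, theta, t_end):
    """Fraction of test patterns of one (pairing, delay) condition that fire."""
    S = 2 * n_aff
    buf_t = np.empty(S)
    buf_a = np.empty(S, dtype=np.int64)
    np.random.seed(seed & 0x7FFFFFFF)
    fired_n = 0
    for _ in range(n_test):
        n = _make_pair_pattern(n_aff, pairing, delta, first_window,
                               buf_t, buf_a)
        ts = buf_t[:n]
        af = buf_a[:n]
        w_s = np.empty(n)
        if model_kind == TM:
            u = np.empty(n)
            x = np.empty(n)
            _tm_weights_into(ts, af, n_aff, omega, U, tau_rec, tau_fac,
                             u, x, w_s)
        else:
            for k in range(n):
                w_s[k] = omega[af[k]]
        vmax, _ = vmax_tmax(ts, w_s, tau_m, tau_s, v0, t_end)
        if vmax >= theta:
            fired_n += 1
    return fired_n / n_test
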