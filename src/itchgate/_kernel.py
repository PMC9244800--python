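"""Numba-jitted integration core for the compartment chain.

One implicit (backward-Euler) voltage step per time step on the tridiagonal
cable system, with Rush-Larsen (exact-exponential) gate updates staggered
before the voltage solve.  Voltage-dependent steady states and per-step
relaxation factors are pre-tabulated on a uniform voltage grid and linearly
interpolated, which keeps the inner loop free of transcendental calls except
for the calcium-dependent SK/BK gates (evaluated directly per hillock
compartment).

Unit system: mV, ms, uS, nF, nA (so C/dt [nF/ms] adds directly to
conductances [uS] and currents come out in nA).

Gate memory layout
    hillock (per hillock compartment): the voltage gates of the Na, KDR, KA
    and CaR channels in channel order (counts given by ``chan_ngates``),
    followed by the SK calcium gate (z) and the BK gate (w).
    table rows: the hillock voltage gates, then nodal HH m, h, n.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NUMERIC_FAILURE = 1


@njit(cache=True, fastmath=True)
def _lerp_row(tab, row, pos, i0, frac):
    return tab[row, i0] * (1.0 - frac) + tab[row, i0 + 1] * frac


@njit(cache=True, fastmath=True)
def _ipow(x, p):
    y = 1.0
    for _ in range(p):
        y *= x
    return y


@njit(cache=True, fastmath=True)
def integrate(
    nsteps,
    dt,
    # geometry / passive (per compartment)
    c_over_dt,  # (N,) nF/ms
    gpas,  # (N,) uS
    gpas_e,  # (N,) uS*mV
    gax,  # (N-1,) uS coupling i..i+1
    # hillock mechanisms
    hill_idx,  # (nh,) int64
    hill_g,  # (nh, 7) uS  [na, kdr, ka, sk, bk, car, lk]
    erev,  # (7,) mV per channel
    ica_conv,  # (nh,) (mA/cm2) per nA at that compartment
    chan_ngates,  # (4,) int64 voltage-gate counts of Na, KDR, KA, CaR
    pw,  # (nhv,) int64 powers of the hillock voltage gates
    # rate tables
    vmin,
    dv,
    inf_tab,  # (10, M)
    rel_tab,  # (10, M)
    # SK / BK / calcium parameters
    sk_kd,
    sk_hill,
    sk_rel,
    bk_vh0,
    bk_slope,
    bk_shift,
    bk_caref,
    bk_rel,
    ca_base,
    ca_ktau,  # k * tau_ca  (uM cm2 ms / (ms mA) * ... ) premultiplied
    ca_rel,  # exp(-dt/tau_ca)
    # nodes
    node_idx,  # (nn,) int64
    node_g,  # (nn, 3) uS [na, k, leak]
    hh_e,  # (3,) mV
    # stimuli (current steps)
    stim_comp,  # (S,) int64
    stim_on,  # (S,) int64 step index
    stim_off,  # (S,) int64
    stim_nA,  # (S,)
    # synapses (double-exponential conductances driven by scheduled events)
    syn_comp,  # (Y,) int64
    syn_e,  # (Y,) mV
    syn_gnorm,  # (Y,) uS peak * normalization
    syn_rr,  # (Y,) exp(-dt/tau_rise)
    syn_rd,  # (Y,) exp(-dt/tau_decay)
    ev_step,  # (E,) int64 sorted event step indices
    ev_syn,  # (E,) int64 synapse index per event
    # state (modified in place)
    V,  # (N,)
    hg,  # (nh, 9)
    ng,  # (nn, 3)
    ca,  # (nh,)
    synA,  # (Y,)
    synB,  # (Y,)
    # recording
    rec_idx,  # (R,) int64
    out,  # (R, nsteps+1)
    # spike watch
    watch_comp,
    watch_thresh,
    watch_min_slope,  # mV/ms required at the crossing (rejects passive charging)
    refrac_steps,
    spike_steps,  # (max_spikes,) int64 out
    stop_after_first,
):
    N = V.shape[0]
    nh = hill_idx.shape[0]
    nn = node_idx.shape[0]
    M = inf_tab.shape[1]
    Y = syn_comp.shape[0]
    nhv = pw.shape[0]  # number of hillock voltage gates
    z_idx = nhv
    w_idx = nhv + 1
    # offsets of each channel's gates within the voltage-gate block
    off_na = 0
    off_kdr = off_na + chan_ngates[0]
    off_ka = off_kdr + chan_ngates[1]
    off_car = off_ka + chan_ngates[2]

    lo = np.empty(N)
    diag = np.empty(N)
    up = np.empty(N)
    rhs = np.empty(N)
    cp = np.empty(N)
    dp = np.empty(N)

    for r in range(rec_idx.shape[0]):
        out[r, 0] = V[rec_idx[r]]

    n_spikes = 0
    last_spike_step = -refrac_steps - 1
    vprev_watch = V[watch_comp]
    ev_ptr = 0
    E = ev_step.shape[0]
    status = STATUS_OK
    steps_done = 0

    for step in range(nsteps):
        # --- gate updates (Rush-Larsen at current V) -----------------------
        for j in range(nh):
            i = hill_idx[j]
            vi = V[i]
            pos = (vi - vmin) / dv
            if pos < 0.0:
                pos = 0.0
            elif pos > M - 2:
                pos = float(M - 2)
            i0 = int(pos)
            frac = pos - i0
            for row in range(nhv):
                inf = _lerp_row(inf_tab, row, pos, i0, frac)
                rel = _lerp_row(rel_tab, row, pos, i0, frac)
                hg[j, row] = inf + (hg[j, row] - inf) * rel

            # calcium pool driven by the R-type current
            g_car = hill_g[j, 5]
            for k in range(chan_ngates[3]):
                g_car *= _ipow(hg[j, off_car + k], pw[off_car + k])
            ica_dens = g_car * (vi - erev[5]) * ica_conv[j]  # mA/cm2
            ca_inf = ca_base - ca_ktau * ica_dens
            cav = ca_inf + (ca[j] - ca_inf) * ca_rel
            if cav < 0.0:
                cav = 0.0
            ca[j] = cav

            # SK gate (calcium Hill)
            can = cav**sk_hill
            zinf = can / (can + sk_kd**sk_hill)
            hg[j, z_idx] = zinf + (hg[j, z_idx] - zinf) * sk_rel

            # BK gate (calcium-shifted Boltzmann in V)
            ca_for_log = cav if cav > 1e-6 else 1e-6
            vh = bk_vh0 - bk_shift * np.log10(ca_for_log / bk_caref)
            winf = 1.0 / (1.0 + np.exp((vh - vi) / bk_slope))
            hg[j, w_idx] = winf + (hg[j, w_idx] - winf) * bk_rel

        for j in range(nn):
            i = node_idx[j]
            vi = V[i]
            pos = (vi - vmin) / dv
            if pos < 0.0:
                pos = 0.0
            elif pos > M - 2:
                pos = float(M - 2)
            i0 = int(pos)
            frac = pos - i0
            for k in range(3):
                row = nhv + k
                inf = _lerp_row(inf_tab, row, pos, i0, frac)
                rel = _lerp_row(rel_tab, row, pos, i0, frac)
                ng[j, k] = inf + (ng[j, k] - inf) * rel

        # --- assemble tridiagonal system -----------------------------------
        for i in range(N):
            diag[i] = c_over_dt[i] + gpas[i]
            rhs[i] = c_over_dt[i] * V[i] + gpas_e[i]
            lo[i] = 0.0
            up[i] = 0.0
        for i in range(N - 1):
            diag[i] += gax[i]
            diag[i + 1] += gax[i]
            up[i] = -gax[i]
            lo[i + 1] = -gax[i]

        for j in range(nh):
            i = hill_idx[j]
            g_na = hill_g[j, 0]
            for k in range(chan_ngates[0]):
                g_na *= _ipow(hg[j, off_na + k], pw[off_na + k])
            g_kdr = hill_g[j, 1]
            for k in range(chan_ngates[1]):
                g_kdr *= _ipow(hg[j, off_kdr + k], pw[off_kdr + k])
            g_ka = hill_g[j, 2]
            for k in range(chan_ngates[2]):
                g_ka *= _ipow(hg[j, off_ka + k], pw[off_ka + k])
            g_sk = hill_g[j, 3] * hg[j, z_idx]
            g_bk = hill_g[j, 4] * hg[j, w_idx]
            g_car = hill_g[j, 5]
            for k in range(chan_ngates[3]):
                g_car *= _ipow(hg[j, off_car + k], pw[off_car + k])
            g_lk = hill_g[j, 6]
            diag[i] += g_na + g_kdr + g_ka + g_sk + g_bk + g_car + g_lk
            rhs[i] += (
                g_na * erev[0]
                + g_kdr * erev[1]
                + g_ka * erev[2]
                + g_sk * erev[3]
                + g_bk * erev[4]
                + g_car * erev[5]
                + g_lk * erev[6]
            )

        for j in range(nn):
            i = node_idx[j]
            g_na = node_g[j, 0] * _ipow(ng[j, 0], 3) * ng[j, 1]
            g_k = node_g[j, 1] * _ipow(ng[j, 2], 4)
            g_l = node_g[j, 2]
            diag[i] += g_na + g_k + g_l
            rhs[i] += g_na * hh_e[0] + g_k * hh_e[1] + g_l * hh_e[2]

        for s in range(stim_comp.shape[0]):
            if stim_on[s] <= step < stim_off[s]:
                rhs[stim_comp[s]] += stim_nA[s]

        # synaptic conductances: decay, apply events, insert implicitly
        while ev_ptr < E and ev_step[ev_ptr] == step:
            y = ev_syn[ev_ptr]
            synA[y] += 1.0
            synB[y] += 1.0
            ev_ptr += 1
        for y in range(Y):
            synA[y] *= syn_rr[y]
            synB[y] *= syn_rd[y]
            gsyn = syn_gnorm[y] * (synB[y] - synA[y])
            if gsyn < 0.0:
                gsyn = 0.0
            i = syn_comp[y]
            diag[i] += gsyn
            rhs[i] += gsyn * syn_e[y]

        # --- Thomas solve ---------------------------------------------------
        cp[0] = up[0] / diag[0]
        dp[0] = rhs[0] / diag[0]
        for i in range(1, N):
            m = diag[i] - lo[i] * cp[i - 1]
            cp[i] = up[i] / m
            dp[i] = (rhs[i] - lo[i] * dp[i - 1]) / m
        V[N - 1] = dp[N - 1]
        for i in range(N - 2, -1, -1):
            V[i] = dp[i] - cp[i] * V[i + 1]

        steps_done = step + 1

        vw = V[watch_comp]
        if not (-500.0 < vw < 500.0) or not (-500.0 < V[hill_idx[0]] < 500.0):
            status = STATUS_NUMERIC_FAILURE
            break

        for r in range(rec_idx.shape[0]):
            out[r, step + 1] = V[rec_idx[r]]

        if (
            vprev_watch < watch_thresh <= vw
            and (vw - vprev_watch) / dt >= watch_min_slope
            and step - last_spike_step > refrac_steps
        ):
            if n_spikes < spike_steps.shape[0]:
                spike_steps[n_spikes] = step + 1
            n_spikes += 1
            last_spike_step = step
            if stop_after_first:
                vprev_watch = vw
                break
        vprev_watch = vw

    return n_spikes, steps_done, status
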