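"""Numba-compiled right-hand side and adaptive RK23 integrator.

The network state vector is laid out as::

    y[0:nc]                     membrane potentials V_i (mV)
    y[nc + 10*i : nc + 10*i+10] gating variables of cell i, in the order
                                (m_NaF, h_NaF, m_KDR, m_KA, h_KA,
                                 m_K2, h_K2, m_H, m_CaT, h_CaT)
    y[11*nc + 2*s : 11*nc+2*s+2] (A, B) states of chemical synapse s

All conductances are densities (mS/cm^2) on equal-area compartments, so with
C_m in uF/cm^2 and V in mV the equations integrate directly in ms.

The integrator is the Bogacki-Shampine 2(3) pair (the method behind MATLAB's
``ode23`` and SciPy's ``RK23``) with a hard step-size cap, step alignment to
scheduled external events, and online threshold-crossing spike detection that
feeds the event-driven chemical synapses with zero delay.
"""

import numpy as np
from numba import njit

NGATE = 10  # gating variables per cell

# channel order used everywhere: NaF, KDR, KA, K2, H, CaT, leak
CH_NAF, CH_KDR, CH_KA, CH_K2, CH_H, CH_CAT, CH_LEAK = range(7)

# integration status codes
OK = 0
RECORD_OVERFLOW = 1
STEP_FAILURE = 2
SPIKE_OVERFLOW = 3


@njit(cache=True)
def gating_rates(v, kin, inf, tau):
    """Steady-state values and time constants (ms) of the 10 gating variables.

    Rate functions follow a single-compartment thalamic reticular (nRT)
    Hodgkin-Huxley formulation; see the provenance table in docs/methods.md.
    ``kin`` packs the constants that differ between published variants of
    that model: [naf_shift (mV), cat_taum_base, cat_taum_scale,
    cat_tauh_base, cat_tauh_scale] (ms).
    """
    # NaF activation (shifted variant parameter), m^3
    vs = v + kin[0]
    inf[0] = 1.0 / (1.0 + np.exp((-vs - 38.0) / 10.0))
    if vs < -30.0:
        tau[0] = 0.0125 + 0.1525 * np.exp((vs + 30.0) / 10.0)
    else:
        tau[0] = 0.02 + 0.145 * np.exp((-vs - 30.0) / 10.0)
    # NaF inactivation
    inf[1] = 1.0 / (1.0 + np.exp((v + 62.9) / 10.7))
    tau[1] = 0.225 + 1.125 / (1.0 + np.exp((v + 37.0) / 15.0))
    # KDR activation, m^4
    inf[2] = 1.0 / (1.0 + np.exp((-v - 29.5) / 10.0))
    if v < -10.0:
        tau[2] = 0.25 + 4.35 * np.exp((v + 10.0) / 10.0)
    else:
        tau[2] = 0.25 + 4.35 * np.exp((-v - 10.0) / 10.0)
    # KA activation, m^4
    inf[3] = 1.0 / (1.0 + np.exp((-v - 60.0) / 8.5))
    tau[3] = 0.185 + 0.5 / (np.exp((v + 35.8) / 19.7) + np.exp((-v - 79.7) / 12.7))
    # KA inactivation
    inf[4] = 1.0 / (1.0 + np.exp((v + 78.0) / 6.0))
    if v <= -63.0:
        tau[4] = 0.5 / (np.exp((v + 46.0) / 5.0) + np.exp((-v - 238.0) / 37.5))
    else:
        tau[4] = 9.12
    # K2 activation, m^1
    inf[5] = 1.0 / (1.0 + np.exp((-v - 10.0) / 17.0))
    tau[5] = 4.95 + 0.5 / (np.exp((v - 81.0) / 25.6) + np.exp((-v - 132.0) / 18.0))
    # K2 inactivation
    inf[6] = 1.0 / (1.0 + np.exp((v + 58.0) / 10.6))
    tau[6] = 60.0 + 0.5 / (np.exp((v - 1.33) / 200.0) + np.exp((-v - 130.0) / 7.1))
    # H (slow anomalous rectifier) activation, m^1
    inf[7] = 1.0 / (1.0 + np.exp((v + 75.0) / 5.5))
    tau[7] = 1.0 / (np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v))
    # CaT activation, m^2
    inf[8] = 1.0 / (1.0 + np.exp((-v - 52.0) / 7.4))
    tau[8] = kin[1] + kin[2] / (np.exp((v + 27.0) / 10.0) + np.exp((-v - 102.0) / 15.0))
    # CaT inactivation
    inf[9] = 1.0 / (1.0 + np.exp((v + 80.0) / 5.0))
    tau[9] = kin[3] + kin[4] / (np.exp((v + 48.0) / 4.0) + np.exp((-v - 407.0) / 50.0))


@njit(cache=True)
def channel_open_fractions(gating, out):
    """Open fraction of each of the 7 channels from the 10 gating variables."""
    out[CH_NAF] = gating[0] ** 3 * gating[1]
    out[CH_KDR] = gating[2] ** 4
    out[CH_KA] = gating[3] ** 4 * gating[4]
    out[CH_K2] = gating[5] * gating[6]
    out[CH_H] = gating[7]
    out[CH_CAT] = gating[8] ** 2 * gating[9]
    out[CH_LEAK] = 1.0


@njit(cache=True)
def rhs(t, y, dydt, gbar, erev, cm, idc, kin,
        syn_post, syn_gbar, syn_e, syn_taur, syn_tauf,
        gap_i, gap_j, gap_g):
    nc = gbar.shape[0]
    ns = syn_gbar.shape[0]
    sb = nc + NGATE * nc
    inf = np.empty(NGATE)
    tau = np.empty(NGATE)
    opens = np.empty(7)
    for i in range(nc):
        v = y[i]
        b = nc + NGATE * i
        channel_open_fractions(y[b:b + NGATE], opens)
        itot = idc[i]
        for c in range(7):
            itot += gbar[i, c] * opens[c] * (erev[c] - v)
        dydt[i] = itot / cm
        gating_rates(v, kin, inf, tau)
        for k in range(NGATE):
            dydt[b + k] = (inf[k] - y[b + k]) / tau[k]
    for s in range(ns):
        a = y[sb + 2 * s]
        bb = y[sb + 2 * s + 1]
        dydt[sb + 2 * s] = -a / syn_taur[s]
        dydt[sb + 2 * s + 1] = -bb / syn_tauf[s]
        p = syn_post[s]
        dydt[p] += syn_gbar[s] * (bb - a) * (syn_e[s] - y[p]) / cm
    for k in range(gap_g.shape[0]):
        ig = gap_g[k] * (y[gap_j[k]] - y[gap_i[k]])
        dydt[gap_i[k]] += ig / cm
        dydt[gap_j[k]] -= ig / cm
    return dydt


@njit(cache=True)
def integrate(y, t0, t1, max_step, rtol, atol,
              gbar, erev, cm, idc, kin,
              syn_pre, syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, syn_fs,
              gap_i, gap_j, gap_g,
              ext_syn, ext_t,
              thresh, min_isi,
              record_every,
              rec_t, rec_v, spike_t, spike_n, gate_min, gate_max):
    """Integrate the network in place from t0 to t1.

    ``y`` is modified in place and holds the final state on return.
    External events (ext_syn, ext_t; sorted by time) increment the (A, B)
    states of their target synapse by f_s at their scheduled time (the step
    grid is aligned to event times).  Upward crossings of ``thresh`` by any
    cell, debounced by ``min_isi``, increment the synapses whose ``syn_pre``
    is that cell and are logged in ``spike_t``/``spike_n``.

    Returns (n_recorded, status).
    """
    n = y.size
    nc = gbar.shape[0]
    ns = syn_gbar.shape[0]
    sb = nc + NGATE * nc
    maxrec = rec_t.shape[0]
    maxspk = spike_t.shape[1]

    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)

    for k in range(NGATE * nc):
        gate_min[k] = y[nc + k]
        gate_max[k] = y[nc + k]

    rhs(t0, y, k1, gbar, erev, cm, idc, kin,
        syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, gap_i, gap_j, gap_g)

    t = t0
    nrec = 0
    rec_t[0] = t0
    for i in range(nc):
        rec_v[0, i] = y[i]
    nrec = 1
    naccept = 0

    prev_v = np.empty(nc)
    for i in range(nc):
        prev_v[i] = y[i]
    last_sp = np.full(nc, -1.0e9)

    pe = 0
    nev = ext_t.shape[0]
    h = max_step

    while t < t1 - 1e-10:
        hmax = max_step
        if t1 - t < hmax:
            hmax = t1 - t
        if pe < nev:
            dte = ext_t[pe] - t
            if dte > 1e-10 and dte < hmax:
                hmax = dte
        if h > hmax:
            h = hmax

        # attempt steps until accepted
        norm = 0.0
        accepted = False
        for _attempt in range(60):
            # Bogacki-Shampine stages (k1 is FSAL-fresh)
            for i in range(n):
                ytmp[i] = y[i] + 0.5 * h * k1[i]
            rhs(t + 0.5 * h, ytmp, k2, gbar, erev, cm, idc, kin,
                syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, gap_i, gap_j, gap_g)
            for i in range(n):
                ytmp[i] = y[i] + 0.75 * h * k2[i]
            rhs(t + 0.75 * h, ytmp, k3, gbar, erev, cm, idc, kin,
                syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, gap_i, gap_j, gap_g)
            for i in range(n):
                ynew[i] = y[i] + h * (2.0 / 9.0 * k1[i] + 1.0 / 3.0 * k2[i]
                                      + 4.0 / 9.0 * k3[i])
            rhs(t + h, ynew, k4, gbar, erev, cm, idc, kin,
                syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, gap_i, gap_j, gap_g)
            ss = 0.0
            for i in range(n):
                e = h * (5.0 / 72.0 * k1[i] - 1.0 / 12.0 * k2[i]
                         - 1.0 / 9.0 * k3[i] + 1.0 / 8.0 * k4[i])
                ay = abs(y[i])
                ayn = abs(ynew[i])
                sc = atol + rtol * (ay if ay > ayn else ayn)
                e = e / sc
                ss += e * e
            norm = np.sqrt(ss / n)
            if norm <= 1.0:
                accepted = True
                break
            fac = 0.9 * norm ** (-1.0 / 3.0)
            if fac < 0.2:
                fac = 0.2
            h *= fac
            if h < 1e-12:
                return nrec, STEP_FAILURE
        if not accepted:
            return nrec, STEP_FAILURE

        tnew = t + h
        # next step size proposal
        if norm == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * norm ** (-1.0 / 3.0)
            if fac > 5.0:
                fac = 5.0
            if fac < 0.2:
                fac = 0.2
        hnext = h * fac

        for i in range(n):
            y[i] = ynew[i]

        changed = False
        # scheduled external events landing on this step end
        while pe < nev and ext_t[pe] <= tnew + 1e-9:
            s = ext_syn[pe]
            y[sb + 2 * s] += syn_fs[s]
            y[sb + 2 * s + 1] += syn_fs[s]
            pe += 1
            changed = True
        # online spike detection -> internal synaptic events
        for i in range(nc):
            if prev_v[i] < thresh and y[i] >= thresh and tnew - last_sp[i] >= min_isi:
                last_sp[i] = tnew
                if spike_n[i] >= maxspk:
                    return nrec, SPIKE_OVERFLOW
                spike_t[i, spike_n[i]] = tnew
                spike_n[i] += 1
                for s in range(ns):
                    if syn_pre[s] == i:
                        y[sb + 2 * s] += syn_fs[s]
                        y[sb + 2 * s + 1] += syn_fs[s]
                        changed = True
            prev_v[i] = y[i]

        # gating-bound bookkeeping
        for k in range(NGATE * nc):
            g = y[nc + k]
            if g < gate_min[k]:
                gate_min[k] = g
            if g > gate_max[k]:
                gate_max[k] = g

        if changed:
            rhs(tnew, y, k1, gbar, erev, cm, idc, kin,
                syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, gap_i, gap_j, gap_g)
        else:
            for i in range(n):
                k1[i] = k4[i]  # FSAL

        naccept += 1
        if naccept % record_every == 0 or tnew >= t1 - 1e-10:
            if nrec >= maxrec:
                return nrec, RECORD_OVERFLOW
            rec_t[nrec] = tnew
            for i in range(nc):
                rec_v[nrec, i] = y[i]
            nrec += 1

        t = tnew
        h = hnext

    return nrec, OK
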