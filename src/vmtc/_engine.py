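"""Fixed-step implicit cable integrator (numba kernel).

The spatially discretized cable equation is advanced with the staggered
implicit scheme: gating variables are updated by exponential Euler using
tabulated steady-state and per-step decay-factor curves, then the voltage
step is solved implicitly (backward Euler) with a Hines elimination over
the compartment tree.  GHK calcium currents are linearized around the
current voltage with a non-negative slope so the voltage solve stays
unconditionally stable.  The kernel operates on a forest of trees, which
lets whole cohorts of cells be integrated in a single call.

Gate order in the state array:
0 NaF.m, 1 NaF.h, 2 NaP.m, 3 NaP.h, 4 KDR.n, 5 KA.m, 6 KA.h, 7 KM.m,
8 CaL.m, 9 CaT.m, 10 CaT.h, 11 IH.m
Channel order for conductance arrays follows membrane.CHANNEL_NAMES.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_GATES = 12
N_CHANNELS = 10

# voltage grid of the lookup tables
V_TAB_MIN = -180.0
V_TAB_MAX = 60.0
V_TAB_STEP = 0.05
N_TAB = int(round((V_TAB_MAX - V_TAB_MIN) / V_TAB_STEP)) + 1

# return codes
OK = 0
DIVERGED = 1


@njit(cache=True, fastmath=True)
def _lerp(tab, g, pos):
    i = int(pos)
    f = pos - i
    return tab[g, i] * (1.0 - f) + tab[g, i + 1] * f


@njit(cache=True, fastmath=True)
def _lerp1(tab, pos):
    i = int(pos)
    f = pos - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True)
def run(
    # state (modified in place)
    v,            # (n,) mV
    gates,        # (N_GATES, n)
    ca,           # (3, n) mM
    # time stepping
    n_steps,      # int
    dt,           # ms
    # geometry / passive
    parent,       # (n,) int64, -1 for roots
    g_ax,         # (n,) uS to parent
    c_nf,         # (n,) nF
    g_leak,       # (n,) uS
    e_pas,        # mV
    area_s,       # (n,) cm^2 * 1e6 (mA/cm^2 -> nA factor)
    # channels
    g_us,         # (N_CHANNELS, n) uS for ohmic channels; 0 rows for GHK
    p_cms,        # (N_CHANNELS, n) cm/s for GHK channels (CaL=5, CaT=8)
    e_rev,        # (N_CHANNELS,) mV (ignored for GHK rows)
    # gate tables
    inf_tab,      # (N_GATES, N_TAB)
    efac_tab,     # (N_GATES, N_TAB) exp(-dt/tau)
    # GHK tables (z=2)
    ghk_a, ghk_b, ghk_da, ghk_db,  # (N_TAB,)
    cao,          # mM
    # calcium pools
    pool_frac,    # (3,)
    pool_efac,    # (3,) exp(-dt/tau)
    pool_tau,     # (3,)
    ca_rest,      # mM
    ca_k,         # influx factor mM/ms per mA/cm^2
    # calcium-activated gating
    sk_ec50, sk_hill, ano2_ec50, ano2_hill, cal_cdi,
    # stimulus: per compartment constant + per-cell step
    stim_comp,    # (n_cells,) int64 compartment index of injection
    bias_na,      # (n_cells,) nA applied from t=0
    step_na,      # (n_cells,) nA
    step_on,      # (n_cells,) int64 step index
    step_off,     # (n_cells,) int64 step index
    # recording
    rec_comp,     # (n_rec,) int64
    rec_every,    # int
    out_v,        # (n_rec, n_samples) filled with v at sample times
):
    n = v.shape[0]
    n_cells = stim_comp.shape[0]
    d = np.empty(n)
    rhs = np.empty(n)
    inv_step = 1.0 / V_TAB_STEP
    cdt = 1.0 / dt
    sample = 0
    n_samples = out_v.shape[1]
    # record initial values
    if n_samples > 0:
        for r in range(rec_comp.shape[0]):
            out_v[r, 0] = v[rec_comp[r]]
        sample = 1

    for step in range(n_steps):
        for i in range(n):
            vi = v[i]
            if vi < V_TAB_MIN:
                vi_c = V_TAB_MIN
            elif vi > V_TAB_MAX:
                vi_c = V_TAB_MAX
            else:
                vi_c = vi
            pos = (vi_c - V_TAB_MIN) * inv_step
            if pos >= N_TAB - 1:
                pos = N_TAB - 1.000001

            # gate updates (exponential Euler at frozen v)
            for g in range(N_GATES):
                inf = _lerp(inf_tab, g, pos)
                ef = _lerp(efac_tab, g, pos)
                gates[g, i] = inf + (gates[g, i] - inf) * ef

            # calcium current densities (mA/cm^2): CaT is GHK flux, CaL is
            # ohmic (S/cm^2 density) with calcium-dependent inactivation
            a = _lerp1(ghk_a, pos)
            b = _lerp1(ghk_b, pos)
            da = _lerp1(ghk_da, pos)
            db = _lerp1(ghk_db, pos)
            open_cal = gates[8, i] * gates[8, i] * (cal_cdi / (cal_cdi + ca[1, i]))
            m = gates[9, i]
            open_cat = m * m * gates[10, i]
            i_cal = p_cms[5, i] * open_cal * (vi - e_rev[5])
            i_cat = p_cms[8, i] * open_cat * (a * ca[2, i] - b * cao)

            # microdomain updates (influx only; exponential relaxation)
            for p in range(3):
                if p < 2:
                    src = i_cal
                else:
                    src = i_cat
                influx = -pool_frac[p] * src * ca_k
                if influx < 0.0:
                    influx = 0.0
                target = ca_rest + influx * pool_tau[p]
                ca[p, i] = target + (ca[p, i] - target) * pool_efac[p]

            # ohmic conductances
            g_sum = g_leak[i]
            ge_sum = g_leak[i] * e_pas
            # NaF
            mm = gates[0, i]
            gch = g_us[0, i] * mm * mm * mm * gates[1, i]
            g_sum += gch
            ge_sum += gch * e_rev[0]
            # NaP
            mm = gates[2, i]
            gch = g_us[1, i] * mm * mm * mm * gates[3, i]
            g_sum += gch
            ge_sum += gch * e_rev[1]
            # KDR (n^2)
            nn = gates[4, i]
            gch = g_us[2, i] * nn * nn
            g_sum += gch
            ge_sum += gch * e_rev[2]
            # KA
            mm = gates[5, i]
            m4 = mm * mm * mm * mm
            gch = g_us[3, i] * m4 * gates[6, i]
            g_sum += gch
            ge_sum += gch * e_rev[3]
            # KM
            gch = g_us[4, i] * gates[7, i]
            g_sum += gch
            ge_sum += gch * e_rev[4]
            # SK (Hill of pool 0)
            cc = ca[0, i]
            chn = cc ** sk_hill
            act = chn / (chn + sk_ec50 ** sk_hill)
            gch = g_us[6, i] * act
            g_sum += gch
            ge_sum += gch * e_rev[6]
            # ANO2 (Hill of pool 1)
            cc = ca[1, i]
            chn = cc ** ano2_hill
            act = chn / (chn + ano2_ec50 ** ano2_hill)
            gch = g_us[7, i] * act
            g_sum += gch
            ge_sum += gch * e_rev[7]
            # IH
            gch = g_us[9, i] * gates[11, i]
            g_sum += gch
            ge_sum += gch * e_rev[9]
            # CaL (ohmic, implicit)
            gch = p_cms[5, i] * open_cal * area_s[i]
            g_sum += gch
            ge_sum += gch * e_rev[5]

            # GHK linearization (CaT): i(v') ~ i(v) + slope*(v'-v), slope >= 0
            i_ghk_na = i_cat * area_s[i]
            slope = (
                p_cms[8, i] * open_cat * (da * ca[2, i] - db * cao)
            ) * area_s[i]
            if slope < 0.0:
                slope = 0.0

            cd = c_nf[i] * cdt
            d[i] = cd + g_sum + slope
            rhs[i] = cd * vi + ge_sum - i_ghk_na + slope * vi

        # stimulus
        for c in range(n_cells):
            inj = bias_na[c]
            if step_on[c] <= step < step_off[c]:
                inj += step_na[c]
            rhs[stim_comp[c]] += inj

        # axial terms
        for i in range(n):
            p = parent[i]
            if p >= 0:
                d[i] += g_ax[i]
                d[p] += g_ax[i]

        # Hines elimination (children have larger indices than parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            if p >= 0:
                f = g_ax[i] / d[i]
                d[p] -= f * g_ax[i]
                rhs[p] += f * rhs[i]
        for i in range(n):
            p = parent[i]
            if p < 0:
                v[i] = rhs[i] / d[i]
            else:
                v[i] = (rhs[i] + g_ax[i] * v[p]) / d[i]

        # divergence check
        for i in range(n):
            if not (-200.0 < v[i] < 200.0) or v[i] != v[i]:
                return DIVERGED, (step + 1) * dt, sample

        if (step + 1) % rec_every == 0 and sample < n_samples:
            for r in range(rec_comp.shape[0]):
                out_v[r, sample] = v[rec_comp[r]]
            sample += 1

    return OK, n_steps * dt, sample
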