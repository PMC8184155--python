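"""Numba-compiled inner loops of the ring simulator.

These fuse the per-step element-wise work (membrane RK2 with Mg-blocked NMDA
conductance, second-order NMDA gating, event scatter and gating decay) over
the (batch, neuron) arrays.  The numerics are identical to the reference
operations in `lif_core` (same RK2 stages, same spike-time interpolation);
`lif_core` remains the readable specification and serves as the comparison
path in the test suite.  The Mg-block exponential uses a dense lookup table
(0.01 mV grid, linear interpolation, relative error < 5e-8) with an exact
fallback outside the tabulated voltage range.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["membrane_step", "nmda_rk2", "begin_step"]

# exp(-0.062 V) tabulated over V in [-130, 70] mV
_V_LO = -130.0
_V_STEP = 0.01
_N_TAB = 20001
_EXP_TAB = np.exp(-0.062 * (_V_LO + _V_STEP * np.arange(_N_TAB)))


@njit(cache=True, fastmath=True, inline="always")
def _exp_mg(v):
    idx = (v - _V_LO) / _V_STEP
    j = int(idx)
    if j < 0 or j >= _N_TAB - 1:
        return math.exp(-0.062 * v)
    f = idx - j
    return _EXP_TAB[j] * (1.0 - f) + _EXP_TAB[j + 1] * f


@njit(cache=True, fastmath=True)
def membrane_step(vm, ref, t, dt, V_rest, V_th, V_L, gL, Cm, tau_ref, V_I, Mg,
                  g_nmda, g_noise, g_aff_b, sn, sa, sg, g_gaba,
                  decay_ampa, decay_gaba, s0, s1, out_b, out_n, out_t):
    """One RK2 step for one population over a (B, N) batch.

    Start-of-step gating is given by `sn` (noise AMPA), `sa` (afferent AMPA),
    `sg` (B,) (uniform GABA) and the NMDA open fraction `s0`; end-of-step
    AMPA/GABA gating follows by exact exponential decay, and the end-of-step
    NMDA gating is `s1`.  `g_aff_b` is the per-trial afferent conductance.
    `s0`/`s1`/`sa` may have a single column (uniform across the population).
    Spiking neurons are appended to the out arrays; returns the spike count.
    """
    B, N = vm.shape
    inv_Cm = 1.0 / Cm
    inv_357 = 1.0 / 3.57
    s_uniform = s0.shape[1] == 1
    sa_uniform = sa.shape[1] == 1
    cnt = 0
    for b in range(B):
        ci0 = g_gaba * sg[b]
        ci1 = ci0 * decay_gaba
        ga = g_aff_b[b]
        for i in range(N):
            gap = ref[b, i] - t
            if gap >= dt:
                vm[b, i] = V_rest
                continue
            dte = dt - gap if gap > 0.0 else dt
            v0 = V_rest if gap > 0.0 else vm[b, i]
            j = 0 if s_uniform else i
            ja = 0 if sa_uniform else i
            cE0 = g_noise * sn[b, i] + ga * sa[b, ja]
            cE1 = cE0 * decay_ampa
            blk = 1.0 / (1.0 + Mg * _exp_mg(v0) * inv_357)
            I = (g_nmda * s0[b, j] * v0 * blk + ci0 * (v0 - V_I)
                 + cE0 * v0 + gL * (v0 - V_L))
            k1 = -I * inv_Cm
            ve = v0 + dte * k1
            blk = 1.0 / (1.0 + Mg * _exp_mg(ve) * inv_357)
            I = (g_nmda * s1[b, j] * ve * blk + ci1 * (ve - V_I)
                 + cE1 * ve + gL * (ve - V_L))
            k2 = -I * inv_Cm
            vn = v0 + 0.5 * dte * (k1 + k2)
            if vn >= V_th:
                frac = (V_th - v0) / (vn - v0) if vn > v0 else 1.0
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
                ts = t + (dt - dte) + dte * frac
                out_b[cnt] = b
                out_n[cnt] = i
                out_t[cnt] = ts
                cnt += 1
                ref[b, i] = ts + tau_ref
                vm[b, i] = V_rest
            else:
                vm[b, i] = vn
    return cnt


@njit(cache=True, fastmath=True)
def nmda_rk2(x, s, s_out, dt, tau_x, alpha_s, tau_s):
    """Heun step of the second-order NMDA gating; x updated in place, the
    new s written to s_out (the caller keeps the old s as the start-of-step
    drive for the membrane step)."""
    B, N = x.shape
    for b in range(B):
        for i in range(N):
            x0 = x[b, i]
            s0 = s[b, i]
            k1x = -x0 / tau_x
            k1s = alpha_s * x0 * (1.0 - s0) - s0 / tau_s
            x1 = x0 + dt * k1x
            s1 = s0 + dt * k1s
            k2x = -x1 / tau_x
            k2s = alpha_s * x1 * (1.0 - s1) - s1 / tau_s
            xo = x0 + 0.5 * dt * (k1x + k2x)
            so = s0 + 0.5 * dt * (k1s + k2s)
            if so < 0.0:
                so = 0.0
            elif so > 1.0:
                so = 1.0
            x[b, i] = xo
            s_out[b, i] = so
    return None


@njit(cache=True, fastmath=True)
def begin_step(sn_p, sn_i, sa_p, sg_p, sg_i, decay_ampa, decay_gaba,
               ev_b, ev_pos, n, w_noise, noise_to_int,
               x_p, k_table, spk_b, spk_n, alpha_x_p,
               x_i, alpha_x_i_over_n, int_b, inv_m):
    """Start-of-step update, applied in place.

    First-order gating decays from the previous step are applied, then this
    step's increments: background-noise events (ev_b, ev_pos) bump the AMPA
    noise gating of their target by w_noise; the previous step's pyramidal
    spikes bump every postsynaptic NMDA x by alpha_x times the connection
    weight (k_table row for pyr->pyr, 1/n for pyr->int); each previous-step
    interneuron spike bumps the uniform GABA gating by 1/m.
    """
    B, N = sn_p.shape
    M = sn_i.shape[1]
    for b in range(B):
        for i in range(N):
            sn_p[b, i] *= decay_ampa
            sa_p[b, i] *= decay_ampa
        for i in range(M):
            sn_i[b, i] *= decay_ampa
        sg_p[b, 0] *= decay_gaba
        sg_i[b, 0] *= decay_gaba
    for e in range(ev_b.size):
        b = ev_b[e]
        p = ev_pos[e]
        if p < n:
            sn_p[b, p] += w_noise
        elif noise_to_int:
            sn_i[b, p - n] += w_noise
    for j in range(spk_b.size):
        b = spk_b[j]
        row = spk_n[j]
        x_i[b, 0] += alpha_x_i_over_n
        for i in range(N):
            x_p[b, i] += alpha_x_p * k_table[row, i]
    for j in range(int_b.size):
        b = int_b[j]
        sg_p[b, 0] += inv_m
        sg_i[b, 0] += inv_m
    return None
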