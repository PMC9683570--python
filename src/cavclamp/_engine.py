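"""Fixed-step RK4 integrator for the whole-cell clamp circuit.

Units inside the kernel: mV, ms, pA, nS, MOhm, pF.  Handy identities:
1 mV / 1 MOhm = 1 nA = 1e3 pA, and pF * mV/ms = pA, so the membrane equation
``c_m dV/dt = I_pip - I_ion - I_leak - I_out`` balances in pA when
conductances are in nS and resistances in MOhm (with the 1e3 factor on the
resistive terms).

State vector: (V_m, I_filt, m, h, s, b)
  V_m     membrane voltage, mV
  I_filt  low-pass-filtered pipette current used by the series-resistance
          compensation feedback, pA
  m       activation gate (current ~ m^2)
  h       voltage-dependent inactivation gate
  s       Ca-dependent-inactivation sensor: low-pass of the inward ionic
          current in nA; the CDI gate is f = 1 / (1 + cdi_gain * s)
  b       drug-bound (blocked) channel fraction

The kernel is numba-jitted without on-disk caching; the one-time compile cost
is paid per process.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _rhs(vm, ifilt, m, h, s, b, vc,
         gmax, erev, avh, asl, tau_a, vvh, vsl, tau_v,
         cdi_gain, tau_c, rleak_inv, eleak, cm,
         rs, comp, lag_ms, gout, ovh, osl, eout, facil,
         kon_o, kon_i, kon_r, koff, conc, ideal):
    if ideal:
        vm = vc
    f = 1.0 / (1.0 + cdi_gain * s)
    i_ion = gmax * m * m * h * f * (1.0 - b) * facil * (vm - erev)
    i_leak = (vm - eleak) * rleak_inv * 1e3
    i_out = gout / (1.0 + math.exp(-(vm - ovh) / osl)) * (vm - eout)

    if ideal:
        dvm = 0.0
        difilt = 0.0
    else:
        vp = vc + comp * rs * ifilt * 1e-3
        i_pip = (vp - vm) / rs * 1e3
        dvm = (i_pip - i_ion - i_leak - i_out) / cm
        difilt = (i_pip - ifilt) / lag_ms

    minf = 1.0 / (1.0 + math.exp(-(vm - avh) / asl))
    hinf = 1.0 / (1.0 + math.exp((vm - vvh) / vsl))
    dm = (minf - m) / tau_a
    dh = (hinf - h) / tau_v
    drive = -i_ion / 1e3
    if drive < 0.0:
        drive = 0.0
    ds = (drive - s) / tau_c

    p_open = m * m * h * f
    p_inact = m * m * (1.0 - h * f)
    p_rest = 1.0 - m * m
    kon = conc * (kon_o * p_open + kon_i * p_inact + kon_r * p_rest) * 1e-3
    db = kon * (1.0 - b) - koff * 1e-3 * b
    return dvm, difilt, dm, dh, ds, db


@njit(cache=False)
def run_clamp(vcmd, dt,
              gmax, erev, avh, asl, tau_a, vvh, vsl, tau_v,
              cdi_gain, tau_c, rleak_inv, eleak, cm,
              rs, comp, lag_ms, gout, ovh, osl, eout, facil,
              kon_o, kon_i, kon_r, koff, conc, b0):
    """Integrate the clamp over the command nodes ``vcmd`` spaced ``dt`` ms.

    Returns (i_rec, v_m, b_final, p_open_mean, p_inact_mean) where i_rec and
    v_m have the same length as vcmd.  i_rec is the amplifier-reported
    current with the whole-cell capacitance transient ideally neutralized:
    the pipette current minus c_m * dV_m/dt, which by the membrane equation
    equals the ionic + leak + outward current at the true membrane voltage.
    The series-resistance voltage error (and its partially-compensated,
    lag-filtered correction) still shapes V_m; with rs == 0 the clamp is
    ideal and V_m is the command.
    """
    n = vcmd.shape[0]
    ideal = rs <= 0.0

    # rest state at the first command level
    vm = vcmd[0]
    m = 1.0 / (1.0 + math.exp(-(vm - avh) / asl))
    h = 1.0 / (1.0 + math.exp((vm - vvh) / vsl))
    s = 0.0
    b = b0
    f0 = 1.0
    i0 = (gmax * m * m * h * f0 * (1.0 - b) * facil * (vm - erev)
          + (vm - eleak) * rleak_inv * 1e3
          + gout / (1.0 + math.exp(-(vm - ovh) / osl)) * (vm - eout))
    ifilt = i0

    i_rec = np.empty(n)
    v_out = np.empty(n)
    po_sum = 0.0
    pi_sum = 0.0

    for i in range(n):
        if ideal:
            vm = vcmd[i]
        f = 1.0 / (1.0 + cdi_gain * s)
        i_rec[i] = (gmax * m * m * h * f * (1.0 - b) * facil * (vm - erev)
                    + (vm - eleak) * rleak_inv * 1e3
                    + gout / (1.0 + math.exp(-(vm - ovh) / osl)) * (vm - eout))
        v_out[i] = vm
        po_sum += m * m * h * f
        pi_sum += m * m * (1.0 - h * f)

        if not math.isfinite(vm) or not math.isfinite(i_rec[i]):
            # solver blow-up: report the offending node via NaN sentinel
            i_rec[i] = np.nan
            return i_rec, v_out, b, po_sum / (i + 1.0), pi_sum / (i + 1.0)

        if i == n - 1:
            break

        v1 = vcmd[i]
        v4 = vcmd[i + 1]
        v23 = 0.5 * (v1 + v4)

        k1 = _rhs(vm, ifilt, m, h, s, b, v1,
                  gmax, erev, avh, asl, tau_a, vvh, vsl, tau_v,
                  cdi_gain, tau_c, rleak_inv, eleak, cm,
                  rs, comp, lag_ms, gout, ovh, osl, eout, facil,
                  kon_o, kon_i, kon_r, koff, conc, ideal)
        k2 = _rhs(vm + 0.5 * dt * k1[0], ifilt + 0.5 * dt * k1[1],
                  m + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3],
                  s + 0.5 * dt * k1[4], b + 0.5 * dt * k1[5], v23,
                  gmax, erev, avh, asl, tau_a, vvh, vsl, tau_v,
                  cdi_gain, tau_c, rleak_inv, eleak, cm,
                  rs, comp, lag_ms, gout, ovh, osl, eout, facil,
                  kon_o, kon_i, kon_r, koff, conc, ideal)
        k3 = _rhs(vm + 0.5 * dt * k2[0], ifilt + 0.5 * dt * k2[1],
                  m + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3],
                  s + 0.5 * dt * k2[4], b + 0.5 * dt * k2[5], v23,
                  gmax, erev, avh, asl, tau_a, vvh, vsl, tau_v,
                  cdi_gain, tau_c, rleak_inv, eleak, cm,
                  rs, comp, lag_ms, gout, ovh, osl, eout, facil,
                  kon_o, kon_i, kon_r, koff, conc, ideal)
        k4 = _rhs(vm + dt * k3[0], ifilt + dt * k3[1],
                  m + dt * k3[2], h + dt * k3[3],
                  s + dt * k3[4], b + dt * k3[5], v4,
                  gmax, erev, avh, asl, tau_a, vvh, vsl, tau_v,
                  cdi_gain, tau_c, rleak_inv, eleak, cm,
                  rs, comp, lag_ms, gout, ovh, osl, eout, facil,
                  kon_o, kon_i, kon_r, koff, conc, ideal)

        sixth = dt / 6.0
        vm += sixth * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        ifilt += sixth * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        m += sixth * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        h += sixth * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
        s += sixth * (k1[4] + 2.0 * k2[4] + 2.0 * k3[4] + k4[4])
        b += sixth * (k1[5] + 2.0 * k2[5] + 2.0 * k3[5] + k4[5])
        if m < 0.0:
            m = 0.0
        if h < 0.0:
            h = 0.0
        if s < 0.0:
            s = 0.0
        if b < 0.0:
            b = 0.0
        elif b > 1.0:
            b = 1.0

    return i_rec, v_out, b, po_sum / n, pi_sum / n
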