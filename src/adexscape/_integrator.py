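"""Compiled forward-Euler kernel for the AdEx equations.

Kept separate from :mod:`adexscape.model` so the numba dependency stays
contained; the wrapper there owns all validation and unit conventions.
"""

import numpy as np
from numba import njit

_EXP_ARG_MAX = 30.0


@njit(cache=False)
def adex_euler(
    C,
    g_L,
    E_L,
    Delta_T,
    V_th,
    a,
    b,
    tau_w,
    V_reset,
    V_peak,
    ref_steps,
    holding_current,
    step_amplitude,
    stim_delay,
    stim_end,
    v0,
    w0,
    dt,
    n,
):
    """Integrate n samples; returns (V, w, spike_indices, fail_index).

    fail_index is -1 on success, otherwise the first sample index at which the
    state was non-finite.  At a spike the stored sample is clamped to V_peak
    (so recorded voltages never exceed it) while the integration state jumps
    to V_reset; w receives its Euler update first and +b afterwards.  Both
    state variables are then held constant for ref_steps samples.
    """
    V = np.empty(n)
    w = np.empty(n)
    spikes = np.empty(n, dtype=np.int64)
    n_spikes = 0

    V[0] = v0
    w[0] = w0
    v = v0
    wv = w0
    ref = 0

    for k in range(n - 1):
        if ref > 0:
            ref -= 1
            V[k + 1] = v
            w[k + 1] = wv
            continue
        t = k * dt
        if stim_delay <= t < stim_end:
            I = holding_current + step_amplitude
        else:
            I = holding_current
        arg = (v - V_th) / Delta_T
        if arg > _EXP_ARG_MAX:
            arg = _EXP_ARG_MAX
        dv = (-g_L * (v - E_L) + g_L * Delta_T * np.exp(arg) + I - wv) / C
        dw = (a * (v - E_L) - wv) / tau_w
        vn = v + dt * dv
        wn = wv + dt * dw
        if not (np.isfinite(vn) and np.isfinite(wn)):
            return V, w, spikes[:n_spikes], k + 1
        if vn >= V_peak:
            wn = wn + b
            V[k + 1] = V_peak
            w[k + 1] = wn
            spikes[n_spikes] = k + 1
            n_spikes += 1
            v = V_reset
            wv = wn
            ref = ref_steps
        else:
            V[k + 1] = vn
            w[k + 1] = wn
            v = vn
            wv = wn

    return V, w, spikes[:n_spikes], -1
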