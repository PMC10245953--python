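"""Low-level numerical kernels (numba-compiled).

Two primitives live here:

* exact sampling of a superposition of biexponential synaptic waveforms
  driven by weighted point events (``biexp_trace``), and
* the exponential-Euler integrate-and-fire loop, either driven by
  precomputed conductance arrays (``lif_traces``) or fused with on-the-fly
  conductance synthesis (``lif_fused``) so that arbitrarily long runs need
  O(events) rather than O(samples) memory.

A biexponential g(t) = A*(exp(-t/tau_d) - exp(-t/tau_r))/N is tracked by two
decaying sums (one per exponential).  Each is advanced exactly by
``exp(-dt/tau)`` per sample and incremented by ``w*exp(-(t_i - t_s)/tau)``
for every event t_s falling in the last sample interval, so the sampled
trace equals the continuous superposition at the sample points to machine
precision (no kernel truncation).

State convention for chunked runs: the conductance states passed in/out are
the decaying-sum values at the *last sample already processed*; events
supplied to a chunk must lie in (t_last_processed, t_end_of_chunk].

All times in milliseconds, conductances in nS, potentials in mV,
capacitance in pF (so Cm/g is directly in ms).
"""

import numpy as np
from numba import njit

__all__ = ["biexp_trace", "lif_traces", "lif_fused"]


@njit(cache=True)
def biexp_trace(times, weights, tau_r, tau_d, norm, dt, n_samples, t0, dd0, dr0):
    """Sample weighted biexponential shot noise at t0 + i*dt, i = 0..n-1.

    ``times`` must be sorted ascending and lie in (t0 - dt, t0 + (n-1)*dt].
    ``dd0``/``dr0`` are the exponential-sum states at time t0 - dt.
    Returns (trace, dd_end, dr_end).
    """
    g = np.zeros(n_samples)
    ed = np.exp(-dt / tau_d)
    er = np.exp(-dt / tau_r)
    dd = dd0
    dr = dr0
    j = 0
    n_ev = times.shape[0]
    for i in range(n_samples):
        dd *= ed
        dr *= er
        ti = t0 + i * dt
        while j < n_ev and times[j] <= ti:
            lag = ti - times[j]
            dd += weights[j] * np.exp(-lag / tau_d)
            dr += weights[j] * np.exp(-lag / tau_r)
            j += 1
        g[i] = (dd - dr) / norm
    return g, dd, dr


@njit(cache=True)
def lif_traces(gE, gI, Cm, gL, VL, VE, VI, theta, Vr, ref_steps, dt, V0, ref0):
    """Exponential-Euler LIF driven by conductance arrays sampled on one grid.

    Conductances are held at their start-of-step value across each step
    (exact for piecewise-constant inputs).  A threshold crossing is recorded
    at the end of the step; V is then clamped at Vr for ``ref_steps`` steps.
    Returns (spike_step_indices, V_trace, ref_left_end).
    """
    n = gE.shape[0]
    V = np.empty(n)
    V[0] = V0
    ref_left = ref0
    spikes = np.empty(n, np.int64)
    ns = 0
    for i in range(n - 1):
        if ref_left > 0:
            V[i + 1] = Vr
            ref_left -= 1
        else:
            gtot = gE[i] + gI[i] + gL
            vinf = (gE[i] * VE + gI[i] * VI + gL * VL) / gtot
            v = vinf + (V[i] - vinf) * np.exp(-dt * gtot / Cm)
            if v >= theta:
                spikes[ns] = i + 1
                ns += 1
                v = Vr
                ref_left = ref_steps
            V[i + 1] = v
    return spikes[:ns], V, ref_left


@njit(cache=True)
def lif_fused(tI, wI, tE, wE,
              trI, tdI, normI, trE, tdE, normE,
              Cm, gL, VL, VE, VI, theta, Vr, ref_steps,
              dt, n_steps, t0, stat_from,
              V0, ref0, ddI0, drI0, ddE0, drE0):
    """LIF integration fused with conductance synthesis for one time chunk.

    Integrates ``n_steps`` steps starting from absolute time ``t0`` (ms);
    membrane potential is defined at samples t0 + i*dt for i = 0..n_steps.
    Event arrays must be sorted and lie in (t0 - dt, t0 + (n_steps-1)*dt]
    (events in the final step interval would first be felt at the sample
    after the chunk, so the caller routes them to the next chunk).

    ``stat_from`` (absolute ms): samples at t >= stat_from contribute to the
    running conductance moments (burn-in exclusion).

    Returns (spike_times_ms_absolute, state, gi_moments, ge_moments) where
    state = (V, ref_left, ddI, drI, ddE, drE) at the last processed sample
    and each moments triple is (n, sum, sum_of_squares).
    """
    edI = np.exp(-dt / tdI)
    erI = np.exp(-dt / trI)
    edE = np.exp(-dt / tdE)
    erE = np.exp(-dt / trE)
    ddI = ddI0
    drI = drI0
    ddE = ddE0
    drE = drE0
    V = V0
    ref_left = ref0
    jI = 0
    jE = 0
    nI = tI.shape[0]
    nE = tE.shape[0]
    max_spikes = n_steps // (ref_steps + 1) + 2
    out = np.empty(max_spikes)
    ns = 0
    n_stat = 0
    s_gI = 0.0
    ss_gI = 0.0
    s_gE = 0.0
    ss_gE = 0.0
    for i in range(n_steps):
        ti = t0 + i * dt
        ddI *= edI
        drI *= erI
        ddE *= edE
        drE *= erE
        while jI < nI and tI[jI] <= ti:
            lag = ti - tI[jI]
            ddI += wI[jI] * np.exp(-lag / tdI)
            drI += wI[jI] * np.exp(-lag / trI)
            jI += 1
        while jE < nE and tE[jE] <= ti:
            lag = ti - tE[jE]
            ddE += wE[jE] * np.exp(-lag / tdE)
            drE += wE[jE] * np.exp(-lag / trE)
            jE += 1
        gI = (ddI - drI) / normI
        gE = (ddE - drE) / normE
        if ti >= stat_from:
            n_stat += 1
            s_gI += gI
            ss_gI += gI * gI
            s_gE += gE
            ss_gE += gE * gE
        if ref_left > 0:
            V = Vr
            ref_left -= 1
        else:
            gtot = gE + gI + gL
            vinf = (gE * VE + gI * VI + gL * VL) / gtot
            V = vinf + (V - vinf) * np.exp(-dt * gtot / Cm)
            if V >= theta:
                out[ns] = ti + dt
                ns += 1
                V = Vr
                ref_left = ref_steps
    return (out[:ns], (V, ref_left, ddI, drI, ddE, drE),
            (n_stat, s_gI, ss_gI), (n_stat, s_gE, ss_gE))
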