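"""Point-conductance integrate-and-fire model of a cerebellar nuclei neuron.

The membrane potential obeys

    Cm dV/dt = gE(t)(VE - V) + gI(t)(VI - V) + gL(VL - V)

with a spike recorded when V reaches the threshold theta, followed by a
2 ms refractory period during which V is clamped at the reset Vr while the
synaptic conductances keep evolving.  Integration is exponential Euler with
conductances held at their start-of-step value, which is exact in the
constant-conductance limit; the matching closed-form ISI for constant
inputs serves as an analytic oracle.

Two parameter presets are provided.  ``CORRELOGRAM_PRESET`` (Cm = 50 pF,
gL = 8.8 nS, VL = -40 mV, 20 000 excitatory events/s) is used for
spike-timing / cross-correlogram studies; ``RATE_PRESET`` (Cm = 200 pF,
gL = 5 nS, VL = -10 mV, 23 650 events/s) for firing-rate, rate-code and
synchrony studies.  Both use VE = 0, VI = -75, theta = -50, Vr = -60 mV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._core import lif_fused, lif_traces
from .conductance import (ConductanceTrace, UnitaryKernel, epsg_kernel,
                          ipsg_kernel)
from .spike_gen import SpikeTrain

__all__ = [
    "NeuronParams",
    "SimResult",
    "GStats",
    "CORRELOGRAM_PRESET",
    "RATE_PRESET",
    "PRESETS",
    "closed_form_isi",
    "closed_form_rate",
    "simulate",
    "simulate_streaming",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF cell parameters: Cm pF, conductances nS, potentials mV, t_ref ms."""

    Cm: float
    gL: float
    VL: float
    VE: float = 0.0
    VI: float = -75.0
    theta: float = -50.0
    Vr: float = -60.0
    t_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.gL <= 0:
            raise ValueError("Cm and gL must be > 0")
        if self.Vr >= self.theta:
            raise ValueError("reset must lie below threshold")


CORRELOGRAM_PRESET = NeuronParams(Cm=50.0, gL=8.8, VL=-40.0)
RATE_PRESET = NeuronParams(Cm=200.0, gL=5.0, VL=-10.0)

#: preset name -> (NeuronParams, default excitatory event rate /s)
PRESETS: dict[str, tuple[NeuronParams, float]] = {
    "fig2": (CORRELOGRAM_PRESET, 20_000.0),
    "fig4_6": (RATE_PRESET, 23_650.0),
}


class GStats(NamedTuple):
    """Running conductance moments collected after burn-in."""

    mean: float
    sd: float
    cv: float


@dataclass(frozen=True)
class SimResult:
    """Output of one simulation run."""

    spikes: SpikeTrain
    params: NeuronParams
    dt: float
    duration: float
    seed: int | None = None
    v_trace: np.ndarray | None = None
    v_times_ms: np.ndarray | None = None
    gi_stats: GStats | None = None
    ge_stats: GStats | None = None

    @property
    def n_spikes(self) -> int:
        return self.spikes.n_spikes


def closed_form_isi(params: NeuronParams, gE_const: float, gI_const: float) -> float:
    """Analytic interspike interval (ms) for constant conductances.

    V relaxes toward V_inf = (gE VE + gI VI + gL VL) / (gE + gI + gL) with
    time constant tau = Cm / (gE + gI + gL); spiking requires V_inf > theta,
    otherwise the interval is infinite.
    """
    if gE_const < 0 or gI_const < 0:
        raise ValueError("conductances must be >= 0")
    gtot = gE_const + gI_const + params.gL
    v_inf = (gE_const * params.VE + gI_const * params.VI
             + params.gL * params.VL) / gtot
    if v_inf <= params.theta:
        return float("inf")
    tau = params.Cm / gtot
    return params.t_ref + tau * float(
        np.log((v_inf - params.Vr) / (v_inf - params.theta)))


def closed_form_rate(params: NeuronParams, gE_const: float, gI_const: float) -> float:
    """Steady firing rate (spikes/s) for constant conductances; 0 if silent."""
    isi = closed_form_isi(params, gE_const, gI_const)
    return 0.0 if np.isinf(isi) else 1e3 / isi


def _ref_steps(params: NeuronParams, dt: float) -> int:
    return int(round(params.t_ref / dt))


def simulate(params: NeuronParams, gE: ConductanceTrace, gI: ConductanceTrace,
             duration: float | None = None, record_v: bool = False,
             v_decimate: int = 1) -> SimResult:
    """Integrate the model over precomputed conductance traces.

    ``gE`` and ``gI`` must share one sampling grid; ``duration`` (s) may
    shorten but not exceed the traces.  ``record_v`` keeps the membrane
    trace (decimated by ``v_decimate``) for inspection.
    """
    if gE.dt != gI.dt or gE.n_samples != gI.n_samples:
        raise ValueError("gE and gI must be sampled on the same grid")
    dt = gE.dt
    n = gE.n_samples
    if duration is not None:
        n_req = int(round(duration * 1e3 / dt)) + 1
        if n_req > n:
            raise ValueError("duration exceeds trace length")
        n = n_req
    else:
        duration = (n - 1) * dt * 1e-3
    spike_idx, v, _ = lif_traces(
        gE.values[:n], gI.values[:n], params.Cm, params.gL, params.VL,
        params.VE, params.VI, params.theta, params.Vr,
        _ref_steps(params, dt), dt, params.Vr, 0)
    times_s = spike_idx * dt * 1e-3
    train = SpikeTrain(times_s[times_s < duration], duration, "output")
    v_out = v[::v_decimate].copy() if record_v else None
    v_t = (np.arange(n)[::v_decimate] * dt).astype(float) if record_v else None
    return SimResult(train, params, dt, duration, v_trace=v_out, v_times_ms=v_t)


def simulate_streaming(params: NeuronParams,
                       inh_times_ms: np.ndarray,
                       inh_weights: np.ndarray,
                       duration: float,
                       exc_event_rate: float,
                       rng: np.random.Generator,
                       dt: float = 0.02,
                       inh_kernel: UnitaryKernel | None = None,
                       exc_kernel: UnitaryKernel | None = None,
                       burn_in: float = 1.0,
                       chunk_s: float = 50.0,
                       seed: int | None = None) -> SimResult:
    """Memory-bounded run: conductance synthesis fused with integration.

    Inhibitory input is a merged, sorted, weighted event stream (ms / nS;
    see :func:`cbnsim.conductance.merge_events`); excitatory events are a
    homogeneous Poisson stream of rate ``exc_event_rate`` (events/s) with
    unit amplitude ``exc_kernel.amplitude``, drawn chunk by chunk from
    ``rng``.  Conductance moments are accumulated on the fly over the
    window after ``burn_in`` seconds and returned in the result, so even
    multi-thousand-second runs never materialize a full trace.

    The integration is step-for-step identical to :func:`simulate` on the
    equivalent precomputed traces.
    """
    if inh_kernel is None:
        inh_kernel = ipsg_kernel()
    if exc_kernel is None:
        exc_kernel = epsg_kernel()
    if exc_event_rate < 0:
        raise ValueError("exc_event_rate must be >= 0")
    dur_ms = duration * 1e3
    n_total = int(round(dur_ms / dt))
    ref_steps = _ref_steps(params, dt)
    steps_per_chunk = max(1, int(round(chunk_s * 1e3 / dt)))
    state = (params.Vr, 0, 0.0, 0.0, 0.0, 0.0)
    spikes: list[np.ndarray] = []
    nI = sI = ssI = 0.0
    nE = sE = ssE = 0.0
    stat_from = burn_in * 1e3
    step0 = 0
    while step0 < n_total:
        n_steps = min(steps_per_chunk, n_total - step0)
        t0 = step0 * dt
        t_end = (step0 + n_steps - 1) * dt  # last absorbed sample
        lo_t = t0 - dt
        sel = (inh_times_ms > lo_t) & (inh_times_ms <= t_end)
        tI = np.ascontiguousarray(inh_times_ms[sel])
        wI = np.ascontiguousarray(inh_weights[sel])
        span_ms = t_end - lo_t
        n_exc = rng.poisson(exc_event_rate * span_ms * 1e-3)
        tE = np.sort(rng.uniform(lo_t, t_end, n_exc))
        tE = tE[tE > lo_t]
        wE = np.full(tE.size, exc_kernel.amplitude)
        out, state, (cn, cs, css), (en, es, ess) = lif_fused(
            tI, wI, tE, wE,
            inh_kernel.tau_rise, inh_kernel.tau_decay, inh_kernel.norm,
            exc_kernel.tau_rise, exc_kernel.tau_decay, exc_kernel.norm,
            params.Cm, params.gL, params.VL, params.VE, params.VI,
            params.theta, params.Vr, ref_steps,
            dt, n_steps, t0, stat_from,
            state[0], state[1], state[2], state[3], state[4], state[5])
        spikes.append(out)
        nI += cn
        sI += cs
        ssI += css
        nE += en
        sE += es
        ssE += ess
        step0 += n_steps
    times_s = (np.concatenate(spikes) if spikes else np.empty(0)) * 1e-3
    train = SpikeTrain(times_s[times_s < duration], duration, "output")

    def _stats(n: float, s: float, ss: float) -> GStats | None:
        if n == 0:
            return None
        mean = s / n
        var = max(ss / n - mean * mean, 0.0)
        sd = var ** 0.5
        return GStats(mean, sd, sd / mean if mean > 0 else float("nan"))

    return SimResult(train, params, dt, duration, seed=seed,
                     gi_stats=_stats(nI, sI, ssI), ge_stats=_stats(nE, sE, ssE))
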