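# Methods

`cbnsim` simulates how a population of inhibitory Purkinje-cell (PC)
synapses with highly nonuniform strengths controls the firing rate and
spike timing of a cerebellar nuclei (CbN) projection neuron. This note
documents the model, its parameters, the numerical choices, and what the
synthetic data do and do not capture.

## Model

### Presynaptic spike trains

PCs fire tonically and regularly. Each input's interspike intervals (ISIs)
are drawn i.i.d. from a lognormal distribution whose standard deviation is
tied to its mean by the empirical linear relation

    sd_isi = -0.00154 + 0.583 * mean_isi     (seconds),

so specifying a target rate fixes the whole distribution (moment inversion
gives the natural-log parameters: sigma^2 = ln(1 + (sd/mean)^2), mu =
ln(mean) - sigma^2/2). The relation requires rate < ~378.6 spikes/s, above
which the implied sd would be negative; the generator rejects such rates.
The lognormal shape concentrates mass away from zero, giving the
refractory-like regularity of PC firing without an explicit hard refractory
period (none is imposed). A memoryless Poisson family (exponential ISIs)
serves as the no-refractoriness control, and a `resampled` family draws
ISIs with replacement from a user-supplied pool for users who have their
own recordings.

Trains start stationary: the first spike is placed at a uniform random
fraction of one drawn ISI. Perfect synchrony is modeled by letting a group
of inputs share one spike train verbatim, which makes k synchronized
equal-amplitude inputs arithmetically identical to a single input of k-fold
amplitude (the package exploits this by merging coincident events before
synthesis, so the equivalence is exact to the bit).

### Synaptic conductances

Each spike contributes a peak-normalized biexponential conductance
`A*(exp(-t/tau_d) - exp(-t/tau_r))/N`. Inhibitory kinetics: tau_r =
0.1 ms, tau_d = 2.5 ms, reversal -75 mV; the per-unit-amplitude time
integral is 2.8589 nS*ms. Excitatory mossy-fiber events: A = 0.4 nS, tau_r
= 0.28 ms, tau_d = 1.06 ms, reversal 0 mV (integral 0.6838 nS*ms). The
"rise/decay times" are interpreted as the two exponential time constants.

Unitary inhibitory amplitudes measured in voltage clamp with a high-Cl
internal are corrected by x0.4 (synaptic depression at physiological rates)
and /2.3 (Cl-driven overestimate). The corrected input-size distribution is
represented two ways: a fixed simplified triplet (16 x 3 + 10 x 10 +
2 x 30 nS, nominal total 200 nS) used for spike-triggered analyses, and a
categorical sampling distribution over {3, 10, 30} nS with weights
{16, 10, 2}/28 used when weight sets are drawn to a target total. Draws
accumulate until the total first reaches the target and are rejected and
restarted if the overshoot exceeds 5%.

### Postsynaptic neuron

A point-conductance leaky integrate-and-fire cell:

    Cm dV/dt = gE(t)(VE - V) + gI(t)(VI - V) + gL(VL - V)

with a spike when V reaches theta = -50 mV, followed by a 2 ms refractory
period (V clamped at the reset Vr = -60 mV while conductances keep
evolving, integration resuming from Vr). Two presets:

| preset | Cm (pF) | gL (nS) | VL (mV) | exc events/s | used for |
|---|---|---|---|---|---|
| `fig2` (correlogram) | 50 | 8.8 | -40 | 20 000 | spike-timing / cross-correlograms |
| `fig4_6` (rate) | 200 | 5 | -10 | 23 650 | rate, rate-code and synchrony scans |

With no synaptic input the rate preset fires tonically at ISI = 2 +
40*ln(50/40) = 10.93 ms (91.5 spikes/s), which doubles as an analytic
oracle: for any constant (gE, gI) the ISI is t_ref +
(Cm/g_tot)*ln((V_inf - Vr)/(V_inf - theta)) with V_inf the conductance-
weighted reversal, or infinite when V_inf <= theta.

## Numerics

* **Exact synthesis.** Conductances are sums of two decaying exponentials,
  tracked in closed form: each state decays by exp(-dt/tau) per sample and
  absorbs events with their exact partial-interval decay. Sampled traces
  therefore equal the continuous superposition at the grid points to
  machine precision; there is no kernel-tail truncation.
* **Integration.** Exponential Euler with conductances held at their
  start-of-step value -- unconditionally stable and exact in the
  constant-conductance limit, so the oracle equivalence is a sharp test.
  Threshold crossings are recorded at the end of the step (no sub-step
  interpolation). Default dt = 0.02 ms resolves the 0.1 ms inhibitory rise
  with five samples; halving dt changes mean rates by < 1% (tested).
* **Streaming runs.** Long simulations use a fused event-driven loop
  (conductance synthesis + integration in one numba kernel, chunked in
  50 s blocks with exact state carryover), needing O(events) memory and
  ~0.2 s per 100 simulated seconds. It is step-for-step identical to the
  trace-based path (tested at the 1e-12 level).
* **Initialization.** V(0) = Vr; a 1 s burn-in is discarded from all
  statistics (stands in for the slow experimental ramp-in used to avoid
  startup adaptation in real cells).
* **Correlograms.** Accumulative histograms of target-spike lags within
  +/-10 ms of every reference spike, divided by (n_ref * bin width); bin
  width defaults to 0.1 ms. Normalization divides by the output's mean
  rate, putting the independent-train baseline at 1. From the normalized
  input->output correlogram: e = max excess above 1 over lags [-4, 0] ms,
  i = 1 - minimum over [0, +6] ms, and t_half = lag from the trough to the
  first bin back at 1 - i/2. With a saturated (flat-at-minimum) trough the
  trough lag is taken as the *last* minimal bin, so t_half measures the
  recovery phase rather than the shutdown plateau. The e/i windows are a
  package choice bracketing the observed features; both are configurable.

## Scaled protocols

Reference protocols are long (e.g. 160,000 s per cell for per-input
correlograms). Runners accept a duration scale; the shipped defaults and
the acceptance script use sizes at which the quantities of interest are
stable to well within their tolerances: 5,000 s for the triplet
correlogram run (per-bin counting error < 2% for the pooled 3 nS class),
20 draws x 200 s for the synchrony comparison, 10 x 100 s per point for
the rate-code endpoints, 100,000 ISIs per rate for the generator
regression.

## What the synthetic data do not capture

* ISIs are i.i.d. within a train (a renewal process): no slow rate
  modulation, bursting, or complex spikes. Rates are piecewise constant
  per run.
* Short-term depression enters only as the static x0.4 amplitude
  correction; no dynamic plasticity.
* The corrected empirical size distribution is represented by a 3-point
  categorical surrogate. This matches the class structure used for
  spike-triggered analyses but truncates the continuous tail above 30 nS,
  so drawn weight sets have a somewhat smaller sum of squared amplitudes
  -- hence a smaller conductance CV and lower fluctuation-driven firing --
  than sets drawn from the unpublished continuous list. Rate-preset
  baseline rates here run ~15% below the published example cell for this
  reason, while relative effects (rate-code transfer ratio, synchrony
  percent changes, correlogram shapes) agree. Users with their own
  measured size lists can supply them via the `user_list` distribution
  kind.
* The excitatory drive is an unstructured Poisson stream; real
  mossy-fiber input carries its own temporal structure.
* The neuron is passive between spikes: no rebound currents, adaptation,
  or dendritic structure. Passing tests show that the fluctuation-driven
  firing mechanism reproduces the reference phenomena, not that these
  intrinsic conductances are negligible in general.
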