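"""Scenario runners wiring generation, synthesis, simulation and analysis.

Each runner reproduces one family of in-silico experiments:

* ``run_size_crosscorr`` — input->output cross-correlograms and (e, i,
  t_half) per input-size class for the simplified triplet drive
  (correlogram preset, 83 spikes/s lognormal inputs).
* ``run_refractory_comparison`` — spike-triggered average conductance and
  cross-correlograms for lognormal inputs at 49/83/122 spikes/s versus a
  Poisson control, total inhibition matched across cases.
* ``run_cv_rate_scan`` — firing rate versus mean and CV of the total
  inhibitory conductance across uniform and nonuniform weight sets.
* ``run_rate_code_scan`` — output rate as one input's rate varies while the
  others hold 80 spikes/s (the rate-code transfer curve and its slope).
* ``run_synchrony_scan`` — rate (and optionally timing) effects of making
  subsets of inputs perfectly synchronous.

Every runner is a pure function of (configuration, seed): rerunning with
the same arguments reproduces its outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .analysis import (Correlogram, EITMetrics, extract_eit, firing_rate,
                       normalize_correlogram, pooled_correlogram,
                       spike_triggered_average)
from .conductance import (SizeDistribution, assemble_inhibition,
                          empirical_surrogate, generate_excitation,
                          merge_events, sample_sizes, simplified_triplet)
from .neuron import (PRESETS, NeuronParams, SimResult, simulate,
                     simulate_streaming)
from .spike_gen import (ISISpec, SpikeTrain, SynchronyGroup, assign_synchrony,
                        lognormal_params_from_rate, poisson_spec)

__all__ = [
    "ExperimentConfig",
    "run_cell",
    "run_size_crosscorr",
    "run_refractory_comparison",
    "run_cv_rate_scan",
    "run_rate_code_scan",
    "run_synchrony_scan",
    "export_waveform",
    "import_spikes",
]

logger = logging.getLogger("cbnsim")


@dataclass
class ExperimentConfig:
    """Declarative description of one simulated cell.

    ``preset`` fixes the neuron parameters and default excitatory event
    rate ("fig2": correlogram preset, "fig4_6": rate preset).  ``scale``
    multiplies ``duration`` so long reference protocols can be run
    shortened with proportionally wider counting error.
    """

    preset: str = "fig4_6"
    duration: float = 100.0
    dt: float = 0.02
    seed: int = 0
    input_rate: float = 80.0
    total_target: float = 200.0
    exc_event_rate: float | None = None
    burn_in: float = 1.0
    scale: float = 1.0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.duration * self.scale <= self.burn_in:
            raise ValueError("duration must exceed the burn-in")

    @property
    def params(self) -> NeuronParams:
        return PRESETS[self.preset][0]

    @property
    def exc_rate(self) -> float:
        return (PRESETS[self.preset][1] if self.exc_event_rate is None
                else self.exc_event_rate)

    @property
    def scaled_duration(self) -> float:
        return self.duration * self.scale

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _log_run(cfg_hash: str, seed: int, result: SimResult) -> None:
    gi = result.gi_stats
    logger.info(
        "run config=%s seed=%s rate=%.2f mean_gI=%s cv_gI=%s",
        cfg_hash, seed, firing_rate(result.spikes, min(1.0, result.duration / 2)),
        f"{gi.mean:.2f}" if gi else "na", f"{gi.cv:.3f}" if gi else "na")


def _after(train: SpikeTrain, t0: float) -> SpikeTrain:
    return SpikeTrain(train.times[train.times >= t0], train.duration,
                      train.unit_id)


def run_cell(params: NeuronParams,
             weights: Sequence[float],
             trains: Sequence[SpikeTrain],
             exc_rate: float,
             duration: float,
             rng: np.random.Generator,
             dt: float = 0.02,
             burn_in: float = 1.0) -> SimResult:
    """Simulate one cell from per-input spike trains and weights."""
    t_ms, w = merge_events([t.times for t in trains], list(weights))
    return simulate_streaming(params, t_ms, w, duration, exc_rate, rng, dt=dt,
                              burn_in=burn_in)


def _make_trains(rates: Sequence[float | str], duration: float,
                 seed_seq: np.random.SeedSequence,
                 groups: Sequence[SynchronyGroup] = (),
                 ) -> list[SpikeTrain]:
    """Per-input trains; a rate entry "poissonR" selects the Poisson family."""
    inputs: list[tuple[str, ISISpec]] = []
    for k, r in enumerate(rates):
        if isinstance(r, str) and r.startswith("poisson"):
            spec: ISISpec = poisson_spec(float(r[len("poisson"):]))
        else:
            spec = lognormal_params_from_rate(float(r))
        inputs.append((f"inh{k:03d}", spec))
    trains = assign_synchrony(inputs, groups, duration, seed_seq)
    return [trains[lab] for lab, _ in inputs]


@dataclass(frozen=True)
class SizeCrosscorrResult:
    """Per-size-class pooled correlograms and metrics for one cell."""

    output_rate: float
    by_size: dict[float, tuple[Correlogram, EITMetrics]]
    result: SimResult
    weights: np.ndarray


def run_size_crosscorr(config: ExperimentConfig | None = None,
                       weights: Sequence[float] | None = None,
                       input_rate: float = 83.0,
                       bin_width: float = 0.1) -> SizeCrosscorrResult:
    """Cross-correlogram / (e, i, t_half) per input-size class.

    Defaults to the correlogram preset driven by the simplified triplet
    (16 x 3 + 10 x 10 + 2 x 30 nS) at 83 spikes/s.  Correlograms are pooled
    over all inputs sharing one amplitude.
    """
    if config is None:
        config = ExperimentConfig(preset="fig2", duration=5000.0)
    if weights is None:
        weights = simplified_triplet().values
    weights = np.asarray(weights, dtype=float)
    duration = config.scaled_duration
    ss = np.random.SeedSequence(config.seed)
    ss_trains, ss_exc = ss.spawn(2)
    trains = _make_trains([input_rate] * len(weights), duration, ss_trains)
    res = run_cell(config.params, weights, trains, config.exc_rate, duration,
                   np.random.default_rng(ss_exc), dt=config.dt,
                   burn_in=config.burn_in)
    _log_run(config.digest(), config.seed, res)
    rate = firing_rate(res.spikes, config.burn_in)
    out = _after(res.spikes, config.burn_in)
    # expected pairs per bin for a single reference input; counting error ~ 1/sqrt
    per_bin = input_rate * (duration - config.burn_in) * rate * bin_width * 1e-3
    if per_bin < 400:  # > 5% relative error per bin
        logger.warning(
            "short run: ~%.0f pairs per correlogram bin (projected counting "
            "error %.0f%%)", per_bin, 100.0 / max(per_bin, 1) ** 0.5)
    by_size: dict[float, tuple[Correlogram, EITMetrics]] = {}
    for size in np.unique(weights):
        refs = [_after(t, config.burn_in)
                for t, w in zip(trains, weights) if w == size]
        cc = pooled_correlogram(refs, out, bin_width=bin_width)
        nc = normalize_correlogram(cc, rate)
        by_size[float(size)] = (nc, extract_eit(nc))
    return SizeCrosscorrResult(rate, by_size, res, weights)


@dataclass(frozen=True)
class RefractoryCase:
    label: str
    sta_lags: np.ndarray
    sta_values: np.ndarray
    crosscorr: Correlogram
    metrics: EITMetrics
    output_rate: float


def run_refractory_comparison(config: ExperimentConfig | None = None,
                              cases: Sequence[tuple[str, int, float]] | None = None,
                              bin_width: float = 0.1) -> list[RefractoryCase]:
    """Refractory (lognormal) versus Poisson inputs at matched inhibition.

    Default cases: 12 x 20 nS at 49 Hz, 9 x 20 nS at 83 Hz, 6 x 20 nS at
    122 Hz, and 9 x 20 nS Poisson at 80 Hz.  For each case the
    spike-triggered average of the total inhibitory conductance (triggered
    on one input's own spikes) and the pooled input->output
    cross-correlogram are computed.
    """
    if config is None:
        config = ExperimentConfig(preset="fig2", duration=200.0)
    if cases is None:
        cases = [("49", 12, 20.0), ("83", 9, 20.0), ("122", 6, 20.0),
                 ("poisson80", 9, 20.0)]
    duration = config.scaled_duration
    out: list[RefractoryCase] = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(cases))
    for (label, n_inputs, size), child in zip(cases, children):
        ss_trains, ss_exc = child.spawn(2)
        rate_key: float | str = label if label.startswith("poisson") else float(label)
        trains = _make_trains([rate_key] * n_inputs, duration, ss_trains)
        weights = np.full(n_inputs, size)
        gi, _ = assemble_inhibition(weights, trains, duration, config.dt)
        ge = generate_excitation(config.exc_rate, duration,
                                 np.random.default_rng(ss_exc), dt=config.dt)
        res = simulate(config.params, ge, gi, duration)
        _log_run(config.digest(), config.seed, res)
        rate = firing_rate(res.spikes, config.burn_in)
        out_train = _after(res.spikes, config.burn_in)
        lags, sta = spike_triggered_average(_after(trains[0], config.burn_in), gi)
        refs = [_after(t, config.burn_in) for t in trains]
        nc = normalize_correlogram(
            pooled_correlogram(refs, out_train, bin_width=bin_width), rate)
        out.append(RefractoryCase(label, lags, sta, nc, extract_eit(nc), rate))
    return out


def run_cv_rate_scan(config: ExperimentConfig | None = None,
                     uniform_configs: Sequence[tuple[int, float]] | None = None,
                     n_nonuniform: int = 10,
                     uniform_rate: float = 100.0,
                     nonuniform_rate: float = 83.0,
                     dist: SizeDistribution | None = None) -> pd.DataFrame:
    """Firing rate versus (mean, CV) of inhibition across weight sets.

    Uniform series defaults to {80 x 2.5, 40 x 5, 20 x 10, 10 x 20,
    5 x 40} nS (all 200 nS total) at 100 spikes/s; nonuniform sets are
    drawn from the corrected size distribution at 83 spikes/s.
    """
    if config is None:
        config = ExperimentConfig(preset="fig4_6", duration=10.0)
    if uniform_configs is None:
        uniform_configs = [(80, 2.5), (40, 5.0), (20, 10.0), (10, 20.0),
                           (5, 40.0)]
    if dist is None:
        dist = empirical_surrogate()
    duration = config.scaled_duration
    rows = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(uniform_configs) + n_nonuniform)
    runs: list[tuple[str, np.ndarray, float]] = [
        (f"uniform_{n}x{s:g}", np.full(n, s), uniform_rate)
        for n, s in uniform_configs
    ]
    for k in range(n_nonuniform):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7, k)))
        w = sample_sizes(dist, config.total_target, rng)
        runs.append((f"nonuniform_{k:02d}", w, nonuniform_rate))
    for (label, weights, rate_in), child in zip(runs, children):
        ss_trains, ss_exc = child.spawn(2)
        trains = _make_trains([rate_in] * len(weights), duration, ss_trains)
        res = run_cell(config.params, weights, trains, config.exc_rate,
                       duration, np.random.default_rng(ss_exc), dt=config.dt,
                       burn_in=config.burn_in)
        _log_run(config.digest(), config.seed, res)
        gi = res.gi_stats
        rows.append({
            "label": label, "n_inputs": len(weights),
            "total_nS": float(np.sum(weights)), "input_rate": rate_in,
            "mean_gI": gi.mean, "cv_gI": gi.cv,
            "rate": firing_rate(res.spikes, config.burn_in),
        })
    return pd.DataFrame(rows)


def run_rate_code_scan(config: ExperimentConfig | None = None,
                       weights: Sequence[float] | None = None,
                       varied: Sequence[int] | None = None,
                       rates: Sequence[float] | None = None,
                       background_rate: float = 80.0) -> pd.DataFrame:
    """Output rate as one input's rate is varied, others fixed at 80 Hz.

    Returns one row per (varied input, rate point) with the measured output
    rate and conductance moments; the per-input transfer slope follows from
    a linear fit over the rate points.
    """
    if config is None:
        config = ExperimentConfig(preset="fig4_6", duration=100.0)
    if weights is None:
        weights = simplified_triplet().values
    weights = np.asarray(weights, dtype=float)
    if varied is None:
        varied = range(len(weights))
    if rates is None:
        rates = np.linspace(0.0, 160.0, 9)
    duration = config.scaled_duration
    rows = []
    for idx in varied:
        for r in rates:
            ss = np.random.SeedSequence((config.seed, idx, int(round(r * 1e3))))
            ss_trains, ss_exc = ss.spawn(2)
            per_rates: list[float | str] = [background_rate] * len(weights)
            if r == 0:
                reduced = np.delete(weights, idx)
                trains = _make_trains([background_rate] * len(reduced),
                                      duration, ss_trains)
                res = run_cell(config.params, reduced, trains, config.exc_rate,
                               duration, np.random.default_rng(ss_exc),
                               dt=config.dt, burn_in=config.burn_in)
            else:
                per_rates[idx] = float(r)
                trains = _make_trains(per_rates, duration, ss_trains)
                res = run_cell(config.params, weights, trains, config.exc_rate,
                               duration, np.random.default_rng(ss_exc),
                               dt=config.dt, burn_in=config.burn_in)
            _log_run(config.digest(), config.seed, res)
            gi = res.gi_stats
            rows.append({
                "input_idx": int(idx), "weight_nS": float(weights[idx]),
                "input_rate": float(r), "mean_gI": gi.mean, "cv_gI": gi.cv,
                "rate": firing_rate(res.spikes, config.burn_in),
            })
    return pd.DataFrame(rows)


def _pick_subset(weights: np.ndarray, subset: str,
                 rng: np.random.Generator) -> np.ndarray:
    order = np.argsort(weights, kind="stable")
    if subset == "largest2":
        return order[-2:]
    if subset == "smallest2":
        return order[:2]
    if subset == "random":
        k = int(rng.integers(2, len(weights) + 1))
        return rng.choice(len(weights), size=k, replace=False)
    raise ValueError(f"unknown subset rule {subset!r}")


def run_synchrony_scan(config: ExperimentConfig | None = None,
                       mode: str = "pairs",
                       subset: str = "largest2",
                       n_draws: int = 20,
                       sync_counts: Iterable[int] = range(0, 21),
                       uniform_n: int = 40,
                       uniform_size: float = 5.0,
                       dist: SizeDistribution | None = None) -> pd.DataFrame:
    """Firing-rate effect of perfect input synchrony.

    ``mode="pairs"``: for each of ``n_draws`` nonuniform 200 nS weight sets,
    simulate asynchronous versus a synchronized subset (``largest2``,
    ``smallest2`` or ``random``) and report the rate change.  The
    synchronized inputs share one spike train verbatim.

    ``mode="uniform"``: 40 x 5 nS inputs with k of them synchronized for
    each k in ``sync_counts``.
    """
    if config is None:
        config = ExperimentConfig(preset="fig4_6", duration=200.0)
    if dist is None:
        dist = empirical_surrogate()
    duration = config.scaled_duration
    rows = []
    if mode == "uniform":
        weights = np.full(uniform_n, uniform_size)
        for k in sync_counts:
            ss = np.random.SeedSequence((config.seed, 11, int(k)))
            ss_trains, ss_exc = ss.spawn(2)
            groups = ([SynchronyGroup([f"inh{j:03d}" for j in range(k)])]
                      if k >= 2 else [])
            trains = _make_trains([config.input_rate] * uniform_n, duration,
                                  ss_trains, groups)
            res = run_cell(config.params, weights, trains, config.exc_rate,
                           duration, np.random.default_rng(ss_exc),
                           dt=config.dt, burn_in=config.burn_in)
            _log_run(config.digest(), config.seed, res)
            rows.append({
                "k_sync": int(k), "sync_amplitude": float(k * uniform_size),
                "cv_gI": res.gi_stats.cv, "mean_gI": res.gi_stats.mean,
                "rate": firing_rate(res.spikes, config.burn_in),
            })
        return pd.DataFrame(rows)
    if mode != "pairs":
        raise ValueError(f"unknown mode {mode!r}")
    for d in range(n_draws):
        ss = np.random.SeedSequence((config.seed, 13, d))
        ss_w, ss_trains, ss_exc = ss.spawn(3)
        rng_w = np.random.default_rng(ss_w)
        weights = sample_sizes(dist, config.total_target, rng_w)
        idx = _pick_subset(weights, subset, rng_w)
        labels = [f"inh{j:03d}" for j in idx]
        rates: list[float | str] = [config.input_rate] * len(weights)
        trains_async = _make_trains(rates, duration, ss_trains)
        # the sync run reuses the same train substreams and the same
        # excitation stream, so the comparison is paired
        res_a = run_cell(config.params, weights, trains_async, config.exc_rate,
                         duration, np.random.default_rng(ss_exc),
                         dt=config.dt, burn_in=config.burn_in)
        trains_sync = _make_trains(rates, duration, ss_trains,
                                   [SynchronyGroup(labels)])
        res_s = run_cell(config.params, weights, trains_sync, config.exc_rate,
                         duration, np.random.default_rng(ss_exc),
                         dt=config.dt, burn_in=config.burn_in)
        _log_run(config.digest(), config.seed, res_a)
        _log_run(config.digest(), config.seed, res_s)
        r_a = firing_rate(res_a.spikes, config.burn_in)
        r_s = firing_rate(res_s.spikes, config.burn_in)
        rows.append({
            "draw": d, "subset": subset,
            "sync_amplitude": float(np.sum(weights[idx])),
            "n_inputs": len(weights),
            "rate_async": r_a, "rate_sync": r_s,
            "pct_change": 100.0 * (r_s - r_a) / r_a,
            "cv_async": res_a.gi_stats.cv, "cv_sync": res_s.gi_stats.cv,
        })
    return pd.DataFrame(rows)


def export_waveform(trace, path) -> None:
    """Write a conductance waveform in the dynamic-clamp CSV format."""
    _io.write_trace_csv(trace, path)


def import_spikes(path, duration: float | None = None):
    """Read spike trains from the two-column CSV format."""
    return _io.read_spike_csv(path, duration)
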