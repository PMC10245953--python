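"""Synaptic weight sets and conductance-waveform synthesis.

Spike trains become conductance traces by superposing one unitary waveform
per spike.  The unitary waveform is a peak-normalized difference of
exponentials

    k(t) = A * (exp(-t/tau_decay) - exp(-t/tau_rise)) / N,   t >= 0,

with N chosen so the peak equals the amplitude A exactly.  Defaults follow
measured synaptic kinetics: inhibitory Purkinje-cell IPSGs rise in 0.1 ms
and decay in 2.5 ms (reversal -75 mV); the excitatory mossy-fiber EPSG is
0.4 nS with 0.28 ms rise / 1.06 ms decay (reversal 0 mV).

Unitary inhibitory amplitudes measured in voltage clamp with a high-Cl
internal are corrected for synaptic depression (x 0.4) and for the
Cl-driven overestimate (/ 2.3) before use.  The corrected input-size
distribution is emulated by a categorical surrogate over {3, 10, 30} nS
with weights {16, 10, 2}/28, alongside the fixed simplified triplet
(16 x 3, 10 x 10, 2 x 30 nS) used for spike-triggered analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._core import biexp_trace
from .spike_gen import SpikeTrain

__all__ = [
    "UnitaryKernel",
    "SizeDistribution",
    "ConductanceTrace",
    "make_kernel",
    "ipsg_kernel",
    "epsg_kernel",
    "simplified_triplet",
    "empirical_surrogate",
    "uniform_sizes",
    "correct_amplitudes",
    "sample_sizes",
    "convolve_train",
    "assemble_inhibition",
    "generate_excitation",
    "trace_stats",
    "merge_events",
]

DEPRESSION_FACTOR = 0.4
CHLORIDE_FACTOR = 2.3


@dataclass(frozen=True)
class UnitaryKernel:
    """One synapse's conductance waveform (peak amplitude in nS, taus in ms)."""

    amplitude: float
    tau_rise: float
    tau_decay: float
    reversal: float

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def peak_time(self) -> float:
        """Time of the waveform maximum (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def norm(self) -> float:
        """Maximum of the un-normalized exponential difference."""
        t = self.peak_time
        return float(np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise))

    @property
    def integral(self) -> float:
        """Time integral of the waveform (nS*ms): A*(tau_d - tau_r)/N."""
        return self.amplitude * (self.tau_decay - self.tau_rise) / self.norm

    @property
    def squared_integral(self) -> float:
        """Integral of the squared waveform (nS^2*ms); Campbell variance factor."""
        tr, td = self.tau_rise, self.tau_decay
        raw = td / 2.0 + tr / 2.0 - 2.0 * tr * td / (tr + td)
        return self.amplitude ** 2 * raw / self.norm ** 2

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate k(t) on an array of times (ms); zero for t < 0."""
        t = np.asarray(t_ms, dtype=float)
        out = np.where(
            t >= 0,
            np.exp(-np.maximum(t, 0) / self.tau_decay)
            - np.exp(-np.maximum(t, 0) / self.tau_rise),
            0.0,
        )
        return self.amplitude * out / self.norm


def make_kernel(amplitude: float, tau_rise: float, tau_decay: float,
                reversal: float) -> UnitaryKernel:
    """Construct a unitary kernel; see :class:`UnitaryKernel`."""
    return UnitaryKernel(amplitude, tau_rise, tau_decay, reversal)


def ipsg_kernel(amplitude: float = 1.0) -> UnitaryKernel:
    """Unitary inhibitory kernel: 0.1 ms rise, 2.5 ms decay, E_rev = -75 mV."""
    return UnitaryKernel(amplitude, 0.1, 2.5, -75.0)


def epsg_kernel(amplitude: float = 0.4) -> UnitaryKernel:
    """Unitary excitatory kernel: 0.28 ms rise, 1.06 ms decay, E_rev = 0 mV."""
    return UnitaryKernel(amplitude, 0.28, 1.06, 0.0)


@dataclass(frozen=True)
class SizeDistribution:
    """Distribution of unitary inhibitory amplitudes (nS, post-correction).

    ``kind="simplified_triplet"`` or ``"user_list"`` carry a fixed list used
    verbatim; ``"uniform"`` and ``"categorical_empirical"`` are sampled until
    a target total is reached.
    """

    kind: str
    values: np.ndarray
    probabilities: np.ndarray | None = None
    depression_factor: float = DEPRESSION_FACTOR
    chloride_factor: float = CHLORIDE_FACTOR

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals <= 0):
            raise ValueError("all sizes must be > 0")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            object.__setattr__(self, "probabilities", p)
            if p.shape != vals.shape or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError("probabilities must match values and sum to 1")


def simplified_triplet() -> SizeDistribution:
    """Fixed 16 x 3 + 10 x 10 + 2 x 30 nS input set (nominal 200 nS total)."""
    vals = np.concatenate([np.full(16, 3.0), np.full(10, 10.0), np.full(2, 30.0)])
    return SizeDistribution("simplified_triplet", vals)


def empirical_surrogate() -> SizeDistribution:
    """Categorical surrogate of the corrected input-size distribution.

    Sizes {3, 10, 30} nS with weights {16, 10, 2}/28, mirroring the
    simplified triplet's composition as sampling probabilities.
    """
    return SizeDistribution(
        "categorical_empirical",
        np.array([3.0, 10.0, 30.0]),
        np.array([16.0, 10.0, 2.0]) / 28.0,
    )


def uniform_sizes(size: float) -> SizeDistribution:
    """All inputs share one amplitude (nS)."""
    return SizeDistribution("uniform", np.array([float(size)]))


def correct_amplitudes(raw: Sequence[float],
                       depression_factor: float = DEPRESSION_FACTOR,
                       chloride_factor: float = CHLORIDE_FACTOR) -> np.ndarray:
    """Scale raw voltage-clamp amplitudes: x depression / chloride factor."""
    if depression_factor <= 0 or chloride_factor <= 0:
        raise ValueError("correction factors must be > 0")
    return np.asarray(raw, dtype=float) * depression_factor / chloride_factor


def sample_sizes(dist: SizeDistribution, total_target: float,
                 rng: np.random.Generator, tolerance: float = 0.05,
                 max_restarts: int = 10_000) -> np.ndarray:
    """Draw unitary amplitudes until their sum reaches ``total_target`` nS.

    Sizes are drawn i.i.d. until the cumulative sum first reaches the
    target; if the final total deviates from the target by more than
    ``tolerance`` (relative), the whole draw is rejected and restarted.
    Fixed-list kinds return their list verbatim.
    """
    if total_target <= 0:
        raise ValueError("total_target must be > 0")
    if dist.kind in ("simplified_triplet", "user_list"):
        return dist.values.copy()
    if dist.values.min() > total_target:
        raise ValueError("smallest available size exceeds the target total")
    for _ in range(max_restarts):
        drawn: list[float] = []
        total = 0.0
        while total < total_target:
            if dist.kind == "uniform":
                s = float(dist.values[0])
            else:
                s = float(rng.choice(dist.values, p=dist.probabilities))
            drawn.append(s)
            total += s
        if abs(total - total_target) <= tolerance * total_target:
            return np.array(drawn)
    raise RuntimeError(
        f"could not hit total {total_target} nS within {tolerance:.0%} after "
        f"{max_restarts} restarts")


@dataclass(frozen=True)
class ConductanceTrace:
    """Uniformly sampled conductance (nS) on a grid of step ``dt`` ms."""

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    def __add__(self, other: "ConductanceTrace") -> "ConductanceTrace":
        if other.dt != self.dt or other.n_samples != self.n_samples:
            raise ValueError("traces must share one sampling grid")
        return ConductanceTrace(self.dt, self.values + other.values, self.t0)


def merge_events(times_s: Sequence[np.ndarray],
                 weights: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Merge per-input spike times into one sorted weighted event stream.

    Times are converted to ms.  Exactly coincident events (perfect
    synchrony) are combined by summing their weights, which makes k equal
    synchronized inputs arithmetically identical to a single k-fold input.
    """
    if len(times_s) != len(weights):
        raise ValueError("one weight per train required")
    if not times_s:
        return np.empty(0), np.empty(0)
    t = np.concatenate([np.asarray(x, dtype=float) * 1e3 for x in times_s])
    w = np.concatenate([np.full(len(x), float(wi))
                        for x, wi in zip(times_s, weights)])
    order = np.argsort(t, kind="stable")
    t, w = t[order], w[order]
    if t.size == 0:
        return t, w
    uniq, inv = np.unique(t, return_inverse=True)
    if uniq.size == t.size:
        return t, w
    wsum = np.zeros(uniq.size)
    np.add.at(wsum, inv, w)
    return uniq, wsum


def convolve_train(train: SpikeTrain, kernel: UnitaryKernel,
                   duration: float | None = None,
                   dt: float = 0.02) -> ConductanceTrace:
    """Superpose one kernel per spike, sampled exactly on a ``dt`` (ms) grid.

    Synthesis tracks the two exponential components of every kernel in
    closed form, so the sampled trace equals the continuous superposition
    at the grid points to machine precision (no tail truncation).

    ``dt`` must resolve the rise: dt <= tau_rise / 2.
    """
    if dt > kernel.tau_rise / 2.0:
        raise ValueError(
            f"dt={dt} ms too coarse: need dt <= tau_rise/2 = "
            f"{kernel.tau_rise / 2.0} ms")
    if duration is None:
        duration = train.duration
    n = int(round(duration * 1e3 / dt)) + 1
    times_ms = train.times * 1e3
    weights = np.full(times_ms.size, kernel.amplitude)
    g, _, _ = biexp_trace(times_ms, weights, kernel.tau_rise, kernel.tau_decay,
                          kernel.norm, dt, n, 0.0, 0.0, 0.0)
    return ConductanceTrace(dt, g)


def assemble_inhibition(weights: Sequence[float],
                        trains: Sequence[SpikeTrain] | Mapping[str, SpikeTrain],
                        duration: float | None = None, dt: float = 0.02,
                        kernel: UnitaryKernel | None = None,
                        include_components: bool = False,
                        ) -> tuple[ConductanceTrace, list[ConductanceTrace] | None]:
    """Total inhibitory conductance of a weighted input population.

    ``weights`` are peak amplitudes (nS), one per train; the shared kernel
    shape defaults to the unitary IPSG.  Returns (total, components) with
    components omitted unless requested (they double memory use).
    """
    if isinstance(trains, Mapping):
        trains = list(trains.values())
    trains = list(trains)
    if len(weights) != len(trains):
        raise ValueError("one weight per train required")
    if kernel is None:
        kernel = ipsg_kernel()
    if duration is None:
        duration = max((t.duration for t in trains), default=0.0)
    n = int(round(duration * 1e3 / dt)) + 1
    t_ms, w = merge_events([t.times for t in trains], list(weights))
    g, _, _ = biexp_trace(t_ms, w, kernel.tau_rise, kernel.tau_decay,
                          kernel.norm, dt, n, 0.0, 0.0, 0.0)
    total = ConductanceTrace(dt, g)
    components = None
    if include_components:
        components = [
            convolve_train(t, make_kernel(wi, kernel.tau_rise, kernel.tau_decay,
                                          kernel.reversal), duration, dt)
            for wi, t in zip(weights, trains)
        ]
    return total, components


def generate_excitation(event_rate: float, duration: float,
                        rng: np.random.Generator,
                        kernel: UnitaryKernel | None = None,
                        dt: float = 0.02) -> ConductanceTrace:
    """Poisson excitatory event stream convolved with the EPSG kernel.

    ``event_rate`` is the total rate of excitatory events per second across
    the (unresolved) mossy-fiber population.
    """
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    if kernel is None:
        kernel = epsg_kernel()
    n_events = rng.poisson(event_rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n_events))
    train = SpikeTrain(np.unique(times), duration) if n_events else \
        SpikeTrain(np.empty(0), duration)
    return convolve_train(train, kernel, duration, dt)


def trace_stats(trace: ConductanceTrace,
                burn_in_s: float = 0.0) -> tuple[float, float, float]:
    """(mean, sd, CV) of a trace over the window after ``burn_in_s`` seconds."""
    start = int(round(burn_in_s * 1e3 / trace.dt))
    if start >= trace.n_samples:
        raise ValueError("burn-in exceeds trace duration")
    v = trace.values[start:]
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    if mean == 0.0:
        raise ValueError("CV undefined for zero-mean trace")
    return mean, sd, sd / mean
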