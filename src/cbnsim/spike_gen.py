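"""Synthetic Purkinje-cell spike trains.

Purkinje cells fire tonically at high rates with remarkably regular
interspike intervals (ISIs); empirically their ISI distributions are well
captured by lognormal densities whose standard deviation scales linearly
with the mean::

    sd_isi = -0.00154 + 0.583 * mean_isi        (seconds)

This module generates trains from that family (plus a memoryless Poisson
control lacking the refractory-like lognormal shape, and trains resampled
from a user-supplied ISI pool), and implements perfect synchrony by letting
groups of inputs share one spike train verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SD_INTERCEPT",
    "SD_SLOPE",
    "MAX_LOGNORMAL_RATE",
    "ISISpec",
    "SpikeTrain",
    "SynchronyGroup",
    "lognormal_params_from_rate",
    "poisson_spec",
    "resampled_spec",
    "draw_isis",
    "generate_train",
    "generate_poisson_train",
    "assign_synchrony",
    "merge_trains",
]

# Linear sd-vs-mean relation of the lognormal ISI family (seconds).
SD_INTERCEPT = -0.00154
SD_SLOPE = 0.583

#: Above this rate the linear relation would give a negative ISI sd.
MAX_LOGNORMAL_RATE = SD_SLOPE / -SD_INTERCEPT  # ~378.6 events/s


@dataclass(frozen=True)
class ISISpec:
    """Generative description of one train's ISI distribution.

    ``mu``/``sigma`` are the natural-log parameters of the lognormal family
    and are present only for ``family="lognormal"``; ``sample_pool`` (ISIs
    in seconds) only for ``family="resampled"``.
    """

    family: str
    rate: float
    mean_isi: float
    sd_isi: float
    mu: float | None = None
    sigma: float | None = None
    sample_pool: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "poisson", "resampled"):
            raise ValueError(f"unknown ISI family {self.family!r}")
        if self.mean_isi <= 0:
            raise ValueError("mean_isi must be positive")
        if self.family == "lognormal":
            if self.sd_isi <= 0:
                raise ValueError("lognormal family requires sd_isi > 0")
            implied = np.exp(self.mu + self.sigma ** 2 / 2.0)
            if abs(implied - self.mean_isi) > 1e-9 * self.mean_isi:
                raise ValueError("(mu, sigma) inconsistent with mean_isi")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered event times (seconds) of one unit over [0, duration)."""

    times: np.ndarray
    duration: float
    unit_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size:
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean event rate over the full duration (events/s)."""
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class SynchronyGroup:
    """Set of input labels that share one spike train (100% synchrony).

    A singleton group is equivalent to an unsynchronized input.
    """

    member_ids: frozenset = field(default_factory=frozenset)

    def __init__(self, members: Iterable[str]):
        object.__setattr__(self, "member_ids", frozenset(members))


def lognormal_params_from_rate(rate: float) -> ISISpec:
    """Lognormal ISI spec for a target firing rate (events/s).

    The ISI sd follows the linear sd-mean relation; (mu, sigma) are obtained
    by moment inversion: sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) -
    sigma^2/2.

    Raises ``ValueError`` for rates outside (0, ~378.6) events/s, where the
    linear relation would give a nonpositive sd.
    """
    if rate <= 0 or rate >= MAX_LOGNORMAL_RATE:
        raise ValueError(
            f"rate must lie in (0, {MAX_LOGNORMAL_RATE:.1f}) events/s for the "
            f"lognormal ISI family; got {rate!r}"
        )
    mean = 1.0 / rate
    sd = SD_INTERCEPT + SD_SLOPE * mean
    sigma2 = np.log1p((sd / mean) ** 2)
    sigma = float(np.sqrt(sigma2))
    mu = float(np.log(mean) - sigma2 / 2.0)
    return ISISpec("lognormal", rate, mean, sd, mu=mu, sigma=sigma)


def poisson_spec(rate: float) -> ISISpec:
    """Memoryless (exponential-ISI) spec: sd equals the mean, no refractoriness."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    mean = 1.0 / rate
    return ISISpec("poisson", rate, mean, mean)


def resampled_spec(pool: Sequence[float]) -> ISISpec:
    """Spec drawing ISIs i.i.d. with replacement from an observed pool."""
    arr = np.asarray(pool, dtype=float)
    if arr.size < 2 or np.any(arr <= 0):
        raise ValueError("sample_pool needs >= 2 strictly positive ISIs")
    mean = float(arr.mean())
    return ISISpec("resampled", 1.0 / mean, mean, float(arr.std(ddof=0)),
                   sample_pool=arr)


def draw_isis(spec: ISISpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. ISIs (seconds) from a spec."""
    if spec.family == "lognormal":
        return rng.lognormal(spec.mu, spec.sigma, n)
    if spec.family == "poisson":
        return rng.exponential(spec.mean_isi, n)
    return rng.choice(spec.sample_pool, size=n, replace=True)


def generate_train(spec: ISISpec, duration: float,
                   rng: np.random.Generator, unit_id: str = "") -> SpikeTrain:
    """Cumulative-sum ISI draw over [0, duration).

    The first spike is placed at a uniform random fraction of one drawn ISI
    (stationary start); subsequent spikes accumulate i.i.d. ISIs until the
    duration is exceeded.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0:
        return SpikeTrain(np.empty(0), 0.0, unit_id)
    t = float(rng.uniform() * draw_isis(spec, 1, rng)[0])
    if t >= duration:
        return SpikeTrain(np.empty(0), duration, unit_id)
    chunks: list[np.ndarray] = []
    expected = max(64, int(1.1 * duration * spec.rate) + 32)
    while t < duration:
        isis = draw_isis(spec, expected, rng)
        times = t + np.cumsum(isis)
        chunks.append(np.concatenate(([t], times)))
        t = float(times[-1])
    times = np.concatenate(chunks)
    return SpikeTrain(times[times < duration], duration, unit_id)


def generate_poisson_train(rate: float, duration: float,
                           rng: np.random.Generator,
                           unit_id: str = "") -> SpikeTrain:
    """Homogeneous Poisson train (exponential ISIs, no refractory period)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or duration == 0:
        return SpikeTrain(np.empty(0), float(duration), unit_id)
    return generate_train(poisson_spec(rate), duration, rng, unit_id)


def assign_synchrony(inputs: Sequence[tuple[str, ISISpec]],
                     groups: Sequence[SynchronyGroup],
                     duration: float,
                     seed: int | np.random.SeedSequence,
                     ) -> dict[str, SpikeTrain]:
    """Generate one train per input, with grouped inputs sharing one train.

    Each synchrony group draws a single spike train that all its members
    reuse verbatim; ungrouped inputs draw independently.  Every train comes
    from its own seed substream keyed by position in ``inputs``, so
    appending an input never perturbs existing trains.

    Raises ``ValueError`` for overlapping groups, unknown members, or
    members whose ISI specs differ within a group.
    """
    labels = [lab for lab, _ in inputs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate input labels")
    spec_of = dict(inputs)
    seen: set[str] = set()
    for g in groups:
        if seen & g.member_ids:
            raise ValueError("synchrony groups must be disjoint")
        unknown = g.member_ids - spec_of.keys()
        if unknown:
            raise ValueError(f"unknown group members: {sorted(unknown)}")
        members = sorted(g.member_ids)
        first = spec_of[members[0]]
        for m in members[1:]:
            s = spec_of[m]
            if s is not first and (s.family != first.family or s.rate != first.rate):
                raise ValueError(
                    "all members of a synchrony group must share one ISI spec")
        seen |= g.member_ids
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # stateless spawning: child i depends only on (ss, i), so repeated calls
    # with one SeedSequence reproduce the same trains and appending inputs
    # never perturbs existing ones
    streams = [
        np.random.SeedSequence(entropy=ss.entropy,
                               spawn_key=tuple(ss.spawn_key) + (i,))
        for i in range(len(inputs))
    ]
    group_of = {m: g for g in groups for m in g.member_ids}
    out: dict[str, SpikeTrain] = {}
    drawn: dict[frozenset, SpikeTrain] = {}
    for (label, spec), child in zip(inputs, streams):
        g = group_of.get(label)
        if g is None:
            out[label] = generate_train(spec, duration,
                                        np.random.default_rng(child), label)
        else:
            if g.member_ids not in drawn:
                # the group's train uses the substream of its first member
                drawn[g.member_ids] = generate_train(
                    spec, duration, np.random.default_rng(child))
            shared = drawn[g.member_ids]
            out[label] = SpikeTrain(shared.times, shared.duration, label)
    return out


def merge_trains(trains: Iterable[SpikeTrain], unit_id: str = "") -> SpikeTrain:
    """Sorted union of several trains (e.g. all inputs of one size class).

    The result must satisfy the strictly-increasing invariant, so the
    inputs may not contain exactly coincident events; independent trains
    satisfy this almost surely.
    """
    trains = list(trains)
    if not trains:
        raise ValueError("no trains to merge")
    duration = max(t.duration for t in trains)
    times = np.sort(np.concatenate([t.times for t in trains]), kind="stable")
    return SpikeTrain(times, duration, unit_id)
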