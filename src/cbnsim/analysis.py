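"""Spike-train and conductance statistics.

Correlograms follow the accumulative-histogram convention: for every spike
of a reference train, spikes of a target train falling within a +/-10 ms
window are binned by lag (lag = t_target - t_ref), and counts are divided
by the number of reference spikes and the bin width, giving the target's
conditional rate in spikes/s.  Dividing further by the target's baseline
rate yields the normalized correlogram, which hovers at 1 for independent
trains.

From the normalized input->output cross-correlogram three scalars are
extracted: the excitation ``e`` (peak excess above 1 just before lag zero,
produced by the input's refractory period transiently withdrawing
inhibition), the inhibition ``i`` (depth of the post-zero trough, 1 minus
the minimum), and the half-decay time ``t_half`` (lag from the trough to
the first recovery halfway back to baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .conductance import ConductanceTrace
from .spike_gen import SpikeTrain

__all__ = [
    "Correlogram",
    "EITMetrics",
    "ISIStats",
    "correlogram",
    "pooled_correlogram",
    "autocorrelogram",
    "normalize_correlogram",
    "extract_eit",
    "spike_triggered_average",
    "firing_rate",
    "isi_stats",
]


@dataclass(frozen=True)
class Correlogram:
    """Binned lag histogram over a +/-``window`` ms span.

    ``values`` are spikes/s when raw (``normalized=False``) and
    dimensionless after normalization by a baseline rate.
    """

    lags: np.ndarray          # bin centers, ms
    values: np.ndarray
    bin_width: float          # ms
    n_ref: int
    window: float = 10.0
    normalized: bool = False


@dataclass(frozen=True)
class EITMetrics:
    """Scalar summary of a normalized cross-correlogram.

    e >= 0: pre-zero excess; i in [0, 1]: trough depth; t_half >= 0 ms:
    trough-to-half-recovery lag (NaN when the trough never recovers within
    the window).
    """

    e: float
    i: float
    t_half: float


def _window_counts(ref_s: np.ndarray, target_s: np.ndarray, window_ms: float,
                   nbins: int, block: int = 200_000) -> np.ndarray:
    """Histogram of target-minus-reference lags within the window."""
    half = window_ms * 1e-3
    counts = np.zeros(nbins, dtype=np.int64)
    for i0 in range(0, ref_s.size, block):
        ref = ref_s[i0:i0 + block]
        lo = np.searchsorted(target_s, ref - half, side="left")
        hi = np.searchsorted(target_s, ref + half, side="right")
        lens = hi - lo
        total = int(lens.sum())
        if total == 0:
            continue
        start = np.cumsum(lens) - lens
        flat = np.arange(total) - np.repeat(start, lens) + np.repeat(lo, lens)
        diffs = (target_s[flat] - np.repeat(ref, lens)) * 1e3
        counts += np.histogram(diffs, bins=nbins,
                               range=(-window_ms, window_ms))[0]
    return counts


def _make_bins(bin_width: float, window: float) -> tuple[int, np.ndarray]:
    nbins_f = 2.0 * window / bin_width
    nbins = int(round(nbins_f))
    if abs(nbins_f - nbins) > 1e-9 or nbins < 2:
        raise ValueError("bin_width must divide the correlogram window evenly")
    centers = -window + bin_width * (np.arange(nbins) + 0.5)
    return nbins, centers


def correlogram(ref: SpikeTrain, target: SpikeTrain, bin_width: float = 0.1,
                window: float = 10.0) -> Correlogram:
    """Cross-correlogram of ``target`` spiking around ``ref`` spikes (spikes/s)."""
    return pooled_correlogram([ref], target, bin_width, window)


def pooled_correlogram(refs: Sequence[SpikeTrain], target: SpikeTrain,
                       bin_width: float = 0.1,
                       window: float = 10.0) -> Correlogram:
    """Correlogram pooled over several reference trains.

    Counts and reference-spike totals are accumulated across all reference
    trains (e.g. every input of one size class) before normalization, which
    is equivalent to histogramming their union.
    """
    nbins, centers = _make_bins(bin_width, window)
    n_ref = sum(r.n_spikes for r in refs)
    if n_ref == 0:
        raise ValueError("reference train(s) empty: normalization undefined")
    counts = np.zeros(nbins, dtype=np.int64)
    for r in refs:
        counts += _window_counts(r.times, target.times, window, nbins)
    values = counts / (n_ref * bin_width * 1e-3)
    return Correlogram(centers, values, bin_width, n_ref, window)


def autocorrelogram(train: SpikeTrain, bin_width: float = 0.1,
                    window: float = 10.0) -> Correlogram:
    """Auto-correlogram with the trivial zero-lag self-pairs excluded."""
    nbins, centers = _make_bins(bin_width, window)
    if train.n_spikes == 0:
        raise ValueError("reference train empty: normalization undefined")
    counts = _window_counts(train.times, train.times, window, nbins)
    counts[nbins // 2] -= train.n_spikes  # lag-0 self pairs land at the 0 edge bin
    values = counts / (train.n_spikes * bin_width * 1e-3)
    return Correlogram(centers, values, bin_width, train.n_spikes, window)


def normalize_correlogram(c: Correlogram, baseline_rate: float) -> Correlogram:
    """Divide by the target's mean rate, mapping the far-lag baseline to 1."""
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be > 0")
    return replace(c, values=c.values / baseline_rate, normalized=True)


def extract_eit(nc: Correlogram,
                e_window: tuple[float, float] = (-4.0, 0.0),
                i_window: tuple[float, float] = (0.0, 6.0),
                baseline_window: tuple[float, float] = (-10.0, -8.0),
                baseline_tol: float = 0.1) -> EITMetrics:
    """Extract (e, i, t_half) from a normalized cross-correlogram.

    e is the peak excess above 1 within ``e_window``; i is 1 minus the
    minimum within ``i_window``; t_half is the lag from the trough (the
    last minimal bin, so a flat trough is measured from where recovery
    starts) to the first later bin at or above 1 - i/2.

    The far-lag baseline (mean over ``baseline_window``) must sit within
    ``baseline_tol`` of 1, otherwise the correlogram is judged
    un-normalized or too noisy and a ``ValueError`` is raised.
    """
    if not nc.normalized:
        raise ValueError("extract_eit expects a normalized correlogram")
    lags, v = nc.lags, nc.values
    base = v[(lags >= baseline_window[0]) & (lags < baseline_window[1])].mean()
    if abs(base - 1.0) > baseline_tol:
        raise ValueError(
            f"baseline {base:.3f} deviates from 1 by more than {baseline_tol}")
    e_mask = (lags >= e_window[0]) & (lags <= e_window[1])
    i_mask = (lags >= i_window[0]) & (lags <= i_window[1])
    e = max(float(v[e_mask].max() - 1.0), 0.0)
    i_region = v[i_mask]
    vmin = float(i_region.min())
    i = max(1.0 - vmin, 0.0)
    if i == 0.0:
        return EITMetrics(e, 0.0, 0.0)
    trough_candidates = np.flatnonzero(i_mask)[i_region == vmin]
    trough_idx = int(trough_candidates[-1])
    trough_lag = float(lags[trough_idx])
    target = 1.0 - i / 2.0
    after = np.flatnonzero((np.arange(v.size) > trough_idx) & (v >= target))
    t_half = float(lags[after[0]] - trough_lag) if after.size else float("nan")
    return EITMetrics(e, i, t_half)


def spike_triggered_average(trigger: SpikeTrain, trace: ConductanceTrace,
                            window: float = 10.0,
                            max_edge_fraction: float = 0.1,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean of trace segments centered on trigger spikes.

    Returns (lags_ms, averaged_values).  Triggers whose +/-``window`` ms
    segment falls outside the trace are dropped; if more than
    ``max_edge_fraction`` of them would be dropped the call errors out.
    """
    if trigger.n_spikes == 0:
        raise ValueError("trigger train empty")
    w = int(round(window / trace.dt))
    centers = np.round(trigger.times * 1e3 / trace.dt).astype(np.int64)
    ok = (centers - w >= 0) & (centers + w < trace.n_samples)
    if (~ok).sum() > max_edge_fraction * centers.size:
        raise ValueError("too many triggers fall within one window of the edges")
    centers = centers[ok]
    if centers.size == 0:
        raise ValueError("no triggers with a full window inside the trace")
    offsets = np.arange(-w, w + 1)
    acc = np.zeros(offsets.size)
    for i0 in range(0, centers.size, 10_000):
        idx = centers[i0:i0 + 10_000, None] + offsets[None, :]
        acc += trace.values[idx].sum(axis=0)
    return offsets * trace.dt, acc / centers.size


def firing_rate(spikes: SpikeTrain, burn_in: float = 1.0) -> float:
    """Mean rate (spikes/s) after discarding an initial burn-in (s)."""
    if spikes.duration <= burn_in:
        raise ValueError("duration must exceed the burn-in")
    n = int(np.count_nonzero(spikes.times >= burn_in))
    return n / (spikes.duration - burn_in)


@dataclass(frozen=True)
class ISIStats:
    mean: float           # s
    sd: float             # s
    cv: float
    hist_counts: np.ndarray
    hist_edges_ms: np.ndarray


def isi_stats(train: SpikeTrain, bin_width_ms: float = 0.5,
              hist_max_ms: float | None = None) -> ISIStats:
    """Sample moments and histogram of a train's interspike intervals."""
    if train.n_spikes < 2:
        raise ValueError("need >= 2 spikes for ISI statistics")
    isis = np.diff(train.times)
    mean = float(isis.mean())
    sd = float(isis.std(ddof=0))
    if hist_max_ms is None:
        hist_max_ms = float(np.ceil(isis.max() * 1e3 / bin_width_ms) * bin_width_ms)
    nbins = max(1, int(round(hist_max_ms / bin_width_ms)))
    counts, edges = np.histogram(isis * 1e3, bins=nbins, range=(0.0, hist_max_ms))
    return ISIStats(mean, sd, sd / mean if mean > 0 else 0.0, counts, edges)
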