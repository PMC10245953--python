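"""Correlograms, spike-triggered averages and e/i/t_half extraction."""

import numpy as np
import pytest

from cbnsim.analysis import (Correlogram, autocorrelogram, correlogram,
                             extract_eit, firing_rate, isi_stats,
                             normalize_correlogram, pooled_correlogram,
                             spike_triggered_average)
from cbnsim.conductance import ConductanceTrace, convolve_train, ipsg_kernel
from cbnsim.spike_gen import (SpikeTrain, generate_poisson_train,
                              generate_train, lognormal_params_from_rate)


def _flat_correlogram(value=1.0, bin_width=0.4, normalized=True):
    nbins = int(round(20.0 / bin_width))
    lags = -10.0 + bin_width * (np.arange(nbins) + 0.5)
    return Correlogram(lags, np.full(nbins, float(value)), bin_width, 1000,
                       normalized=normalized)


class TestCorrelogram:
    def test_independent_poisson_flat_at_base_rate(self):
        ref = generate_poisson_train(80.0, 1000.0, np.random.default_rng(0))
        tgt = generate_poisson_train(80.0, 1000.0, np.random.default_rng(1))
        cc = correlogram(ref, tgt, bin_width=1.0)
        sd = np.sqrt(tgt.rate / (ref.n_spikes * 1e-3))
        assert np.all(np.abs(cc.values - tgt.rate) < 4 * sd)

    def test_empty_target_all_zero(self):
        ref = generate_poisson_train(10.0, 10.0, np.random.default_rng(2))
        cc = correlogram(ref, SpikeTrain(np.empty(0), 10.0))
        assert np.all(cc.values == 0)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            correlogram(SpikeTrain(np.empty(0), 1.0),
                        generate_poisson_train(10.0, 1.0,
                                               np.random.default_rng(0)))

    def test_uneven_bin_width_errors(self):
        ref = generate_poisson_train(10.0, 10.0, np.random.default_rng(3))
        with pytest.raises(ValueError, match="divide"):
            correlogram(ref, ref, bin_width=0.3)

    def test_symmetry_under_ref_target_swap(self):
        # counts(a,b) at lag l == counts(b,a) at -l
        a = generate_poisson_train(40.0, 50.0, np.random.default_rng(4))
        b = generate_poisson_train(60.0, 50.0, np.random.default_rng(5))
        ab = correlogram(a, b, bin_width=0.5)
        ba = correlogram(b, a, bin_width=0.5)
        counts_ab = ab.values * ab.n_ref
        counts_ba = ba.values * ba.n_ref
        np.testing.assert_allclose(counts_ab, counts_ba[::-1], rtol=1e-9)

    def test_pooled_equals_sum_of_counts(self):
        refs = [generate_poisson_train(20.0, 50.0, np.random.default_rng(k))
                for k in (6, 7)]
        tgt = generate_poisson_train(50.0, 50.0, np.random.default_rng(8))
        pooled = pooled_correlogram(refs, tgt, bin_width=1.0)
        singles = [correlogram(r, tgt, bin_width=1.0) for r in refs]
        manual = (singles[0].values * singles[0].n_ref
                  + singles[1].values * singles[1].n_ref) / pooled.n_ref
        np.testing.assert_allclose(pooled.values, manual, rtol=1e-12)

    def test_autocorrelogram_refractory_trough(self):
        train = generate_train(lognormal_params_from_rate(122.0), 300.0,
                               np.random.default_rng(9))
        ac = autocorrelogram(train, bin_width=0.5)
        inner = np.abs(ac.lags) < 1.3
        assert ac.values[inner].max() < 0.1 * train.rate


class TestNormalization:
    def test_flat_becomes_ones(self):
        c = _flat_correlogram(80.0, normalized=False)
        nc = normalize_correlogram(c, 80.0)
        assert nc.normalized and np.allclose(nc.values, 1.0)

    def test_round_trip_identity(self):
        c = _flat_correlogram(42.0, normalized=False)
        nc = normalize_correlogram(c, 7.0)
        np.testing.assert_allclose(nc.values * 7.0, c.values)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            normalize_correlogram(_flat_correlogram(1.0), 0.0)


class TestExtractEIT:
    def test_all_ones_gives_zeros(self):
        m = extract_eit(_flat_correlogram(1.0))
        assert (m.e, m.i, m.t_half) == (0.0, 0.0, 0.0)

    def test_hand_constructed_piecewise(self):
        # 1 everywhere; 1.3 at lag -1 ms; 0.2 over (0, 2] ms; linear recovery
        # to 1 at 4 ms -> e = 0.3, i = 0.8; continuous t_half = 1.0 ms,
        # measured on 0.4 ms bins (trough = last minimal bin at 1.8 ms,
        # first half-recovered bin center at 3.0 ms) -> 1.2 ms
        c = _flat_correlogram(1.0, bin_width=0.4)
        v = c.values.copy()
        lags = c.lags
        v[np.isclose(lags, -1.0)] = 1.3
        flat = (lags > 0) & (lags <= 2.0)
        v[flat] = 0.2
        ramp = (lags > 2.0) & (lags <= 4.0)
        v[ramp] = 0.2 + 0.4 * (lags[ramp] - 2.0)
        c = Correlogram(lags, v, c.bin_width, c.n_ref, normalized=True)
        m = extract_eit(c)
        assert m.e == pytest.approx(0.3)
        assert m.i == pytest.approx(0.8)
        assert m.t_half == pytest.approx(1.2)

    def test_unnormalized_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            extract_eit(_flat_correlogram(1.5))


class TestSTA:
    def test_constant_trace_flat(self):
        trig = generate_poisson_train(20.0, 10.0, np.random.default_rng(10))
        trace = ConductanceTrace(0.02, np.full(int(10e3 / 0.02) + 1, 5.0))
        lags, sta = spike_triggered_average(trig, trace)
        assert np.allclose(sta, 5.0)

    def test_own_spikes_show_kernel_after_lag_zero(self):
        train = generate_poisson_train(10.0, 200.0, np.random.default_rng(11))
        trace = convolve_train(train, ipsg_kernel(5.0), 200.0)
        lags, sta = spike_triggered_average(train, trace)
        base = sta[lags <= -2.0].mean()
        k = ipsg_kernel(5.0)
        peak_lag = lags[np.argmax(sta)]
        assert peak_lag == pytest.approx(k.peak_time, abs=0.1)
        assert sta.max() - base == pytest.approx(5.0, rel=0.1)
        # pre-lag side flat for a memoryless trigger
        assert np.all(np.abs(sta[lags <= -2.0] - base) < 0.5)

    def test_empty_trigger_errors(self):
        with pytest.raises(ValueError, match="trigger"):
            spike_triggered_average(SpikeTrain(np.empty(0), 1.0),
                                    ConductanceTrace(0.02, np.zeros(1000)))


class TestRateAndISI:
    def test_firing_rate_burn_in_arithmetic(self):
        # 100 spikes over 10 s, 10 of them inside the 1 s burn-in -> 10 /s
        times = np.concatenate([np.linspace(0.05, 0.95, 10),
                                np.linspace(1.05, 9.95, 90)])
        assert firing_rate(SpikeTrain(times, 10.0), 1.0) == pytest.approx(10.0)

    def test_empty_train_zero_rate(self):
        assert firing_rate(SpikeTrain(np.empty(0), 10.0), 1.0) == 0.0

    def test_periodic_train_isi(self):
        t = SpikeTrain(np.arange(100) * 0.01, 1.0)
        s = isi_stats(t)
        assert s.mean == pytest.approx(0.01)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.cv == pytest.approx(0.0, abs=1e-9)

    def test_lognormal_isi_moments(self):
        train = generate_train(lognormal_params_from_rate(80.0), 500.0,
                               np.random.default_rng(12))
        s = isi_stats(train)
        assert s.mean == pytest.approx(0.0125, rel=0.02)
        assert s.sd == pytest.approx(0.0057475, rel=0.05)

    def test_too_few_spikes_errors(self):
        with pytest.raises(ValueError):
            isi_stats(SpikeTrain(np.array([0.5]), 1.0))
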