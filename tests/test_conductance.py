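"""Kernels, weight sampling and shot-noise conductance synthesis."""

import numpy as np
import pytest

from cbnsim.conductance import (assemble_inhibition, convolve_train,
                                correct_amplitudes, empirical_surrogate,
                                epsg_kernel, generate_excitation, ipsg_kernel,
                                make_kernel, sample_sizes, simplified_triplet,
                                trace_stats, uniform_sizes, ConductanceTrace)
from cbnsim.spike_gen import (SpikeTrain, generate_poisson_train,
                              generate_train, lognormal_params_from_rate)


class TestKernel:
    def test_ipsg_closed_forms(self):
        k = ipsg_kernel()
        # t* = tau_r tau_d / (tau_d - tau_r) * ln(tau_d/tau_r)
        assert k.peak_time == pytest.approx(0.33530, abs=1e-5)
        assert k.integral == pytest.approx(2.8589, abs=2e-4)
        # peak-normalization: waveform maximum equals the amplitude
        assert k.waveform(np.array([k.peak_time]))[0] == pytest.approx(1.0)

    def test_epsg_integral(self):
        assert epsg_kernel().integral == pytest.approx(0.6836, abs=2e-4)

    def test_zero_amplitude_zero_waveform(self):
        k = make_kernel(0.0, 0.1, 2.5, -75.0)
        assert np.all(k.waveform(np.linspace(0, 20, 100)) == 0)

    def test_bad_taus_error(self):
        with pytest.raises(ValueError):
            make_kernel(1.0, 2.5, 0.1, -75.0)


class TestConvolve:
    def test_empty_train_zero_trace(self):
        tr = convolve_train(SpikeTrain(np.empty(0), 1.0), ipsg_kernel(), 1.0)
        assert np.all(tr.values == 0)

    def test_single_spike_peak(self):
        tr = convolve_train(SpikeTrain(np.array([0.0]), 0.05), ipsg_kernel(),
                            0.05, dt=0.02)
        k = ipsg_kernel()
        assert tr.values.max() == pytest.approx(1.0, abs=1e-4)
        assert np.argmax(tr.values) * tr.dt == pytest.approx(k.peak_time,
                                                             abs=tr.dt)

    def test_dt_too_coarse_errors(self):
        with pytest.raises(ValueError, match="tau_rise/2"):
            convolve_train(SpikeTrain(np.empty(0), 1.0), ipsg_kernel(), 1.0,
                           dt=0.1)

    def test_campbell_mean(self, rng):
        # shot noise first moment: mean = rate * kernel integral
        train = generate_poisson_train(80.0, 300.0, rng)
        tr = convolve_train(train, ipsg_kernel(), 300.0)
        assert tr.mean == pytest.approx(0.080 * ipsg_kernel().integral,
                                        rel=0.02)

    def test_campbell_variance(self, rng):
        train = generate_poisson_train(80.0, 300.0, rng)
        tr = convolve_train(train, ipsg_kernel(), 300.0)
        _, sd, _ = trace_stats(tr)
        assert sd ** 2 == pytest.approx(
            0.080 * ipsg_kernel().squared_integral, rel=0.05)


class TestSizeSampling:
    def test_uniform_5ns_gives_40_inputs(self, rng):
        w = sample_sizes(uniform_sizes(5.0), 200.0, rng)
        assert len(w) == 40 and np.all(w == 5.0)

    def test_triplet_fixed_list(self, rng):
        w = sample_sizes(simplified_triplet(), 200.0, rng)
        vals, counts = np.unique(w, return_counts=True)
        np.testing.assert_array_equal(vals, [3.0, 10.0, 30.0])
        np.testing.assert_array_equal(counts, [16, 10, 2])
        assert w.sum() == pytest.approx(208.0)

    def test_categorical_mean_size(self, rng):
        dist = empirical_surrogate()
        sizes = np.concatenate([sample_sizes(dist, 200.0, rng)
                                for _ in range(60)])
        assert sizes.mean() == pytest.approx(208.0 / 28.0, rel=0.05)

    def test_draw_total_within_tolerance(self, rng):
        for _ in range(20):
            w = sample_sizes(empirical_surrogate(), 200.0, rng)
            assert 200.0 <= w.sum() <= 210.0

    def test_min_size_above_target_errors(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            sample_sizes(uniform_sizes(50.0), 30.0, rng)


class TestCorrections:
    def test_values(self):
        np.testing.assert_allclose(correct_amplitudes([172.5]), [30.0])
        np.testing.assert_allclose(correct_amplitudes([0.0]), [0.0])
        np.testing.assert_allclose(correct_amplitudes([7.0], 1.0, 1.0), [7.0])

    def test_bad_factors_error(self):
        with pytest.raises(ValueError):
            correct_amplitudes([1.0], 0.0, 2.3)


class TestAssembly:
    def _trains(self, n, rate, duration, seed):
        spec = lognormal_params_from_rate(rate)
        return [generate_train(spec, duration, np.random.default_rng((seed, k)))
                for k in range(n)]

    def test_additivity(self):
        trains = self._trains(6, 80.0, 5.0, 0)
        w = [3.0, 3.0, 10.0, 10.0, 30.0, 5.0]
        total, _ = assemble_inhibition(w, trains, 5.0)
        a, _ = assemble_inhibition(w[:3], trains[:3], 5.0)
        b, _ = assemble_inhibition(w[3:], trains[3:], 5.0)
        np.testing.assert_allclose(total.values, a.values + b.values,
                                   rtol=1e-10, atol=1e-10)

    def test_scale_equivariance(self):
        trains = self._trains(4, 80.0, 5.0, 1)
        w = np.array([3.0, 10.0, 30.0, 5.0])
        t1, _ = assemble_inhibition(w, trains, 5.0)
        t2, _ = assemble_inhibition(2.5 * w, trains, 5.0)
        assert t2.mean == pytest.approx(2.5 * t1.mean, rel=1e-9)
        assert t2.sd == pytest.approx(2.5 * t1.sd, rel=1e-9)
        assert t2.cv == pytest.approx(t1.cv, rel=1e-9)

    def test_campbell_mean_triplet(self):
        trains = self._trains(28, 80.0, 100.0, 2)
        w = simplified_triplet().values
        total, _ = assemble_inhibition(w, trains, 100.0)
        assert total.mean == pytest.approx(
            0.080 * ipsg_kernel().integral * 208.0, rel=0.02)

    def test_cv_rises_as_inputs_get_fewer_and_larger(self):
        # fixed 200 nS total: CV of the summed trace grows with input size
        cvs = []
        for n, size in [(80, 2.5), (40, 5.0), (20, 10.0), (10, 20.0),
                        (5, 40.0)]:
            trains = self._trains(n, 100.0, 20.0, 3)
            total, _ = assemble_inhibition(np.full(n, size), trains, 20.0)
            cvs.append(trace_stats(total, 1.0)[2])
        assert np.all(np.diff(cvs) > 0)

    def test_mismatched_weights_error(self):
        with pytest.raises(ValueError, match="one weight per train"):
            assemble_inhibition([1.0, 2.0], self._trains(1, 80.0, 1.0, 0), 1.0)

    def test_zero_weights_zero_trace(self):
        total, _ = assemble_inhibition([0.0, 0.0],
                                       self._trains(2, 80.0, 2.0, 4), 2.0)
        assert np.all(total.values == 0)


class TestExcitation:
    def test_mean_at_preset_rates(self, rng):
        tr = generate_excitation(23650.0, 100.0, rng)
        assert tr.mean == pytest.approx(23.65 * epsg_kernel().integral,
                                        rel=0.02)  # ~16.2 nS
        tr2 = generate_excitation(20000.0, 100.0, rng)
        assert tr2.mean == pytest.approx(20.0 * epsg_kernel().integral,
                                         rel=0.02)  # ~13.7 nS

    def test_zero_rate_zero_trace(self, rng):
        assert np.all(generate_excitation(0.0, 1.0, rng).values == 0)

    def test_negative_rate_errors(self, rng):
        with pytest.raises(ValueError):
            generate_excitation(-1.0, 1.0, rng)


class TestTraceStats:
    def test_constant_trace(self):
        mean, sd, cv = trace_stats(ConductanceTrace(0.02, np.full(100, 7.0)))
        assert (mean, sd, cv) == (7.0, 0.0, 0.0)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError, match="CV undefined"):
            trace_stats(ConductanceTrace(0.02, np.zeros(100)))
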