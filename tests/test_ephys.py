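"""Spike-train analysis: PSTH, tuning, spectra, assignment, size maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rgcsample import ephys, synthetic
from rgcsample.core import (
    InsufficientWindowError,
    NoPeakError,
    ZeroResponseError,
)


def spike_data(times_per_trial, n_trials, duration=1.0, baseline=0.5,
               direction=np.nan):
    rows = [("c", "s", t, direction, float(s))
            for t in range(n_trials) for s in times_per_trial]
    frame = pd.DataFrame(rows, columns=["cell_id", "stimulus", "trial",
                                        "direction_deg", "spike_time_s"])
    return synthetic.SpikeData(trials=frame, duration=duration,
                               baseline_window=baseline,
                               n_trials_per_condition=n_trials)


class TestPsth:
    def test_one_spike_per_trial_in_one_bin_gives_twenty_hertz(self):
        psth = ephys.compute_psth(spike_data([0.112], n_trials=10))
        assert psth.rates.max() == pytest.approx(20.0)  # 1 / 0.05 s

    def test_empty_trains_give_all_zero(self):
        psth = ephys.compute_psth(spike_data([], n_trials=5))
        assert np.all(psth.rates == 0)

    def test_spike_count_conservation_is_exact(self):
        rng = np.random.default_rng(0)
        times = list(rng.uniform(-0.5, 0.999, 137))
        psth = ephys.compute_psth(spike_data(times, n_trials=7))
        total = psth.rates.sum() * psth.bin_width * psth.n_trials
        assert total == pytest.approx(137 * 7, abs=1e-9)

    def test_homogeneous_poisson_rate_recovered(self):
        stim = synthetic.generate_chirp_stimulus(60.0)
        tuning = synthetic.TuningSpec(baseline_rate=10.0, peak_rate=10.0,
                                      n_trials=100, seed=1)
        spikes = synthetic.generate_chirp_response(stim, tuning)
        psth = ephys.compute_psth(spikes)
        assert psth.stimulus_rates.mean() == pytest.approx(10.0, abs=1.0)


class TestIsResponding:
    @staticmethod
    def psth_with(rates, baseline_mean=5.0, baseline_sd=1.0):
        n = len(rates)
        return ephys.PSTH(bin_width=0.05,
                          edges=np.arange(0, (n + 1) * 0.05 - 1e-12, 0.05) - 0.0,
                          rates=np.asarray(rates, float),
                          baseline_mean=baseline_mean, baseline_sd=baseline_sd,
                          n_trials=10)

    def test_flat_psth_at_baseline_not_responding(self):
        assert not ephys.is_responding(self.psth_with([5.0] * 20))

    def test_three_sd_peak_is_responding(self):
        rates = [5.0] * 20
        rates[7] = 8.0  # baseline + 3 SD
        assert ephys.is_responding(self.psth_with(rates))

    def test_false_positive_rate_matches_monte_carlo_oracle(self):
        # 200 non-responsive Poisson cells vs a direct max-of-bins null
        rng = np.random.default_rng(2)
        n_cells, n_trials, rate, duration, baseline = 200, 10, 8.0, 1.0, 1.0
        fp = 0
        for _ in range(n_cells):
            times = []
            for t in range(n_trials):
                n = rng.poisson(rate * (duration + baseline))
                times.extend(rng.uniform(-baseline, duration, n))
            rows = [("c", "s", 0, np.nan, s) for s in times]
            frame = pd.DataFrame(rows, columns=["cell_id", "stimulus", "trial",
                                                "direction_deg", "spike_time_s"])
            sd = synthetic.SpikeData(trials=frame, duration=duration,
                                     baseline_window=baseline,
                                     n_trials_per_condition=n_trials)
            fp += ephys.is_responding(ephys.compute_psth(sd))
        # oracle: same criterion applied to freshly simulated binned counts
        oracle_fp = 0
        for _ in range(n_cells):
            counts = rng.poisson(rate * 0.05 * n_trials, size=40) / (0.05 * n_trials)
            base, stim = counts[:20], counts[20:]
            if stim.max() > base.mean() + 2 * base.std():
                oracle_fp += 1
        assert abs(fp - oracle_fp) / n_cells < 0.12


class TestDirectionSelectivity:
    def test_single_direction_responder(self):
        res = ephys.direction_orientation_selectivity([1, 0, 0, 0, 0, 0, 0, 0])
        assert res.dsi == pytest.approx(1.0)
        assert res.preferred_direction_deg == pytest.approx(0.0)

    def test_symmetric_responses_cancel(self):
        res = ephys.direction_orientation_selectivity([3.0] * 8)
        assert res.dsi == pytest.approx(0.0, abs=1e-12)
        assert res.osi == pytest.approx(0.0, abs=1e-12)

    def test_complex_sum_oracle(self):
        # raw [2,1,...,1] -> normalized [1, 0.5 x 7]: DSI = 0.5/4.5
        res = ephys.direction_orientation_selectivity([2, 1, 1, 1, 1, 1, 1, 1])
        r = np.array([1.0] + [0.5] * 7)
        a = np.deg2rad(np.arange(0, 360, 45))
        oracle = np.abs(np.sum(r * np.exp(1j * a))) / r.sum()
        assert res.dsi == pytest.approx(oracle, abs=1e-12)
        assert res.dsi == pytest.approx(0.5 / 4.5, abs=1e-12)

    @given(scale=st.floats(0.1, 50.0))
    def test_invariant_to_positive_scaling(self, scale):
        base = np.array([4, 1, 0.5, 2, 3, 1, 1, 0.2])
        a = ephys.direction_orientation_selectivity(base)
        b = ephys.direction_orientation_selectivity(base * scale)
        assert a.dsi == pytest.approx(b.dsi, abs=1e-9)
        assert a.osi == pytest.approx(b.osi, abs=1e-9)

    def test_invariant_to_direction_relabeling(self):
        base = np.array([4, 1, 0.5, 2, 3, 1, 1, 0.2])
        dirs = np.arange(0, 360, 45)
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        a = ephys.direction_orientation_selectivity(base, dirs)
        b = ephys.direction_orientation_selectivity(base[perm], dirs[perm])
        assert a.dsi == pytest.approx(b.dsi, abs=1e-12)

    def test_all_zero_responses_raise(self):
        with pytest.raises(ZeroResponseError):
            ephys.direction_orientation_selectivity([0] * 8)


class TestChirpSpectrum:
    @staticmethod
    def modulated_spikes(freq_hz, seed=3, rate=40.0, n_trials=30, t0=0.0, t1=6.0):
        rng = np.random.default_rng(seed)
        times = []
        dt = 0.001
        t = np.arange(t0, t1, dt)
        lam = rate * 0.5 * (1 + np.sin(2 * np.pi * freq_hz * t)) * dt
        for trial in range(n_trials):
            hits = t[rng.uniform(size=t.size) < lam]
            times.extend(hits)
        rows = [("c", "s", 0, np.nan, s) for s in times]
        frame = pd.DataFrame(rows, columns=["cell_id", "stimulus", "trial",
                                            "direction_deg", "spike_time_s"])
        return synthetic.SpikeData(trials=frame, duration=t1,
                                   baseline_window=0.0,
                                   n_trials_per_condition=n_trials)

    def test_three_hertz_modulation_dominates_two_to_four_band(self):
        spikes = self.modulated_spikes(3.0)
        _, _, bands = ephys.chirp_spectrum(spikes, sweep_window=(0.0, 6.0))
        assert np.argmax(bands) == 2  # [2, 4) Hz

    def test_constant_rate_has_no_band_power(self):
        # an exactly constant rate (regular spike train at 40 Hz) carries
        # no power in the 0.5-8 Hz bands beyond DC
        times = list(np.arange(0.0125, 6.0, 0.025))
        spikes = spike_data(times, n_trials=20, duration=6.0, baseline=0.0)
        _, _, flat_bands = ephys.chirp_spectrum(spikes, sweep_window=(0.0, 6.0))
        _, _, mod_bands = ephys.chirp_spectrum(self.modulated_spikes(3.0),
                                               sweep_window=(0.0, 6.0))
        assert flat_bands.max() < 0.05 * mod_bands.max()

    def test_linearity_doubling_spikes_doubles_amplitude(self):
        spikes = self.modulated_spikes(2.5)
        doubled = synthetic.SpikeData(
            trials=pd.concat([spikes.trials, spikes.trials], ignore_index=True),
            duration=spikes.duration, baseline_window=0.0,
            n_trials_per_condition=spikes.n_trials_per_condition,
        )
        _, amp1, _ = ephys.chirp_spectrum(spikes, sweep_window=(0.0, 6.0))
        _, amp2, _ = ephys.chirp_spectrum(doubled, sweep_window=(0.0, 6.0))
        assert np.allclose(amp2, 2 * amp1, atol=1e-9)

    def test_short_window_rejected(self):
        spikes = self.modulated_spikes(3.0)
        with pytest.raises(InsufficientWindowError):
            ephys.chirp_spectrum(spikes, sweep_window=(0.0, 1.5))


class TestResponseHalfwidth:
    @staticmethod
    def psth_from_rates(rates, bin_width=0.05):
        rates = np.asarray(rates, float)
        edges = bin_width * np.arange(rates.size + 1)
        return ephys.PSTH(bin_width=bin_width, edges=edges, rates=rates,
                          baseline_mean=0.0, baseline_sd=0.0, n_trials=1,
                          baseline_undefined=True)

    def test_triangular_peak_geometry(self):
        rates = [0, 0, 2.5, 5, 7.5, 10, 7.5, 5, 2.5, 0, 0]
        width = ephys.response_halfwidth(self.psth_from_rates(rates))
        assert width == pytest.approx(0.2, abs=1e-6)

    def test_highest_of_two_peaks_wins(self):
        rates = [0, 5, 0, 0, 0, 10, 10, 10, 0, 0, 5, 0]
        width = ephys.response_halfwidth(self.psth_from_rates(rates))
        assert width > 0.1  # the broad 10 Hz plateau, not the 5 Hz spikes

    def test_gaussian_bump_fwhm_identity(self):
        bin_width = 0.01
        t = np.arange(0, 2, bin_width)
        sigma = 0.12
        rates = 30 * np.exp(-0.5 * ((t - 1.0) / sigma) ** 2)
        width = ephys.response_halfwidth(self.psth_from_rates(rates, bin_width))
        assert width == pytest.approx(2.3548 * sigma, abs=bin_width)

    def test_no_positive_bin_raises(self):
        with pytest.raises(NoPeakError):
            ephys.response_halfwidth(self.psth_from_rates([0, 0, 0]))


class TestCalciumConvolve:
    def test_delta_input_reproduces_kernel(self):
        dt = 0.01
        x = np.zeros(1200)
        n0 = 100
        x[n0] = 1.0 / dt  # unit-area delta, preceded by silence
        out = ephys.calcium_convolve(x, dt)
        kernel = ephys.calcium_kernel(dt)
        m = min(kernel.size, x.size - n0)
        assert np.allclose(out[n0:n0 + m], kernel[:m], atol=1e-9)

    def test_constant_input_stays_constant(self):
        out = ephys.calcium_convolve(np.full(500, 3.7), dt=0.01)
        assert np.allclose(out, 3.7, atol=1e-9)

    def test_step_response_matches_closed_form(self):
        # double-exponential kernel: step response at time t is
        # (tau_d (1 - e^{-t/tau_d}) - tau_r (1 - e^{-t/tau_r})) / (tau_d - tau_r)
        dt = 0.005
        rise, decay = 0.07, 0.78
        x = np.concatenate([np.zeros(200), np.ones(2000)])
        out = ephys.calcium_convolve(x, dt, rise_s=rise, decay_s=decay)
        for mult in (1.0, 3.0):
            t = mult * decay
            idx = 200 + int(t / dt)
            closed = (decay * (1 - np.exp(-t / decay))
                      - rise * (1 - np.exp(-t / rise))) / (decay - rise)
            assert out[idx] == pytest.approx(closed, abs=0.01)
        # and near-saturation within 3.5 decay constants
        assert out[200 + int(3.5 * decay / dt)] > 0.95

    def test_bad_time_constants_rejected(self):
        from rgcsample.core import ConfigError

        with pytest.raises(ConfigError):
            ephys.calcium_convolve(np.ones(10), dt=0.01, rise_s=-1.0)


class TestFunctionalAssignment:
    @staticmethod
    def template_set(n=10, seed=5, length=400):
        rng = np.random.default_rng(seed)
        times = np.linspace(0, 29.5, length)
        traces = {
            f"T{i}": np.convolve(rng.normal(0, 1, length), np.ones(25) / 25, "same")
            for i in range(n)
        }
        return ephys.ChirpTemplateSet(times=times, traces=traces)

    def test_identical_response_ranks_first_by_all_metrics(self):
        ts = self.template_set()
        a = ephys.assign_functional_cluster(ts.traces["T3"], ts.times, ts)
        assert a.final_template == "T3"
        assert a.agreement
        assert (a.ranks.loc["T3"] == 1).all()

    def test_noisy_self_recovery(self):
        ts = self.template_set()
        rng = np.random.default_rng(6)
        correct = 0
        for i in range(200):
            k = int(rng.integers(10))
            resp = ts.traces[f"T{k}"] + rng.normal(0, 0.15, ts.times.size)
            a = ephys.assign_functional_cluster(resp, ts.times, ts)
            correct += a.final_template == f"T{k}"
        assert correct / 200 >= 0.95

    def test_disagreeing_metrics_fall_back_to_best_correlation(self):
        # adversarial fixtures found by randomized search over perturbation
        # families that decouple the three metrics: scaled copies win the
        # correlation, dense small noise the Euclidean distance, sparse
        # large outliers the summed-residual ranking
        rng = np.random.default_rng(7)
        times = np.linspace(0, 10, 120)
        n_disagree = 0
        for _ in range(50):
            r = rng.normal(0, 1, 120)
            traces = {
                "A0": float(rng.uniform(2, 4)) * r,
                "A1": float(rng.uniform(2, 4)) * r + rng.normal(0, 0.05, 120),
                "B0": r + rng.normal(0, rng.uniform(0.3, 0.6), 120),
                "B1": r + rng.normal(0, rng.uniform(0.3, 0.6), 120),
            }
            for name in ("C0", "C1"):
                t = r.copy()
                k = int(rng.integers(2, 5))
                idx = rng.choice(120, k, replace=False)
                t[idx] += rng.choice([-1, 1], k) * rng.uniform(3, 6)
                traces[name] = t
            ts = ephys.ChirpTemplateSet(times=times, traces=traces)
            a = ephys.assign_functional_cluster(
                r + rng.normal(0, 0.01, 120), times, ts)
            if not a.agreement:
                n_disagree += 1
                assert a.final_template == a.scores["correlation"].idxmax()
        assert n_disagree > 0

    def test_empty_template_set_rejected(self):
        from rgcsample.core import ConfigError

        with pytest.raises(ConfigError):
            ephys.ChirpTemplateSet(times=np.arange(5.0), traces={})


class TestRetinotopicSizeMap:
    def test_uniform_field_gives_constant_map_and_null_correlations(self):
        rng = np.random.default_rng(8)
        pos = rng.uniform(-2000, 2000, (300, 2))
        diam = np.full(300, 210.0)
        m = ephys.retinotopic_size_map(pos, diam)
        finite = m.smoothed_map[np.isfinite(m.smoothed_map)]
        assert np.allclose(finite, 210.0, atol=1e-6)
        assert abs(m.r_nasotemporal) < 1e-6 or np.isnan(m.r_nasotemporal)

    def test_noiseless_linear_gradient_gives_unit_correlation(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(-2000, 2000, (200, 2))
        diam = 150.0 - 0.02 * pos[:, 0]
        m = ephys.retinotopic_size_map(pos, diam)
        assert m.r_nasotemporal == pytest.approx(-1.0, abs=1e-9)

    def test_smoothing_preserves_global_mean_with_uniform_coverage(self):
        rng = np.random.default_rng(10)
        pos = rng.uniform(-2400, 2400, (3000, 2))
        diam = rng.uniform(100, 300, 3000)
        m = ephys.retinotopic_size_map(pos, diam)
        finite = m.smoothed_map[np.isfinite(m.smoothed_map)]
        assert finite.mean() == pytest.approx(np.median(diam), rel=0.01)

    def test_noise_calibrated_gradient_recovery(self):
        # a negative naso-temporal gradient with calibrated scatter recovers
        # r near the generating value
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(20):
            pos = rng.uniform(-2000, 2000, (120, 2))
            diam = 220 - 0.03 * pos[:, 0] + rng.normal(0, 67, 120)
            m = ephys.retinotopic_size_map(pos, diam)
            rs.append(m.r_nasotemporal)
        assert -0.80 < np.mean(rs) < -0.30

    def test_colocated_cells_rejected(self):
        pos = np.zeros((20, 2))
        with pytest.raises(ephys.DegenerateGridError):
            ephys.retinotopic_size_map(pos, np.full(20, 100.0))
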