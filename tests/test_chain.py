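"""Signal-chain tests: Laplacian, Burg band amplitude, normalizer, full chain."""
import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as st

from smrbci.chain import (ARSpec, ChainConfig, LaplacianSpec, Normalizer,
                          ar_band_amplitude, ar_band_amplitudes, burg_fit,
                          laplacian_filter, raw_control_value,
                          run_signal_chain)
from smrbci.errors import (BufferingError, InvalidArgumentError, MontageError)
from smrbci.recording import EEGRecording


def narrowband(n, fs, amp, seed, f0=12.0, bw=0.5, noise=0.3):
    """Mu-like narrowband test signal: jittered frequency plus white noise."""
    rng = np.random.default_rng(seed)
    rho = np.exp(-1.0 / (0.5 * fs))
    jit = sps.lfilter([np.sqrt(1 - rho ** 2) * bw], [1, -rho],
                      rng.standard_normal(n))
    phase = 2 * np.pi * np.cumsum(f0 + jit) / fs
    return amp * np.sin(phase + rng.uniform(0, 2 * np.pi)) \
        + noise * rng.standard_normal(n)


def periodogram_band_amplitude(x, fs, lo=10.5, hi=13.5):
    f, p = sps.periodogram(x, fs)
    sel = (f >= lo) & (f <= hi)
    return np.sqrt(p[sel].mean())


class TestLaplacian:
    def test_common_mode_rejection(self):
        labels = ("C3", "FC3", "CP3", "C1", "C5")
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 200))
        rec = EEGRecording(data, 1000, labels)
        spec = LaplacianSpec.small("C3")
        base = laplacian_filter(rec, spec)
        offset = rng.standard_normal(200)  # same c(t) added to every channel
        rec2 = EEGRecording(data + offset, 1000, labels)
        assert np.allclose(laplacian_filter(rec2, spec), base, atol=1e-9)

    def test_constant_channels_give_zero(self):
        rec = EEGRecording(np.full((5, 100), 5.0), 1000,
                           ("C3", "FC3", "CP3", "C1", "C5"))
        out = laplacian_filter(rec, LaplacianSpec.small("C3"))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_isolated_center_passes_through(self):
        data = np.zeros((5, 100))
        s = np.sin(np.arange(100))
        data[0] = s
        rec = EEGRecording(data, 1000, ("C3", "FC3", "CP3", "C1", "C5"))
        assert np.allclose(laplacian_filter(rec, LaplacianSpec.small("C3")), s)

    def test_mean_of_neighbors_definition(self):
        data = np.array([[10.0], [2.0], [4.0], [6.0], [8.0]])
        rec = EEGRecording(data, 1000, ("C3", "FC3", "CP3", "C1", "C5"))
        out = laplacian_filter(rec, LaplacianSpec.small("C3"))
        assert out[0] == pytest.approx(5.0)

    def test_missing_channel_raises(self):
        rec = EEGRecording(np.zeros((2, 10)), 1000, ("C3", "FC3"))
        with pytest.raises(MontageError):
            laplacian_filter(rec, LaplacianSpec.small("C3"))

    def test_too_few_neighbors_rejected(self):
        with pytest.raises(InvalidArgumentError):
            LaplacianSpec("C3", ("FC3",))

    def test_fallback_to_nearest_montage_neighbors(self, montage):
        sub = montage.subset([l for l in montage.labels if l != "FC3"])
        with pytest.warns(UserWarning):
            spec = LaplacianSpec.small("C3", sub)
        assert len(spec.neighbors) == 4
        assert "FC3" not in spec.neighbors


class TestARBandAmplitude:
    def test_zero_window_gives_zero_amplitude(self):
        assert ar_band_amplitude(np.zeros(600), 1000) < 1e-9

    def test_window_too_short_raises(self):
        with pytest.raises(InvalidArgumentError):
            ar_band_amplitude(np.zeros(20), 1000, ARSpec(order=16))

    def test_scale_equivariance_within_one_percent(self):
        x = narrowband(500, 1000, 1.0, seed=1)
        base = ar_band_amplitude(x, 1000)
        for k in (0.5, 2.0, 7.3):
            assert ar_band_amplitude(k * x, 1000) == pytest.approx(
                k * base, rel=0.01)

    def test_amplitude_doubles_with_source_amplitude(self):
        # 12 Hz narrowband realizations of amplitude A and 2A with the same
        # phase/noise seed (the whole realization scales, i.e. fixed SNR)
        # -> band-amplitude ratio 2 within 5%.  With amplitude-independent
        # additive noise the Burg bin-mean is deliberately NOT power-linear
        # (the normalizer absorbs scale; only monotonicity is contractual,
        # covered by the rank-correlation test below).
        for seed in range(5):
            a1 = ar_band_amplitude(
                narrowband(500, 1000, 1.0, seed=seed, noise=0.3), 1000)
            a2 = ar_band_amplitude(
                narrowband(500, 1000, 2.0, seed=seed, noise=0.6), 1000)
            assert a2 / a1 == pytest.approx(2.0, rel=0.05)

    def test_out_of_band_tone_strongly_rejected(self):
        rng = np.random.default_rng(3)
        noise = 0.02 * rng.standard_normal(500)
        t = np.arange(500) / 1000
        in_band = ar_band_amplitude(np.sin(2 * np.pi * 12 * t) + noise, 1000)
        out_band = ar_band_amplitude(np.sin(2 * np.pi * 30 * t) + noise, 1000)
        assert out_band < 0.1 * in_band

    def test_rank_correlation_with_periodogram_oracle(self):
        # 50 random narrowband amplitudes on 4 s windows
        rng = np.random.default_rng(42)
        amps = rng.uniform(0.2, 5.0, size=50)
        ar_vals, pg_vals = [], []
        for i, a in enumerate(amps):
            x = narrowband(4000, 1000, a, seed=100 + i)
            ar_vals.append(ar_band_amplitude(x, 1000))
            pg_vals.append(periodogram_band_amplitude(x, 1000))
        rho = st.spearmanr(ar_vals, pg_vals).statistic
        assert rho > 0.95

    def test_batch_matches_single_window_path(self):
        rng = np.random.default_rng(9)
        W = rng.standard_normal((7, 500))
        batch = ar_band_amplitudes(W, 1000)
        singles = [ar_band_amplitude(w, 1000) for w in W]
        assert np.allclose(batch, singles, rtol=1e-6)

    def test_burg_matches_independent_reference(self):
        from statsmodels.regression.linear_model import burg as sm_burg

        rng = np.random.default_rng(11)
        for _ in range(10):
            x = narrowband(400, 1000, rng.uniform(0.5, 2.0), seed=rng.integers(1e6))
            a, _ = burg_fit(x - x.mean(), 12)
            phi, _ = sm_burg(x, 12, demean=True)
            assert np.allclose(a[1:], -phi, atol=1e-3)


class TestControlLaw:
    def test_lr_is_difference_ud_is_sum(self):
        assert raw_control_value(0.7, 1.2, "LR") == pytest.approx(0.5)
        assert raw_control_value(0.7, 1.2, "UD") == pytest.approx(1.9)
        assert raw_control_value(1.0, 1.0, "LR") == 0.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidArgumentError):
            raw_control_value(-0.1, 1.0, "LR")
        with pytest.raises(InvalidArgumentError):
            raw_control_value(0.1, 1.0, "XY")


class TestNormalizer:
    def test_constant_input_pins_output_to_zero(self):
        norm = Normalizer(100)
        out = [norm.update(3.5) for _ in range(300)]
        assert all(v == 0.0 for v in out)

    def test_warmup_emits_zero(self):
        norm = Normalizer(100)
        assert norm.update(1.0) == 0.0

    def test_stationary_stream_converges_to_zero_mean_unit_variance(self):
        rng = np.random.default_rng(1)
        norm = Normalizer(750)  # 30 s at 40 ms ticks
        stream = 5.0 + 2.0 * rng.standard_normal(3000)  # 120 s of ticks
        out = np.array([norm.update(v) for v in stream])
        tail = out[750:]
        assert abs(tail.mean()) < 0.1
        assert 0.8 < tail.var() < 1.2

    def test_adapts_within_buffer_length_after_mean_step(self):
        rng = np.random.default_rng(2)
        norm = Normalizer(750)
        for v in rng.standard_normal(1500):
            norm.update(v)
        stepped = 10.0 + rng.standard_normal(1500)
        out = np.array([norm.update(v) for v in stepped])
        assert abs(out[750:].mean()) < 0.1  # back near 0 within 30 s

    def test_non_finite_raw_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Normalizer(10).update(float("nan"))


class TestRunSignalChain:
    def _recording(self, data, fs=1000):
        labels = ("C3", "FC3", "CP3", "C1", "C5",
                  "C4", "FC4", "CP4", "C2", "C6")
        return EEGRecording(data, fs, labels)

    def test_zero_recording_gives_all_zero_normalized(self):
        rec = self._recording(np.zeros((10, 3000)))
        trace = run_signal_chain(rec, task="LR")
        assert np.allclose(trace.normalized, 0.0)

    def test_tick_count_arithmetic(self):
        # floor((n_samples - window) / hop) + 1
        rng = np.random.default_rng(0)
        rec = self._recording(rng.standard_normal((10, 3123)))
        trace = run_signal_chain(rec, task="LR")
        assert trace.n_ticks == (3123 - 500) // 40 + 1

    def test_causality_under_truncation(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 4000))
        full = run_signal_chain(self._recording(data), task="UD")
        trunc = run_signal_chain(self._recording(data[:, :2500]), task="UD")
        n = trunc.n_ticks
        assert np.allclose(full.raw[:n], trunc.raw[:n], rtol=1e-6)
        assert np.allclose(full.normalized[:n], trunc.normalized[:n], rtol=1e-6)

    def test_underrun_raises(self):
        rec = self._recording(np.zeros((10, 100)))
        with pytest.raises(BufferingError):
            run_signal_chain(rec, task="LR")

    def test_right_mi_raises_lr_control_value(self, bci_montage):
        # ERD at C3 during right-hand imagery -> C4 - C3 above its mean
        from smrbci.synth import alternating_schedule, add_mu_sources, \
            generate_background_eeg, generate_subject

        fs = 500
        subj = generate_subject(dict(erd_depth=0.5, alpha_amplitude=0.0), seed=6)
        sched = alternating_schedule(["rest", "right_MI"], 10.0, 12)
        rec = generate_background_eeg(bci_montage, 120.0, fs, 4.0, seed=7)
        rec = add_mu_sources(rec, subj, sched, bci_montage)
        trace = run_signal_chain(rec, task="LR")
        cond = np.array([sched.condition_gain(rec.n_samples, fs,
                                              {"right_MI": 0.0}, 1.0)
                         [int(t * fs) - 1] for t in trace.times])
        warm = trace.times > 40.0  # let the normalizer settle
        mi = trace.normalized[(cond == 0.0) & warm]
        rest = trace.normalized[(cond == 1.0) & warm]
        assert mi.mean() > rest.mean() + 0.2

    def test_trace_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        rec = self._recording(rng.standard_normal((10, 2000)))
        trace = run_signal_chain(rec, task="LR")
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import csv

        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == trace.n_ticks
        assert float(rows[3]["raw"]) == pytest.approx(trace.raw[3])


class TestChainConfig:
    def test_required_channels_cover_both_laplacians(self):
        chain = ChainConfig()
        req = set(chain.required_channels())
        assert {"C3", "C4", "FC3", "CP3", "C1", "C5",
                "FC4", "CP4", "C2", "C6"} == req

    def test_buffer_ticks_is_thirty_seconds_of_updates(self):
        assert ChainConfig().buffer_ticks == 750

    def test_describe_mentions_band_and_order(self):
        text = ChainConfig().describe()
        assert "order=16" in text and "[10.5, 13.5]" in text
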