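"""Offline pipeline: screening, interpolation, preprocessing, topographies,
offline control signal and Δcontrol."""
import numpy as np
import pytest
from scipy import signal as sps

from smrbci.errors import InterpolationError, InvalidArgumentError
from smrbci.montage import BCI_CHANNELS, MontageLayout
from smrbci.offline import (CANONICAL_BANDS, MU_BAND, BandDefinition, EpochSet,
                            DeltaControlSummary, PreprocConfig, TopographyMap,
                            band_power_topography, common_average_reference,
                            correlate_delta_with_pvc, delta_control,
                            detect_bad_channels, electrode_power,
                            epochs_from_intervals, interpolate_channels,
                            offline_control_signal, preprocess, reject_trials)
from smrbci.recording import EEGRecording
from smrbci.synth import (alternating_schedule, add_mu_sources,
                          generate_background_eeg, generate_subject,
                          inject_artifacts)


def smooth_field_recording(montage, n_sources=5, duration=4.0, fs=250, seed=0):
    """Recording driven by a few spatially smooth source patterns."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    data = np.zeros((len(montage), n))
    for _ in range(n_sources):
        center = montage.positions[rng.integers(len(montage))]
        d = np.arccos(np.clip(montage.positions @ center, -1, 1))
        gain = np.exp(-0.5 * (d / 0.8) ** 2)
        data += gain[:, None] * rng.standard_normal(n)[None, :]
    return EEGRecording(data, fs, montage.labels)


class TestBadChannelDetection:
    def test_homogeneous_recording_flags_nothing(self, montage):
        rec = generate_background_eeg(montage, 5.0, 500, 4.0, seed=1)
        assert detect_bad_channels(rec) == []

    def test_fifty_fold_variance_channel_uniquely_flagged(self, montage):
        rec = generate_background_eeg(montage, 5.0, 500, 4.0, seed=2)
        bad = inject_artifacts(rec, bad_channels=["F7"], seed=3)
        assert detect_bad_channels(bad, threshold_z=5.0) == ["F7"]

    def test_flat_channel_flagged(self, montage):
        rec = generate_background_eeg(montage, 5.0, 500, 4.0, seed=4)
        rec.data[rec.index("P3")] = 0.0
        assert detect_bad_channels(rec) == ["P3"]

    def test_too_few_channels_rejected(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((4, 100)),
                           100, ("C3", "C4", "Cz", "Pz"))
        with pytest.raises(InvalidArgumentError):
            detect_bad_channels(rec)


class TestInterpolation:
    def test_leave_one_out_recovery_on_smooth_field(self, montage):
        rec = smooth_field_recording(montage, seed=5)
        original = rec.get("C1").copy()
        removed = rec.copy()
        removed.data[rec.index("C1")] = np.random.default_rng(1).normal(
            size=rec.n_samples)
        fixed = interpolate_channels(removed, ["C1"], montage)
        rho = np.corrcoef(fixed.get("C1"), original)[0, 1]
        assert rho > 0.95

    def test_zero_good_channels_give_zero_interpolant(self, montage):
        rec = EEGRecording(np.zeros((len(montage), 500)), 250, montage.labels)
        rec.data[rec.index("C1")] = 7.0
        fixed = interpolate_channels(rec, ["C1"], montage)
        assert np.allclose(fixed.get("C1"), 0.0, atol=1e-9)

    def test_empty_label_list_is_identity(self, montage):
        rec = smooth_field_recording(montage, seed=6)
        out = interpolate_channels(rec, [], montage)
        assert np.array_equal(out.data, rec.data)

    def test_too_few_good_channels_raise(self):
        labels = ("C3", "C4", "Cz", "Pz", "Fz")
        rec = EEGRecording(np.ones((5, 100)), 100, labels)
        montage = MontageLayout.standard(labels)
        with pytest.raises(InterpolationError):
            interpolate_channels(rec, ["C3", "C4"], montage)


class TestPreprocess:
    def test_slow_drift_attenuated_by_over_20_db(self, montage):
        fs = 1000
        t = np.arange(int(20 * fs)) / fs
        drift = 50 * np.sin(2 * np.pi * 0.3 * t)
        carrier = np.sin(2 * np.pi * 10 * t)
        rng = np.random.default_rng(3)
        data = np.tile(drift + carrier, (len(montage), 1)) \
            + rng.standard_normal((len(montage), len(t)))
        rec = EEGRecording(data, fs, montage.labels)
        out = preprocess(rec, PreprocConfig(car=False), montage)

        def power_at(x, f0, fs):
            f, p = sps.periodogram(x, fs)
            return p[np.argmin(np.abs(f - f0))]

        x_in, x_out = rec.get("Cz"), out.get("Cz")
        drop = power_at(x_in, 0.3, fs) / max(power_at(x_out, 0.3, 250), 1e-12)
        keep = power_at(x_in, 10, fs) / max(power_at(x_out, 10, 250), 1e-12)
        assert drop > 100          # > 20 dB at 0.3 Hz
        assert keep < 10           # passband substantially preserved

    def test_output_is_car_referenced_and_resampled(self, montage):
        rec = generate_background_eeg(montage, 60.0, 1000, 4.0, seed=7)
        out = preprocess(rec, PreprocConfig(), montage)
        assert out.fs == 250.0
        assert out.n_samples == 15000
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_car_is_idempotent(self, montage):
        rec = generate_background_eeg(montage, 2.0, 500, 4.0, seed=8)
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_native_rate_must_cover_band(self, montage):
        rec = generate_background_eeg(montage, 2.0, 500, 4.0, seed=8)
        rec = EEGRecording(rec.data, 150.0, rec.labels)
        with pytest.raises(InvalidArgumentError):
            preprocess(rec, PreprocConfig())


class TestTrialRejection:
    def _epochs(self, scale_one=None, n=10, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 4, 200))
        if scale_one is not None:
            data[3] *= scale_one
        labels = tuple(np.where(np.arange(n) % 2, "left", "right"))
        return EpochSet(data, labels, 250, "LR", ("C3", "C4", "Cz", "Pz"))

    def test_homogeneous_epochs_all_kept(self):
        ep = self._epochs()
        assert reject_trials(ep).n_trials == 10

    def test_twenty_fold_epoch_uniquely_removed_with_labels_aligned(self):
        ep = self._epochs(scale_one=np.sqrt(20))
        out = reject_trials(ep, threshold_z=5.0)
        assert out.n_trials == 9
        expected = tuple(l for i, l in enumerate(ep.class_labels) if i != 3)
        assert out.class_labels == expected

    def test_infinite_threshold_is_identity(self):
        ep = self._epochs(scale_one=50.0)
        assert reject_trials(ep, threshold_z=np.inf).n_trials == 10

    def test_fewer_than_three_trials_rejected(self):
        ep = self._epochs(n=3)
        with pytest.raises(InvalidArgumentError):
            reject_trials(EpochSet(ep.data[:2], ep.class_labels[:2], 250,
                                   "LR", ep.ch_labels))


class TestElectrodePower:
    def test_constant_channel_has_zero_power(self):
        rec = EEGRecording(np.full((2, 1000), 3.3), 250, ("C3", "C4"))
        assert np.allclose(electrode_power(rec).power, 0.0)

    def test_unit_sinusoid_has_power_half(self):
        fs, f0 = 250, 5.0
        t = np.arange(fs * 4) / fs  # whole periods
        rec = EEGRecording(np.sin(2 * np.pi * f0 * t)[None, :], fs, ("Cz",))
        assert electrode_power(rec).value("Cz") == pytest.approx(0.5, rel=0.01)

    def test_scaling_a_channel_scales_power_quadratically(self, rng):
        data = rng.standard_normal((2, 500))
        rec = EEGRecording(data, 250, ("C3", "C4"))
        scaled = EEGRecording(data * np.array([[3.0], [1.0]]), 250,
                              ("C3", "C4"))
        p0, p1 = electrode_power(rec).power, electrode_power(scaled).power
        assert p1[0] == pytest.approx(9 * p0[0])
        assert p1[1] == pytest.approx(p0[1])


class TestBandTopography:
    def test_pure_delta_tone_dominates_beta(self, montage):
        fs = 250
        t = np.arange(fs * 8) / fs
        data = np.tile(np.sin(2 * np.pi * 2.0 * t), (len(montage), 1))
        rec = EEGRecording(data, fs, montage.labels)
        delta = band_power_topography(rec, CANONICAL_BANDS[0]).power.mean()
        beta = band_power_topography(rec, CANONICAL_BANDS[3]).power.mean()
        assert delta > 100 * beta

    def test_zero_recording_gives_zero_maps_in_every_band(self, montage):
        rec = EEGRecording(np.zeros((len(montage), 1000)), 250, montage.labels)
        for band in CANONICAL_BANDS:
            assert np.allclose(band_power_topography(rec, band).power, 0.0,
                               atol=1e-20)

    def test_band_powers_subadditive_vs_broadband(self, montage):
        # on a 1-30 Hz band-limited signal the four canonical bands cover
        # the broadband power up to filter leakage
        rec = generate_background_eeg(montage, 30.0, 250, 4.0, seed=9)
        from smrbci.offline import bandpass

        limited = bandpass(rec, 1.0, 30.0)
        broadband = electrode_power(limited).power
        total = sum(band_power_topography(limited, b).power
                    for b in CANONICAL_BANDS)
        assert np.all(total <= 1.1 * broadband)

    def test_group_average_and_csv(self, montage, tmp_path):
        rec = generate_background_eeg(montage, 5.0, 250, 4.0, seed=10)
        maps = [electrode_power(rec) for _ in range(3)]
        avg = TopographyMap.group_average(maps)
        assert avg.n_subjects == 3
        avg.to_csv(tmp_path / "topo.csv", montage)
        import csv

        rows = list(csv.DictReader(open(tmp_path / "topo.csv")))
        assert len(rows) == len(montage)
        assert float(rows[0]["power"]) >= 0


class TestOfflineControl:
    def _mi_epochs(self, erd=0.6, n_blocks=16, fs=250, seed=0):
        montage = MontageLayout.standard(BCI_CHANNELS)
        subj = generate_subject(dict(erd_depth=erd, alpha_amplitude=0.0),
                                seed=seed)
        block = 4.0
        sched = alternating_schedule(["left_MI", "right_MI"], block, n_blocks)
        rec = generate_background_eeg(montage, block * n_blocks, fs, 4.0,
                                      seed=seed + 1)
        rec = add_mu_sources(rec, subj, sched, montage)
        intervals = [(i * block + 0.5, "left" if i % 2 == 0 else "right")
                     for i in range(n_blocks)]
        return epochs_from_intervals(rec, intervals, 3.0, "LR")

    def test_normalized_values_have_zero_mean_unit_sd(self):
        ctl = offline_control_signal(self._mi_epochs())
        assert abs(ctl.normalized.mean()) < 1e-9
        assert ctl.normalized.std() == pytest.approx(1.0, abs=1e-9)

    def test_constructed_erd_separates_classes_in_the_right_direction(self):
        ctl = offline_control_signal(self._mi_epochs(erd=0.6))
        right = ctl.normalized[[l == "right" for l in ctl.class_labels]]
        left = ctl.normalized[[l == "left" for l in ctl.class_labels]]
        assert right.mean() > left.mean()

    def test_null_epochs_have_small_class_means(self):
        ctl = offline_control_signal(self._mi_epochs(erd=0.0, n_blocks=24))
        for cls in ("left", "right"):
            vals = ctl.normalized[[l == cls for l in ctl.class_labels]]
            assert abs(vals.mean()) < 0.3

    def test_missing_laplacian_channels_raise(self):
        ep = EpochSet(np.zeros((4, 2, 100)), ("left",) * 4, 250, "LR",
                      ("C3", "C4"))
        from smrbci.errors import MontageError

        with pytest.raises(MontageError):
            offline_control_signal(ep)


class TestDeltaControl:
    def test_symmetric_classes_give_small_delta(self, rng):
        vals = rng.standard_normal(60)
        labels = ["left", "right"] * 30
        assert abs(delta_control(vals, labels, "LR")) < 0.3

    def test_arithmetic_on_constructed_values(self):
        vals = np.array([0.8, -0.8] * 15)
        labels = ["right", "left"] * 15
        assert delta_control(vals, labels, "LR") == pytest.approx(1.6)
        # UD orientation: down minus up
        vals_ud = np.array([0.8, -0.8] * 15)
        labels_ud = ["down", "up"] * 15
        assert delta_control(vals_ud, labels_ud, "UD") == pytest.approx(1.6)

    def test_label_shuffle_null_is_centered_on_zero(self, rng):
        vals = np.concatenate([rng.normal(1.0, 1.0, 30),
                               rng.normal(-1.0, 1.0, 30)])
        labels = np.array(["right"] * 30 + ["left"] * 30)
        deltas = []
        for _ in range(200):
            rng.shuffle(labels)
            deltas.append(delta_control(vals, labels, "LR"))
        assert abs(np.mean(deltas)) < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            delta_control([1.0, 2.0], ["left", "left"], "LR")


class TestCorrelateDeltaWithPVC:
    def test_positive_association_recovered(self, rng):
        summaries = []
        for i in range(20):
            d = rng.uniform(0, 2)
            summaries.append(DeltaControlSummary(
                f"s{i}", "LR", d, 50 + 20 * d + rng.normal(0, 5)))
        res = correlate_delta_with_pvc(summaries)
        assert res.statistic > 0 and res.p < 0.05

    def test_too_few_subjects_rejected(self):
        rows = [DeltaControlSummary(str(i), "LR", i, i) for i in range(4)]
        with pytest.raises(InvalidArgumentError):
            correlate_delta_with_pvc(rows)
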