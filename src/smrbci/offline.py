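"""Offline EEG analysis pipeline.

Mirrors a conventional sensorimotor-BCI offline workflow: variance-based
bad-channel screening with spherical-spline interpolation, 1–100 Hz
band-pass, downsampling to 250 Hz, common-average re-reference, detrending,
variance-based trial rejection, per-electrode (band) power topographies,
and an offline reconstruction of the online control signal from which the
per-subject Δcontrol class-separability statistic is computed.

Offline filters are zero-phase (forward-backward); only the online chain in
:mod:`smrbci.chain` is causal.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .chain import ChainConfig
from .errors import (DegenerateDataError, EmptyEpochsError,
                     InterpolationError, InvalidArgumentError, MontageError)
from .montage import MontageLayout
from .recording import EEGRecording
from .stats import StatResult, spearman

# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class PreprocConfig:
    """Offline preprocessing settings (order fixed: bad-channel repair,
    band-pass, downsample, common average reference, detrend)."""

    l_freq: float = 1.0
    h_freq: float = 100.0
    target_fs: float = 250.0
    bad_z: float = 5.0
    notch_60: bool = False
    car: bool = True

    def __post_init__(self):
        if not 0 < self.l_freq < self.h_freq:
            raise InvalidArgumentError("need 0 < l_freq < h_freq")
        if self.target_fs <= 0:
            raise InvalidArgumentError("target_fs must be positive")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise InvalidArgumentError("need 0 < low < high")


#: canonical frequency bands used for the group topography maps
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass
class TopographyMap:
    """Per-electrode power values (µV²) for one frequency band."""

    labels: tuple[str, ...]
    power: np.ndarray
    band: str = "broadband"
    n_subjects: int = 1

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.labels) != len(self.power):
            raise InvalidArgumentError("one power value per label required")
        if np.any(self.power < -1e-12):
            raise InvalidArgumentError("power values must be nonnegative")

    def value(self, label: str) -> float:
        return float(self.power[self.labels.index(label)])

    def argmax_label(self) -> str:
        return self.labels[int(np.argmax(self.power))]

    @classmethod
    def group_average(cls, maps: Sequence["TopographyMap"]) -> "TopographyMap":
        if not maps:
            raise InvalidArgumentError("no maps to average")
        labels = maps[0].labels
        if any(m.labels != labels or m.band != maps[0].band for m in maps):
            raise InvalidArgumentError("maps must share labels and band")
        power = np.mean([m.power for m in maps], axis=0)
        return cls(labels, power, maps[0].band, sum(m.n_subjects for m in maps))

    def to_csv(self, path, montage: MontageLayout | None = None) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            if montage is not None:
                proj = {lab: xy for lab, xy in
                        zip(montage.labels, montage.projection_2d())}
                w.writerow(["channel", "x", "y", "power"])
                for lab, p in zip(self.labels, self.power):
                    x, y = proj[lab]
                    w.writerow([lab, f"{x:.4f}", f"{y:.4f}", repr(float(p))])
            else:
                w.writerow(["channel", "power"])
                for lab, p in zip(self.labels, self.power):
                    w.writerow([lab, repr(float(p))])


@dataclass
class EpochSet:
    """Fixed-length trials x channels x samples with per-trial class labels."""

    data: np.ndarray
    class_labels: tuple[str, ...]
    fs: float
    task: str
    ch_labels: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("epochs must be 3D (trials, ch, samples)")
        self.class_labels = tuple(self.class_labels)
        self.ch_labels = tuple(self.ch_labels)
        if len(self.class_labels) != self.data.shape[0]:
            raise InvalidArgumentError("one class label per trial required")
        if len(self.ch_labels) != self.data.shape[1]:
            raise InvalidArgumentError("one channel label per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class DeltaControlSummary:
    """Per-subject offline class separability paired with performance."""

    subject: str
    task: str
    delta: float
    pvc: float


# ---------------------------------------------------------------------------
# channel screening and repair


def detect_bad_channels(recording: EEGRecording, threshold_z: float = 5.0
                        ) -> list[str]:
    """Flag channels by robust z-score of log variance (plus flat channels).

    The z-score uses the median and MAD of the per-channel log variances, so
    a single extreme channel cannot mask itself.
    """
    if recording.n_channels < 8:
        raise InvalidArgumentError("need >= 8 channels for variance screening")
    var = recording.data.var(axis=1)
    med = float(np.median(var))
    flat = var <= max(med, 1.0) * 1e-12
    bad = set(np.array(recording.labels)[flat])
    ok = ~flat
    if ok.sum() >= 3:
        logv = np.log(var[ok])
        center = np.median(logv)
        mad = np.median(np.abs(logv - center)) * 1.4826
        if mad > 0:
            z = (logv - center) / mad
            for lab, zz in zip(np.array(recording.labels)[ok], z):
                if abs(zz) > threshold_z:
                    bad.add(lab)
    return [lab for lab in recording.labels if lab in bad]


def interpolate_channels(recording: EEGRecording, labels: Sequence[str],
                         montage: MontageLayout) -> EEGRecording:
    """Replace flagged channels by spherical-spline interpolation.

    Delegates to MNE's spherical-spline implementation (spline order m=4,
    regularization 1e-5) over the remaining good channels.
    """
    labels = list(labels)
    if not labels:
        return recording.copy()
    for lab in labels:
        recording.index(lab)
        if lab not in montage:
            raise MontageError(f"channel {lab!r} not in montage")
    n_good = recording.n_channels - len(labels)
    if n_good < 4:
        raise InterpolationError("fewer than 4 good channels remain")
    import mne

    info = mne.create_info(list(recording.labels), recording.fs, "eeg",
                           verbose="error")
    raw = mne.io.RawArray(recording.data * 1e-6, info, verbose="error")
    with np.errstate(invalid="ignore"):
        raw.set_montage("standard_1005", on_missing="raise", verbose="error")
    raw.info["bads"] = labels
    raw.interpolate_bads(reset_bads=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, recording.fs, recording.labels)


# ---------------------------------------------------------------------------
# preprocessing


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if high >= nyq:
        raise InvalidArgumentError("band edge at or above Nyquist")
    return sps.butter(order, [low / nyq, high / nyq], btype="bandpass",
                      output="sos")


def bandpass(recording: EEGRecording, low: float, high: float,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel."""
    sos = _bandpass_sos(low, high, recording.fs, order)
    data = sps.sosfiltfilt(sos, recording.data, axis=1)
    return EEGRecording(data, recording.fs, recording.labels)


def preprocess(recording: EEGRecording, config: PreprocConfig | None = None,
               montage: MontageLayout | None = None) -> EEGRecording:
    """Full offline preprocessing chain.

    Steps, in order: bad-channel detection and spherical interpolation,
    optional 60 Hz notch, zero-phase 1–100 Hz band-pass, polyphase
    downsampling to 250 Hz, common average reference, mean removal and
    linear detrend.
    """
    config = config or PreprocConfig()
    if recording.fs < 2 * config.h_freq:
        raise InvalidArgumentError("native rate below twice the upper edge")
    if config.target_fs > recording.fs:
        raise InvalidArgumentError("target rate above native rate")
    rec = recording
    bads = detect_bad_channels(rec, config.bad_z) if rec.n_channels >= 8 else []
    if bads:
        if montage is None:
            montage = MontageLayout.standard(rec.labels)
        rec = interpolate_channels(rec, bads, montage)
    data = rec.data
    if config.notch_60:
        b, a = sps.iirnotch(60.0, 30.0, fs=rec.fs)
        data = sps.filtfilt(b, a, data, axis=1)
    sos = _bandpass_sos(config.l_freq, config.h_freq, rec.fs)
    data = sps.sosfiltfilt(sos, data, axis=1)
    frac = Fraction(config.target_fs / rec.fs).limit_denominator(1000)
    if frac != 1:
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    if config.car:
        data = data - data.mean(axis=0, keepdims=True)
    data = data - data.mean(axis=1, keepdims=True)
    data = sps.detrend(data, axis=1, type="linear")
    return EEGRecording(data, config.target_fs, rec.labels)


def common_average_reference(recording: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous across-channel mean from every channel."""
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, recording.fs, recording.labels)


# ---------------------------------------------------------------------------
# trial screening


def reject_trials(epochs: EpochSet, threshold_z: float = 5.0) -> EpochSet:
    """Drop trials with abnormally large pooled-channel variance.

    Robust z on log pooled variance (median/MAD over trials); one-sided —
    only abnormally *large* trials are artifacts worth dropping, and a
    two-sided rule on the tightly concentrated per-trial variances would
    discard clean low-variance trials.
    """
    if epochs.n_trials < 3:
        raise InvalidArgumentError("need >= 3 trials for variance screening")
    var = epochs.data.var(axis=(1, 2))
    logv = np.log(np.maximum(var, 1e-300))
    center = np.median(logv)
    mad = np.median(np.abs(logv - center)) * 1.4826
    if mad > 0 and np.isfinite(threshold_z):
        keep = (logv - center) / mad <= threshold_z
    else:
        keep = np.ones(epochs.n_trials, dtype=bool)
    if not keep.any():
        raise EmptyEpochsError("all trials rejected")
    labels = tuple(np.array(epochs.class_labels)[keep])
    return EpochSet(epochs.data[keep], labels, epochs.fs, epochs.task,
                    epochs.ch_labels)


# ---------------------------------------------------------------------------
# power topographies


def electrode_power(recording: EEGRecording) -> TopographyMap:
    """Mean squared deviation from each electrode's own mean (µV²).

    This is the population-convention sample variance of each channel.
    """
    if recording.duration < 1.0:
        raise InvalidArgumentError("need >= 1 s of data")
    return TopographyMap(recording.labels, recording.data.var(axis=1),
                         band="broadband")


def band_power_topography(recording: EEGRecording, band: BandDefinition
                          ) -> TopographyMap:
    """Electrode power of the zero-phase band-passed recording."""
    filtered = bandpass(recording, band.low, band.high)
    out = electrode_power(filtered)
    out.band = band.name
    return out


# ---------------------------------------------------------------------------
# offline control signal and Δcontrol


@dataclass
class OfflineControl:
    """Per-trial raw and z-scored offline control values."""

    raw: np.ndarray
    normalized: np.ndarray
    class_labels: tuple[str, ...]
    task: str


#: offline mu band matching the online 3 Hz bin around 12 Hz
MU_BAND = BandDefinition("mu", 10.5, 13.5)


def offline_control_signal(epochs: EpochSet, chain: ChainConfig | None = None,
                           mu_band: BandDefinition = MU_BAND) -> OfflineControl:
    """Reconstruct the control signal per trial from epoched EEG.

    Per trial: small-Laplacian C3 and C4 series over the control period,
    zero-phase band-pass to the mu bin, band power = variance; the raw value
    is C4 - C3 power (LR) or C4 + C3 power (UD), then z-scored across all
    the subject's trials with classes pooled.
    """
    chain = chain or ChainConfig()
    w3 = chain.lap_c3.weights(epochs.ch_labels)
    w4 = chain.lap_c4.weights(epochs.ch_labels)
    lap3 = np.einsum("c,tcs->ts", w3, epochs.data)
    lap4 = np.einsum("c,tcs->ts", w4, epochs.data)
    sos = _bandpass_sos(mu_band.low, mu_band.high, epochs.fs)
    p3 = sps.sosfiltfilt(sos, lap3, axis=1).var(axis=1)
    p4 = sps.sosfiltfilt(sos, lap4, axis=1).var(axis=1)
    sign = -1.0 if epochs.task == "LR" else 1.0
    raw = p4 + sign * p3
    sd = raw.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("offline control values have zero variance")
    return OfflineControl(raw, (raw - raw.mean()) / sd, epochs.class_labels,
                          epochs.task)


#: Δcontrol orientation per task: positive difference means the class pair
#: separates in the direction that drives the cursor correctly.  For LR,
#: right-hand imagery raises C4-C3, so right minus left; for UD with the
#: up-velocity proportional to minus (C4+C3), imagery (up) lowers the sum,
#: so down minus up.
_DELTA_ORIENT = {"LR": ("right", "left"), "UD": ("down", "up")}


def delta_control(values: np.ndarray, labels: Sequence[str],
                  task: str | None = None) -> float:
    """Difference of class-mean control values, oriented so that better
    class separation in the task's correct direction is positive."""
    labels = tuple(labels)
    values = np.asarray(values, dtype=float)
    if len(values) != len(labels):
        raise InvalidArgumentError("one label per value required")
    present = set(labels)
    if task is None:
        for t, pair in _DELTA_ORIENT.items():
            if present <= set(pair):
                task = t
                break
        else:
            raise InvalidArgumentError(f"cannot infer task from labels {present}")
    pos, neg = _DELTA_ORIENT[task]
    if not ({pos, neg} <= present):
        raise InvalidArgumentError(
            f"need at least one trial of each class {pos!r}/{neg!r}")
    v_pos = values[[l == pos for l in labels]]
    v_neg = values[[l == neg for l in labels]]
    return float(v_pos.mean() - v_neg.mean())


def subject_delta_control(epochs: EpochSet, pvc: float, subject: str = "",
                          chain: ChainConfig | None = None) -> DeltaControlSummary:
    """Convenience: epochs + performance -> one DeltaControlSummary row."""
    ctl = offline_control_signal(epochs, chain)
    d = delta_control(ctl.normalized, ctl.class_labels, epochs.task)
    return DeltaControlSummary(subject, epochs.task, d, pvc)


def delta_summaries_to_csv(summaries: Sequence[DeltaControlSummary],
                           path) -> None:
    """Write per-subject Δcontrol/PVC rows as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "task", "delta", "pvc"])
        for s in summaries:
            w.writerow([s.subject, s.task, repr(float(s.delta)),
                        repr(float(s.pvc))])


def correlate_delta_with_pvc(summaries: Sequence[DeltaControlSummary]
                             ) -> StatResult:
    """Spearman rank correlation between per-subject Δcontrol and PVC."""
    if len(summaries) < 5:
        raise InvalidArgumentError("need >= 5 subjects")
    deltas = [s.delta for s in summaries]
    pvcs = [s.pvc for s in summaries]
    return spearman(deltas, pvcs)


# ---------------------------------------------------------------------------
# epoch construction


def epochs_from_intervals(recording: EEGRecording,
                          intervals: Sequence[tuple[float, str]],
                          epoch_s: float, task: str) -> EpochSet:
    """Cut fixed-length epochs starting at (onset_s, class_label) pairs."""
    n = int(round(epoch_s * recording.fs))
    if n < 2:
        raise InvalidArgumentError("epoch too short")
    data = []
    labels = []
    for onset, lab in intervals:
        i0 = int(round(onset * recording.fs))
        if i0 < 0 or i0 + n > recording.n_samples:
            raise InvalidArgumentError("epoch outside recording")
        data.append(recording.data[:, i0:i0 + n])
        labels.append(lab)
    return EpochSet(np.stack(data), tuple(labels), recording.fs, task,
                    recording.labels)
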