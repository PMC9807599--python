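"""Online control-signal chain of a sensorimotor-rhythm BCI.

The chain mirrors the standard BCI2000-style front-end: a small surface
Laplacian at C3 and C4, maximum-entropy (Burg) autoregressive spectral
amplitude in a 3 Hz bin around 12 Hz on a short trailing window, an adaptive
normalizer that maps the raw C4-C3 (left/right) or C4+C3 (up/down)
combination to zero mean and unit variance using statistics from a 30 s
buffer, and a 40 ms update tick.  Everything here is causal: a control value
at tick t depends only on samples up to t.
"""
from __future__ import annotations

import collections
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (BufferingError, DegenerateDataError, InvalidArgumentError,
                     MontageError)
from .montage import MontageLayout
from .recording import EEGRecording

# ---------------------------------------------------------------------------
# surface Laplacian

#: conventional small-Laplacian neighbour sets on an extended 10-20 cap
SMALL_LAPLACIAN_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "C3": ("FC3", "CP3", "C1", "C5"),
    "C4": ("FC4", "CP4", "C2", "C6"),
}


@dataclass(frozen=True)
class LaplacianSpec:
    """Center electrode minus the mean of its neighbour set."""

    center: str
    neighbors: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "neighbors", tuple(self.neighbors))
        if len(self.neighbors) < 2:
            raise InvalidArgumentError("Laplacian needs >= 2 neighbors")
        if self.center in self.neighbors:
            raise InvalidArgumentError("center cannot be its own neighbor")

    @classmethod
    def small(cls, center: str, montage: MontageLayout | None = None) -> "LaplacianSpec":
        """Default small Laplacian; falls back to nearest montage neighbours."""
        neighbors = SMALL_LAPLACIAN_NEIGHBORS.get(center)
        if montage is not None:
            if neighbors is None or any(n not in montage for n in neighbors):
                fallback = montage.nearest_neighbors(center, k=4)
                warnings.warn(
                    f"standard small-Laplacian neighbours unavailable for "
                    f"{center}; using nearest montage neighbours {fallback}",
                    stacklevel=2)
                neighbors = fallback
        elif neighbors is None:
            raise MontageError(f"no default neighbour set for {center!r}")
        return cls(center, tuple(neighbors))

    def weights(self, labels: tuple[str, ...]) -> np.ndarray:
        """Weight vector over `labels`: +1 center, -1/k per neighbour."""
        index = {lab: i for i, lab in enumerate(labels)}
        missing = [l for l in (self.center, *self.neighbors) if l not in index]
        if missing:
            raise MontageError(f"missing channels for Laplacian: {missing}")
        w = np.zeros(len(labels))
        w[index[self.center]] = 1.0
        for nb in self.neighbors:
            w[index[nb]] = -1.0 / len(self.neighbors)
        return w


def laplacian_filter(recording: EEGRecording, spec: LaplacianSpec) -> np.ndarray:
    """Apply a surface Laplacian; returns a single-channel series (µV)."""
    return spec.weights(recording.labels) @ recording.data


# ---------------------------------------------------------------------------
# AR (maximum entropy) band amplitude


@dataclass(frozen=True)
class ARSpec:
    """Burg AR spectral-amplitude estimator settings.

    The amplitude is the square root of the mean AR power spectral density
    over the bin ``[center - width/2, center + width/2]`` evaluated on a
    regular grid.
    """

    order: int = 16
    window_ms: float = 500.0
    center_hz: float = 12.0
    width_hz: float = 3.0
    grid_step_hz: float = 0.25

    def __post_init__(self):
        if self.order < 1:
            raise InvalidArgumentError("AR order must be positive")
        if self.window_ms <= 0 or self.width_hz <= 0 or self.grid_step_hz <= 0:
            raise InvalidArgumentError("window, width and grid step must be > 0")
        if self.center_hz - self.width_hz / 2 <= 0:
            raise InvalidArgumentError("band must lie above 0 Hz")

    def window_samples(self, fs: float) -> int:
        n = int(round(self.window_ms / 1000.0 * fs))
        if n <= 2 * self.order:
            raise InvalidArgumentError(
                f"window of {n} samples too short for AR order {self.order}")
        return n

    def band_grid(self, fs: float) -> np.ndarray:
        lo = self.center_hz - self.width_hz / 2
        hi = self.center_hz + self.width_hz / 2
        if hi >= fs / 2:
            raise InvalidArgumentError("band exceeds Nyquist frequency")
        return np.arange(lo, hi + 1e-9, self.grid_step_hz)


def burg_fit(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg (maximum-entropy) AR fit of one window.

    Returns ``(a, noise_var)`` where ``a`` is the length ``order + 1`` AR
    polynomial ``[1, a1, ..., ap]`` of ``x[t] + a1 x[t-1] + ... = e[t]``.
    """
    A, E = _burg_batch(np.asarray(x, dtype=float)[None, :], order)
    return A[0], float(E[0])


def _burg_batch(X: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Burg recursion over a batch of windows (rows of X)."""
    X = np.asarray(X, dtype=float)
    n_win, N = X.shape
    if N <= 2 * order:
        raise InvalidArgumentError("window too short for AR order")
    if not np.all(np.isfinite(X)):
        raise DegenerateDataError("non-finite samples in AR window")
    # Double-buffered in-place recursion with Andersen's denominator update;
    # avoids reallocating the shrinking error arrays at every model order.
    # The error recursion runs in float32 (it is memory-bandwidth bound on
    # long sliding-window batches); reflection coefficients, AR polynomial
    # and residual variance are accumulated in float64.
    Xs = X.astype(np.float32)
    f = Xs.copy()
    falt = np.empty_like(Xs)
    b = Xs.copy()
    scratch = np.empty_like(Xs)
    A = np.zeros((n_win, order + 1))
    A[:, 0] = 1.0
    E = np.einsum("ij,ij->i", X, X) / N
    W = N
    fp = f[:, 1:W]
    bp = b[:, : W - 1]
    den = (np.einsum("ij,ij->i", fp, fp) + np.einsum("ij,ij->i", bp, bp)
           ).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        for m in range(order):
            # den is floored so an all-zero (or fully predicted) window gives
            # k = 0 rather than NaN; |k| <= 1 keeps E nonnegative.
            k = -2.0 * np.einsum("ij,ij->i", fp, bp) / np.maximum(den, 1e-300)
            np.maximum(k, -1.0, out=k)
            np.minimum(k, 1.0, out=k)
            kc = k.astype(np.float32)[:, None]
            prev = A[:, : m + 1].copy()
            A[:, 1 : m + 2] += k[:, None] * prev[:, ::-1]
            t = falt[:, : W - 1]
            np.multiply(bp, kc, out=t)
            t += fp                  # new forward error
            u = scratch[:, : W - 1]
            np.multiply(fp, kc, out=u)
            bp += u                  # new backward error, in place
            E = E * (1.0 - k * k)
            W -= 1
            f, falt = falt, f
            if m < order - 1:
                den = ((1.0 - k * k) * den
                       - f[:, 0].astype(np.float64) ** 2
                       - b[:, W - 1].astype(np.float64) ** 2)
                fp = f[:, 1:W]
                bp = b[:, : W - 1]
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(E))):
        raise DegenerateDataError("numerically singular Burg fit")
    return A, np.maximum(E, 0.0)


def ar_psd(a: np.ndarray, noise_var: float, fs: float, freqs: np.ndarray) -> np.ndarray:
    """One-sided AR power spectral density (µV²/Hz) at given frequencies."""
    psd = _ar_psd_batch(np.asarray(a)[None, :], np.array([noise_var]), fs,
                        np.asarray(freqs, dtype=float))
    return psd[0]


def _ar_psd_batch(A: np.ndarray, E: np.ndarray, fs: float,
                  freqs: np.ndarray) -> np.ndarray:
    order = A.shape[1] - 1
    k = np.arange(order + 1)
    basis = np.exp(-2j * np.pi * np.outer(k, freqs) / fs)  # (order+1, n_freq)
    denom = np.abs(A @ basis) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        psd = 2.0 * E[:, None] / (fs * denom)
    psd[~np.isfinite(psd)] = 0.0
    psd[E <= 0] = 0.0
    return psd


def ar_band_amplitude(window: np.ndarray, fs: float, spec: ARSpec | None = None) -> float:
    """Maximum-entropy band amplitude of one window (nonnegative, µV-scaled)."""
    spec = spec or ARSpec()
    window = np.asarray(window, dtype=float)
    if window.ndim != 1:
        raise InvalidArgumentError("window must be 1-D")
    spec.window_samples(fs)  # validates the spec/fs combination
    if len(window) <= 2 * spec.order:
        raise InvalidArgumentError("window too short for AR order")
    return float(ar_band_amplitudes(window[None, :], fs, spec)[0])


def ar_band_amplitudes(windows: np.ndarray, fs: float, spec: ARSpec | None = None
                       ) -> np.ndarray:
    """Batch version of :func:`ar_band_amplitude` over rows of `windows`."""
    spec = spec or ARSpec()
    W = np.asarray(windows, dtype=float)
    W = W - W.mean(axis=1, keepdims=True)
    A, E = _burg_batch(W, spec.order)
    psd = _ar_psd_batch(A, E, fs, spec.band_grid(fs))
    return np.sqrt(psd.mean(axis=1))


# ---------------------------------------------------------------------------
# control law and normalizer


def raw_control_value(amp_c3: float, amp_c4: float, task: str) -> float:
    """Combine the two band amplitudes: C4 - C3 (LR) or C4 + C3 (UD)."""
    if amp_c3 < 0 or amp_c4 < 0:
        raise InvalidArgumentError("band amplitudes must be nonnegative")
    if task == "LR":
        return float(amp_c4 - amp_c3)
    if task == "UD":
        return float(amp_c4 + amp_c3)
    raise InvalidArgumentError(f"task must be 'LR' or 'UD', got {task!r}")


class Normalizer:
    """Adaptive zero-mean unit-variance normalizer over a 30 s ring buffer.

    Offset (buffer mean) and gain (reciprocal buffer standard deviation) are
    recomputed at every update from the most recent ``capacity`` raw values
    (750 ticks = 30 s at a 40 ms update interval).  Before the buffer holds
    two values, and whenever the buffer standard deviation collapses below
    the floor, the normalized output is 0 (neutral cursor).
    """

    SD_FLOOR = 1e-8

    def __init__(self, capacity: int = 750):
        if capacity < 2:
            raise InvalidArgumentError("buffer capacity must be >= 2")
        self.capacity = int(capacity)
        self._buf: collections.deque[float] = collections.deque(maxlen=self.capacity)
        self._sum = 0.0
        self._sumsq = 0.0
        self._updates = 0

    @property
    def n(self) -> int:
        return len(self._buf)

    @property
    def offset(self) -> float:
        return self._sum / self.n if self.n else 0.0

    @property
    def sd(self) -> float:
        if self.n < 2:
            return 0.0
        var = self._sumsq / self.n - self.offset ** 2
        return float(np.sqrt(max(var, 0.0)))

    @property
    def gain(self) -> float:
        sd = self.sd
        floor = self._sd_floor()
        return 1.0 / sd if sd > floor else 0.0

    def _sd_floor(self) -> float:
        rms = np.sqrt(self._sumsq / self.n) if self.n else 0.0
        return self.SD_FLOOR * max(1.0, rms)

    def update(self, raw: float) -> float:
        """Append one raw value; return its normalized value."""
        raw = float(raw)
        if raw != raw or raw in (float("inf"), float("-inf")):
            raise InvalidArgumentError("raw control value must be finite")
        buf = self._buf
        if len(buf) == self.capacity:
            old = buf[0]
            self._sum -= old
            self._sumsq -= old * old
        buf.append(raw)
        self._sum += raw
        self._sumsq += raw * raw
        self._updates += 1
        if self._updates % 4096 == 0:  # guard running sums against fp drift
            arr = np.array(buf)
            self._sum = float(arr.sum())
            self._sumsq = float((arr * arr).sum())
        n = len(buf)
        if n < 2:
            return 0.0
        mean = self._sum / n
        msq = self._sumsq / n
        var = msq - mean * mean
        sd = var ** 0.5 if var > 0 else 0.0
        floor = self.SD_FLOOR * max(1.0, msq ** 0.5 if msq > 0 else 0.0)
        if sd <= floor:
            return 0.0
        return (raw - mean) / sd


# ---------------------------------------------------------------------------
# full chain


@dataclass(frozen=True)
class ChainConfig:
    """Everything the online chain needs besides the EEG itself."""

    lap_c3: LaplacianSpec = field(
        default_factory=lambda: LaplacianSpec.small("C3"))
    lap_c4: LaplacianSpec = field(
        default_factory=lambda: LaplacianSpec.small("C4"))
    ar: ARSpec = field(default_factory=ARSpec)
    update_interval_s: float = 0.040
    buffer_s: float = 30.0

    def __post_init__(self):
        if self.update_interval_s <= 0 or self.buffer_s <= 0:
            raise InvalidArgumentError("intervals must be positive")

    @property
    def buffer_ticks(self) -> int:
        return max(2, int(round(self.buffer_s / self.update_interval_s)))

    def required_channels(self) -> tuple[str, ...]:
        labs: list[str] = []
        for spec in (self.lap_c3, self.lap_c4):
            for lab in (spec.center, *spec.neighbors):
                if lab not in labs:
                    labs.append(lab)
        return tuple(labs)

    def describe(self) -> str:
        """Human-readable defaults dump (used by the CLI --show-config)."""
        lines = [
            f"laplacian C3: center={self.lap_c3.center} neighbors={list(self.lap_c3.neighbors)}",
            f"laplacian C4: center={self.lap_c4.center} neighbors={list(self.lap_c4.neighbors)}",
            f"ar: order={self.ar.order} window_ms={self.ar.window_ms} "
            f"band=[{self.ar.center_hz - self.ar.width_hz / 2}, "
            f"{self.ar.center_hz + self.ar.width_hz / 2}] Hz "
            f"grid_step={self.ar.grid_step_hz} Hz",
            f"update_interval_s: {self.update_interval_s}",
            f"normalizer_buffer_s: {self.buffer_s} ({self.buffer_ticks} ticks)",
        ]
        return "\n".join(lines)


@dataclass
class ControlTrace:
    """Per-tick raw and normalized control values of one recording or run."""

    task: str
    times: np.ndarray          # window-end time of each tick (s)
    raw: np.ndarray
    normalized: np.ndarray
    update_interval_s: float

    def __post_init__(self):
        if not (len(self.times) == len(self.raw) == len(self.normalized)):
            raise InvalidArgumentError("trace arrays must be equal length")

    @property
    def n_ticks(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["tick", "time_s", "raw", "normalized"])
            for i, (t, r, z) in enumerate(zip(self.times, self.raw, self.normalized)):
                w.writerow([i, f"{t:.3f}", repr(float(r)), repr(float(z))])


def sliding_band_amplitudes(series: np.ndarray, fs: float, spec: ARSpec,
                            tick_ends: np.ndarray) -> np.ndarray:
    """Band amplitudes of trailing windows ending at given sample indices."""
    win = spec.window_samples(fs)
    tick_ends = np.asarray(tick_ends, dtype=int)
    if len(tick_ends) == 0:
        return np.zeros(0)
    if tick_ends.min() < win - 1 or tick_ends.max() >= len(series):
        raise BufferingError("tick window extends outside the series")
    views = np.lib.stride_tricks.sliding_window_view(series, win)
    return ar_band_amplitudes(views[tick_ends - win + 1], fs, spec)


def run_signal_chain(recording: EEGRecording, chain: ChainConfig | None = None,
                     task: str = "LR",
                     normalizer: Normalizer | None = None) -> ControlTrace:
    """Run the full online chain over a recording.

    Ticks fall every ``update_interval_s``; the first tick fires as soon as
    one full AR estimation window is available.  The number of ticks is
    ``floor((n_samples - window) / hop) + 1``.
    """
    chain = chain or ChainConfig()
    if task not in ("LR", "UD"):
        raise InvalidArgumentError("task must be 'LR' or 'UD'")
    fs = recording.fs
    win = chain.ar.window_samples(fs)
    hop = max(1, int(round(chain.update_interval_s * fs)))
    if recording.n_samples < win:
        raise BufferingError("recording shorter than one AR window")
    lap3 = laplacian_filter(recording, chain.lap_c3)
    lap4 = laplacian_filter(recording, chain.lap_c4)
    ends = np.arange(win - 1, recording.n_samples, hop)
    a3 = sliding_band_amplitudes(lap3, fs, chain.ar, ends)
    a4 = sliding_band_amplitudes(lap4, fs, chain.ar, ends)
    sign = -1.0 if task == "LR" else 1.0
    raw = a4 + sign * a3
    norm = normalizer or Normalizer(chain.buffer_ticks)
    normalized = np.array([norm.update(r) for r in raw])
    return ControlTrace(task, (ends + 1) / fs, raw, normalized,
                        chain.update_interval_s)
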