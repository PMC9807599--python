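"""In-memory EEG container: channels x samples in microvolts."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InvalidArgumentError, MontageError


@dataclass
class EEGRecording:
    """Multichannel scalp EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potential in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : tuple of str
        Extended 10–20 channel labels, one per row of ``data``.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be 2D (channels x samples)")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise InvalidArgumentError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgumentError("duplicate channel labels")
        if not self.fs > 0:
            raise InvalidArgumentError("fs must be positive")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- basic properties ------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    # -- channel access ---------------------------------------------------
    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise MontageError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        """Return the time series of one channel (a view)."""
        return self.data[self.index(label)]

    def select(self, labels: Iterable[str]) -> "EEGRecording":
        labels = tuple(labels)
        idx = [self.index(lab) for lab in labels]
        return EEGRecording(self.data[idx].copy(), self.fs, labels)

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.fs, self.labels)

    def crop(self, tmin: float, tmax: float) -> "EEGRecording":
        i0 = max(0, int(round(tmin * self.fs)))
        i1 = min(self.n_samples, int(round(tmax * self.fs)))
        if i1 <= i0:
            raise InvalidArgumentError("empty crop interval")
        return EEGRecording(self.data[:, i0:i1].copy(), self.fs, self.labels)
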