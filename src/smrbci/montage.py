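"""Electrode montage geometry for the extended 10–20 system.

Positions come from MNE's bundled idealized 10-05 montage and are renormalized
to the unit sphere, so geodesic distances are plain great-circle arcs in
radians.  The default layout is a 60-channel cap covering the extended 10–20
labels a sensorimotor BCI needs (C3/C4 and their immediate neighbours,
occipital row, frontal row).
"""
from __future__ import annotations

import csv
import warnings
from typing import Iterable, Sequence

import numpy as np

from .errors import MontageError

#: 60-channel extended 10–20 cap used by default throughout the package.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

#: Channels needed to run the online control-signal chain (small Laplacians
#: around C3 and C4); used by the closed-loop simulator to avoid generating
#: channels the chain never reads.
BCI_CHANNELS: tuple[str, ...] = (
    "C3", "FC3", "CP3", "C1", "C5",
    "C4", "FC4", "CP4", "C2", "C6",
)


class MontageLayout:
    """Channel labels with unit-sphere 3D positions and a 2D projection."""

    def __init__(self, labels: Sequence[str], positions: np.ndarray):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise MontageError("duplicate channel labels")
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(labels), 3):
            raise MontageError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(positions, axis=1)
        if np.any(norms == 0):
            raise MontageError("zero-norm electrode position")
        self.labels = labels
        self.positions = positions / norms[:, None]
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- construction ---------------------------------------------------
    @classmethod
    def standard(cls, labels: Iterable[str] = DEFAULT_CHANNELS) -> "MontageLayout":
        """Build a layout from MNE's idealized 10-05 electrode positions.

        Cached per label tuple (construction reads MNE's montage files).
        """
        return _standard_cached(tuple(labels))

    @classmethod
    def _standard_uncached(cls, labels: tuple[str, ...]) -> "MontageLayout":
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            try:
                mont = mne.channels.make_standard_montage("standard_1005")
            except ValueError:  # pragma: no cover - newer MNE renames it
                mont = mne.channels.make_standard_montage("colin27_1005")
        pos = mont.get_positions()["ch_pos"]
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise MontageError(f"labels not in standard montage: {missing}")
        arr = np.array([pos[lab] for lab in labels])
        return cls(labels, arr)

    def subset(self, labels: Iterable[str]) -> "MontageLayout":
        labels = tuple(labels)
        idx = [self.index(lab) for lab in labels]
        return MontageLayout(labels, self.positions[idx])

    # -- lookups --------------------------------------------------------
    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise MontageError(f"channel {label!r} not in montage") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    # -- geometry -------------------------------------------------------
    def geodesic(self, a: str, b: str) -> float:
        """Great-circle distance between two electrodes (radians)."""
        d = float(np.dot(self.position(a), self.position(b)))
        return float(np.arccos(np.clip(d, -1.0, 1.0)))

    def distances_from(self, label: str) -> np.ndarray:
        """Geodesic distance from one electrode to every electrode (radians)."""
        d = self.positions @ self.position(label)
        return np.arccos(np.clip(d, -1.0, 1.0))

    def nearest_neighbors(self, label: str, k: int = 4) -> tuple[str, ...]:
        d = self.distances_from(label)
        order = np.argsort(d)
        out = [self.labels[i] for i in order if self.labels[i] != label]
        return tuple(out[:k])

    def median_spacing(self) -> float:
        """Median nearest-neighbour geodesic distance (radians)."""
        gram = self.positions @ self.positions.T
        d = np.arccos(np.clip(gram, -1.0, 1.0))
        np.fill_diagonal(d, np.inf)
        return float(np.median(d.min(axis=1)))

    def projection_2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection (vertex at Cz) for topography CSVs."""
        x, y, z = self.positions.T
        polar = np.arccos(np.clip(z, -1.0, 1.0))
        az = np.arctan2(y, x)
        return np.column_stack([polar * np.cos(az), polar * np.sin(az)])

    def to_csv(self, path) -> None:
        proj = self.projection_2d()
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["channel", "x3d", "y3d", "z3d", "x2d", "y2d"])
            for lab, p3, p2 in zip(self.labels, self.positions, proj):
                w.writerow([lab, *(f"{v:.6f}" for v in p3), *(f"{v:.6f}" for v in p2)])


import functools


@functools.lru_cache(maxsize=32)
def _standard_cached(labels: tuple[str, ...]) -> "MontageLayout":
    return MontageLayout._standard_uncached(labels)


def require_channels(montage_or_labels, needed: Iterable[str]) -> None:
    """Raise :class:`MontageError` unless every needed label is present."""
    if isinstance(montage_or_labels, MontageLayout):
        have = set(montage_or_labels.labels)
    else:
        have = set(montage_or_labels)
    missing = [lab for lab in needed if lab not in have]
    if missing:
        raise MontageError(f"missing required channels: {missing}")
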