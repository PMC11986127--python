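"""Core domain types shared across the pipeline.

All signal containers hold channel-by-sample float arrays in microvolts.
Microstate maps are average-referenced, unit-norm scalp topographies;
segmentations are per-frame integer labels with ``UNASSIGNED`` (-1) as the
below-threshold sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

UNASSIGNED: int = -1


class ChannelMismatchError(ValueError):
    """Raised when two artifacts disagree on their channel sets."""


@dataclass
class Montage:
    """Sensor layout: unique channel names with unit-sphere 3D positions.

    Coordinate convention: +x right, +y anterior, +z superior, head-centered.
    """

    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3), unit radius

    def __post_init__(self) -> None:
        self.channel_names = list(self.channel_names)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("montage channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.channel_names)} channels"
            )
        radii = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(radii, 1.0, atol=1e-6):
            raise ValueError("montage positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(self.channel_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise ChannelMismatchError(f"channels absent from montage: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)


@dataclass
class Recording:
    """Multichannel EEG segment: (n_channels, n_samples) potentials in µV."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    montage: Montage | None = None
    bad_channels: list[str] = field(default_factory=list)
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = list(self.channel_names)
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        unknown_bads = set(self.bad_channels) - set(self.channel_names)
        if unknown_bads:
            raise ValueError(f"bad_channels not in channel_names: {sorted(unknown_bads)}")
        if self.montage is not None and self.montage.channel_names != self.channel_names:
            raise ChannelMismatchError(
                "recording channel order must match its montage "
                f"({len(self.channel_names)} vs {self.montage.n_channels} channels)"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, sampling_rate: float | None = None,
                  note: str | None = None) -> "Recording":
        """Copy with new data (and optionally rate), appending a history note."""
        history = list(self.history) + ([note] if note else [])
        return replace(self, data=data,
                       sampling_rate=sampling_rate or self.sampling_rate,
                       history=history)


@dataclass
class MicrostateMapSet:
    """K microstate topographies: average-referenced, unit-norm rows."""

    maps: np.ndarray  # (K, n_channels)
    channel_names: list[str]
    level: str = "subject"  # "subject" | "group"
    labels: list[str] | None = None
    fit_gev: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.channel_names = list(self.channel_names)
        if self.maps.shape[0] < 1:
            raise ValueError("map set must contain at least one map")
        if self.maps.shape[1] != len(self.channel_names):
            raise ValueError(
                f"maps have {self.maps.shape[1]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.level not in ("subject", "group"):
            raise ValueError("level must be 'subject' or 'group'")
        if self.labels is None:
            self.labels = [chr(ord("A") + i) if i < 26 else f"M{i}"
                           for i in range(self.maps.shape[0])]
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map required")
        if self.fit_gev is not None and not (0.0 <= self.fit_gev <= 1.0):
            raise ValueError("fit_gev must lie in [0, 1]")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    def normalized(self) -> "MicrostateMapSet":
        """Return a copy with rows re-centered (average reference) and unit-norm."""
        m = self.maps - self.maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot normalize an all-zero map")
        return replace(self, maps=m / norms)


@dataclass
class Segment:
    state: int
    start: int
    length: int

    @property
    def stop(self) -> int:  # exclusive
        return self.start + self.length


@dataclass
class Segmentation:
    """Per-frame microstate labels with the UNASSIGNED (-1) sentinel.

    ``corr`` optionally stores each frame's winning spatial correlation and
    ``gfp`` the frame's global field power; both are carried through smoothing
    so source imaging can apply its correlation gate.
    """

    labels: np.ndarray  # (n_frames,), int; UNASSIGNED for below threshold
    sampling_rate: float
    corr: np.ndarray | None = None
    gfp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("corr", "gfp"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.labels.shape:
                    raise ValueError(f"{name} must align with labels")
                setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.labels.size

    @property
    def segments(self) -> list[Segment]:
        """Maximal runs of a single non-sentinel label (unassigned gaps break runs)."""
        return segments_from_labels(self.labels)

    def states_present(self) -> list[int]:
        return sorted(s for s in np.unique(self.labels) if s != UNASSIGNED)


def segments_from_labels(labels: np.ndarray) -> list[Segment]:
    labels = np.asarray(labels, dtype=int)
    segs: list[Segment] = []
    if labels.size == 0:
        return segs
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [labels.size]))
    for a, b in zip(starts, stops):
        if labels[a] != UNASSIGNED:
            segs.append(Segment(state=int(labels[a]), start=int(a), length=int(b - a)))
    return segs


def labels_from_segments(segments: Sequence[Segment], n_frames: int) -> np.ndarray:
    labels = np.full(n_frames, UNASSIGNED, dtype=int)
    for seg in segments:
        labels[seg.start:seg.stop] = seg.state
    return labels
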