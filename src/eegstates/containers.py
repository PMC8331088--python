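"""Core data containers: montages, recordings, epochs, templates and label sequences.

All voltages are in microvolts, sampling rates in Hz, positions on (or near)
the unit sphere in arbitrary length units.  Containers are thin dataclasses
around NumPy arrays; they validate their invariants on construction and are
otherwise passive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidArgumentError

UNASSIGNED = -1
"""Label value for samples no template could be assigned to."""


@dataclass(frozen=True)
class Montage:
    """Electrode layout: channel names and 3-D sensor positions.

    Positions live on the upper hemisphere of a unit sphere by convention
    (+x right, +y anterior, +z up); only relative geometry is used.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(names) < 8:
            raise InvalidArgumentError(
                f"montage needs >= 8 channels, got {len(names)}")
        if len(set(names)) != len(names):
            raise InvalidArgumentError("channel names must be unique")
        if pos.shape != (len(names), 3):
            raise InvalidArgumentError(
                f"positions shape {pos.shape} does not match {len(names)} channels")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise InvalidArgumentError("two montage positions coincide")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.channel_names)}
        return np.array([lookup[n] for n in names], dtype=int)


@dataclass(frozen=True)
class Recording:
    """A continuous multichannel EEG recording (channels x samples, microvolts)."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    montage: Montage
    subject_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise InvalidArgumentError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        if data.shape[0] != self.montage.n_channels:
            raise InvalidArgumentError(
                f"{data.shape[0]} data rows vs {self.montage.n_channels} montage channels")
        if not np.all(np.isfinite(data)):
            raise InvalidArgumentError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


@dataclass(frozen=True)
class Epochs:
    """Non-overlapping, equal-length epochs cut from one recording.

    ``data`` keeps every epoch (rejected ones included); ``kept`` marks the
    epochs that survive artifact rejection.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    fs: float
    epoch_length: float
    montage: Montage
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise InvalidArgumentError("epoch data must be 3-D")
        kept = self.kept
        if kept is None:
            kept = np.ones(data.shape[0], dtype=bool)
        kept = np.asarray(kept, dtype=bool)
        if kept.shape != (data.shape[0],):
            raise InvalidArgumentError("kept mask length must equal epoch count")
        object.__setattr__(self, "kept", kept)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_data(self) -> np.ndarray:
        """Surviving epochs as a (n_kept, n_channels, n_samples) array."""
        return self.data[self.kept]

    def concatenate(self) -> np.ndarray:
        """Kept epochs joined back into a (n_channels, total_samples) array."""
        kd = self.kept_data()
        return kd.transpose(1, 0, 2).reshape(self.data.shape[1], -1)


@dataclass(frozen=True)
class TemplateSet:
    """K microstate template maps (average-referenced, unit GFP).

    ``level`` records whether the set came from a single subject or from
    pooling individual templates across a group.  ``gev`` is the fraction of
    GFP-weighted variance the set explained on the data it was fitted to.
    """

    maps: np.ndarray  # (K, n_channels)
    class_labels: tuple[str, ...]
    level: str = "individual"  # "individual" | "group"
    gev: Optional[float] = None

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        object.__setattr__(self, "maps", maps)
        labels = tuple(self.class_labels)
        object.__setattr__(self, "class_labels", labels)
        if maps.ndim != 2:
            raise InvalidArgumentError("template maps must be 2-D (K x channels)")
        if len(labels) != maps.shape[0]:
            raise InvalidArgumentError("one class label per template required")
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("class labels must be unique")
        if self.level not in ("individual", "group"):
            raise InvalidArgumentError(f"unknown template level {self.level!r}")
        if self.gev is not None and not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise InvalidArgumentError(f"gev must lie in [0, 1], got {self.gev}")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def relabel(self, labels: Sequence[str], order: Sequence[int]) -> "TemplateSet":
        """Reorder maps by ``order`` and attach new class labels."""
        order = np.asarray(order, dtype=int)
        return TemplateSet(self.maps[order], tuple(labels), self.level, self.gev)


@dataclass(frozen=True)
class LabelSequence:
    """Per-sample microstate class labels for one recording.

    ``labels`` holds class indices into ``class_labels`` or :data:`UNASSIGNED`.
    ``epoch_edges`` are the cumulative sample boundaries of the epochs the
    sequence was computed over ([0, n] for a continuous record); runs never
    span an edge.
    """

    labels: np.ndarray  # (n_samples,) int
    fs: float
    class_labels: tuple[str, ...]
    epoch_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        edges = self.epoch_edges
        if edges is None:
            edges = np.array([0, labels.size])
        edges = np.asarray(edges, dtype=int)
        object.__setattr__(self, "epoch_edges", edges)
        if labels.ndim != 1:
            raise InvalidArgumentError("labels must be 1-D")
        empty_ok = labels.size == 0 and edges[-1] == 0
        if (edges[0] != 0 or edges[-1] != labels.size
                or (not empty_ok and np.any(np.diff(edges) <= 0))):
            raise InvalidArgumentError("epoch edges must partition the sequence")
        K = len(self.class_labels)
        bad = (labels != UNASSIGNED) & ((labels < 0) | (labels >= K))
        if bad.any():
            raise InvalidArgumentError("label out of range for class legend")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_epochs(self) -> int:
        return self.epoch_edges.size - 1

    def epoch_slices(self) -> list[slice]:
        e = self.epoch_edges
        return [slice(int(a), int(b)) for a, b in zip(e[:-1], e[1:])]
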