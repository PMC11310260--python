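"""Core data containers and error types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MuSuppressError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MuSuppressError):
    """Empty, malformed, or out-of-contract input."""


class InvalidGeometryError(MuSuppressError):
    """Head-model geometry too small or degenerate to build."""


class ConfigurationError(MuSuppressError):
    """Unknown label or inconsistent configuration."""


class InconsistentInputError(MuSuppressError):
    """Inputs that must agree (fs, channels, lengths) do not."""


class InvalidTrimError(MuSuppressError):
    """Trim longer than half a block."""


class InvalidBandError(MuSuppressError):
    """Frequency band outside the representable range."""


class DegenerateInputError(MuSuppressError):
    """Zero-variance or otherwise statistically degenerate input."""


class IncompleteDesignError(MuSuppressError):
    """Missing cells in a fully-crossed repeated-measures design."""


class SingularSystemError(MuSuppressError):
    """Unregularized inverse of a rank-deficient system."""


class PairingError(MuSuppressError):
    """Subject or vertex sets do not match between paired tables."""


class InvalidGraphError(MuSuppressError):
    """Adjacency structure is not a valid undirected graph."""


class CalibrationError(MuSuppressError):
    """Threshold calibration cannot reach the requested target."""


@dataclass
class Recording:
    """One multi-channel EEG block.

    data is [channels x samples]; times are in seconds, sample indices
    0-based, intervals half-open [start, end).
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    condition: str = ""
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("Recording.data must be 2-D [channels x samples]")
        if self.data.shape[0] != len(self.ch_names):
            raise InconsistentInputError(
                f"{self.data.shape[0]} rows but {len(self.ch_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.fs, list(self.ch_names),
            self.condition, self.subject, self.session,
        )


@dataclass
class ConditionSegment:
    """Trimmed, concatenated per-condition signal ready for spectral analysis.

    provenance records, per concatenated clip, the (clip index, start, stop)
    sample range of the original block that survived trimming.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    condition: str = ""
    subject: str = ""
    session: str = ""
    provenance: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SourceModel:
    """Discrete source space: mesh on an upper hemisphere plus lead field.

    vertices: [n_vertices x 3] positions; channels: [n_channels x 3];
    triangles: [n_tri x 3] vertex indices; adjacency: dense symmetric
    0/1 matrix with zero diagonal; leadfield: [n_channels x n_vertices].
    """

    vertices: np.ndarray
    channels: np.ndarray
    ch_names: list[str]
    triangles: np.ndarray
    adjacency: np.ndarray
    leadfield: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    def vertex_neighborhood(self, vertex: int, rings: int = 1) -> set[int]:
        """Vertices within `rings` mesh edges of `vertex` (inclusive)."""
        frontier = {vertex}
        seen = {vertex}
        for _ in range(rings):
            nxt = set()
            for v in frontier:
                nxt.update(np.nonzero(self.adjacency[v])[0].tolist())
            frontier = nxt - seen
            seen |= nxt
        return seen

    def nearest_channel(self, vertex: int) -> int:
        """Index of the sensor closest to a source vertex."""
        d = np.linalg.norm(self.channels - self.vertices[vertex], axis=1)
        return int(np.argmin(d))
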