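"""Core containers: frequency bands, region signal sets and edge frame series.

Connectome frames are stored as vectors over the upper-triangle edge set in
row-major order (``np.triu_indices(R, k=1)``); this edge order is fixed and
shared by every operation in the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "RegionSignalSet",
    "WindowSpec",
    "EdgeFrameSeries",
    "edge_pairs",
    "n_edges",
    "sym_to_vec",
    "vec_to_sym",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: ({self.low}, {self.high})")

    def validate_fs(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} high edge {self.high} Hz >= Nyquist ({fs / 2} Hz)"
            )


#: Canonical electrophysiological bands (Hz).
CANONICAL_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 5.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 14.0, 30.0),
    "gamma": BandSpec("gamma", 31.0, 60.0),
}


def edge_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle (i, j) index pair arrays for ``n_regions``."""
    return np.triu_indices(n_regions, k=1)


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def sym_to_vec(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (row-major, diagonal excluded) of a square matrix."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    i, j = edge_pairs(mat.shape[0])
    return mat[i, j]


def vec_to_sym(vec: np.ndarray, n_regions: int, diag: float = 0.0) -> np.ndarray:
    """Re-assemble an edge vector into its symmetric matrix form."""
    vec = np.asarray(vec)
    if vec.shape[-1] != n_edges(n_regions):
        raise ValueError(
            f"edge vector length {vec.shape[-1]} inconsistent with R={n_regions}"
        )
    i, j = edge_pairs(n_regions)
    out = np.full(vec.shape[:-1] + (n_regions, n_regions), diag, dtype=float)
    out[..., i, j] = vec
    out[..., j, i] = vec
    return out


@dataclass
class RegionSignalSet:
    """Region x time signals of one modality at a fixed sampling rate.

    Parameters
    ----------
    values : ndarray, shape (R, T)
        One row per region.
    fs : float
        Sampling rate in Hz (for BOLD-like data, ``1 / TR``).
    modality : {"fast", "slow"}
        "fast" for electrophysiology-like signals, "slow" for BOLD-like ones.
    region_labels : sequence of str, optional
        Unique labels; defaults to ``r000, r001, ...``.
    band : BandSpec, optional
        Set once the signals have been band-limited.
    """

    values: np.ndarray
    fs: float
    modality: str = "fast"
    region_labels: Optional[list[str]] = None
    band: Optional[BandSpec] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signals contain non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.modality not in ("fast", "slow"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.region_labels is None:
            self.region_labels = [f"r{i:03d}" for i in range(self.values.shape[0])]
        self.region_labels = list(self.region_labels)
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError("one label per region required")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_values(self, values: np.ndarray, band: Optional[BandSpec] = None) -> "RegionSignalSet":
        return replace(self, values=values, band=band if band is not None else self.band)


@dataclass
class WindowSpec:
    """TR-locked sliding-window specification.

    Window ``k`` covers the acquisition interval of fMRI volume ``k``
    (``[k TR, (k+1) TR)``), i.e. centers sit at ``(k + 1/2) TR`` and step by
    exactly one TR, so frame indices match fMRI volume indices one-to-one.
    """

    length: float  # seconds, equal to TR
    n_samples: int  # samples per window, round(length * fs)
    centers: np.ndarray  # window-center times (s)

    @classmethod
    def from_sampling(cls, tr: float, fs: float, n_samples_total: int) -> "WindowSpec":
        n_win = int(round(tr * fs))
        if n_win < 1:
            raise ValueError("window shorter than one sample")
        n_frames = int(np.floor(n_samples_total / n_win))
        centers = (np.arange(n_frames) + 0.5) * tr
        return cls(length=tr, n_samples=n_win, centers=centers)

    def sample_starts(self, fs: float, n_samples_total: int) -> np.ndarray:
        """Start sample of each window whose full extent fits the recording."""
        starts = np.round((self.centers - self.length / 2) * fs).astype(int)
        ok = (starts >= 0) & (starts + self.n_samples <= n_samples_total)
        return starts[ok]


@dataclass
class EdgeFrameSeries:
    """Frame-wise connectome patterns over the fixed upper-triangle edge set.

    ``frames`` has one row per TR frame and one column per edge; ``coupling``
    records the FC measure ("amp" = envelope co-fluctuation, "phase" =
    phase-locking value, "bold" = BOLD edge time series).
    """

    frames: np.ndarray  # (T, E)
    tr: float
    coupling: str
    n_regions: int
    band: Optional[BandSpec] = None
    frame_times: Optional[np.ndarray] = None
    shifted: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D frame x edge array")
        if self.frames.shape[1] != n_edges(self.n_regions):
            raise ValueError(
                f"{self.frames.shape[1]} edges inconsistent with R={self.n_regions}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.coupling not in ("amp", "phase", "bold"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "phase":
            if self.frames.size and (self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9):
                raise ValueError("phase-coupling values must lie in [0, 1]")
        if self.frame_times is None:
            self.frame_times = (np.arange(self.frames.shape[0]) + 0.5) * self.tr
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape[0] != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_edges(self) -> int:
        return self.frames.shape[1]

    @property
    def edge_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return edge_pairs(self.n_regions)

    def matrices(self, diag: float = 0.0) -> np.ndarray:
        """Frames re-assembled to symmetric (T, R, R) matrix form."""
        return vec_to_sym(self.frames, self.n_regions, diag=diag)
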