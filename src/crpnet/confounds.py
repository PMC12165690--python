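"""Confound checks: does cross-modal similarity track nuisance processes?

The per-TR cross-modal similarity timecourse (diagonal of the lag-corrected
CRP) is correlated with candidate nuisance timecourses — overall FC
strength, framewise displacement, static-connectome prominence — and each
correlation is tested against Fourier phase-permuted versions of the
similarity timecourse.  Overlap between significant-similarity epochs and
marked artifact intervals is tested with the Jaccard index against a
circular-shift null.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signals import EdgeFrameSeries, edge_pairs
from .stats import jaccard
from .surrogates import phase_randomize_1d

__all__ = [
    "NuisanceTimecourses",
    "similarity_timecourse",
    "fc_strength_timecourse",
    "framewise_displacement",
    "static_prominence_timecourse",
    "timecourse_null_correlation",
    "artifact_overlap_test",
    "network_strength_timecourse",
]


@dataclass
class NuisanceTimecourses:
    """Aligned per-TR nuisance measures for one subject."""

    similarity: np.ndarray
    fc_strength: np.ndarray
    fd: Optional[np.ndarray] = None
    static_prominence: Optional[np.ndarray] = None
    artifact_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = self.similarity.size
        for name in ("fc_strength", "fd", "static_prominence", "artifact_mask"):
            v = getattr(self, name)
            if v is not None and np.asarray(v).size != n:
                raise ValueError(f"{name} length differs from similarity timecourse")
        if self.fd is not None and np.any(self.fd < 0):
            raise ValueError("framewise displacement cannot be negative")


def similarity_timecourse(crp_r: np.ndarray) -> np.ndarray:
    """Synchronous cross-modal similarity: main diagonal of a lag-corrected CRP."""
    crp_r = np.asarray(crp_r)
    return np.diagonal(crp_r).copy()


def fc_strength_timecourse(frames: EdgeFrameSeries) -> np.ndarray:
    """Per-frame root-sum-square of the FC values over all connections."""
    return np.sqrt(np.sum(frames.frames ** 2, axis=1))


def framewise_displacement(motion: np.ndarray, radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement from a 6-column motion table.

    Columns are 3 translations (mm) then 3 rotations (radians); rotations
    are converted to arc length on a ``radius_mm`` sphere.  FD(t) is the sum
    of absolute backward differences; the first frame is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns (3 transl., 3 rot.)")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def static_prominence_timecourse(frames: EdgeFrameSeries) -> np.ndarray:
    """Per-frame Pearson correlation with the series' static (mean) connectome."""
    X = frames.frames
    if X.shape[1] < 8:
        raise ValueError("need at least 8 edges")
    static = X.mean(axis=0)
    if static.std() == 0:
        raise ValueError("static connectome has zero variance")
    zs = (static - static.mean()) / static.std()
    sd = X.std(axis=1)
    sd = np.where(sd == 0, np.nan, sd)
    zf = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return (zf * zs).mean(axis=1)


def timecourse_null_correlation(x: np.ndarray, y: np.ndarray, n_perm: int = 100,
                                seed=None) -> tuple[float, float]:
    """Observed Pearson r(x, y) with a two-sided phase-permutation p-value.

    The null ensemble phase-randomizes ``x`` (the similarity timecourse),
    preserving its autocorrelation structure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 16:
        raise ValueError("need equal-length timecourses of at least 16 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    count = 0
    for _ in range(n_perm):
        r_null = np.corrcoef(phase_randomize_1d(x, rng), y)[0, 1]
        count += abs(r_null) >= abs(r_obs)
    return r_obs, float((1 + count) / (n_perm + 1))


def artifact_overlap_test(sim_binary: np.ndarray, artifact_mask: np.ndarray,
                          n_shifts: int = 100, seed=None) -> tuple[float, float]:
    """Jaccard overlap of similarity epochs with artifact epochs vs shift null.

    The null circularly shifts the binarized similarity timecourse by a
    random non-zero number of samples (without replacement when fewer shifts
    than requested are available); p is one-tailed for excess overlap.
    """
    sim = np.asarray(sim_binary, dtype=bool)
    art = np.asarray(artifact_mask, dtype=bool)
    if sim.shape != art.shape or sim.ndim != 1:
        raise ValueError("masks must be equal-length 1-D arrays")
    if not art.any():
        warnings.warn("empty artifact mask; overlap undefined")
        return float("nan"), float("nan")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = jaccard(sim, art)
    T = sim.size
    avail = np.arange(1, T)
    if n_shifts < avail.size:
        shifts = rng.choice(avail, size=n_shifts, replace=False)
    else:
        shifts = avail
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = np.array([jaccard(np.roll(sim, int(s)), art) for s in shifts])
    null = null[np.isfinite(null)]
    if not np.isfinite(obs) or null.size == 0:
        return obs, float("nan")
    return obs, float((1 + np.sum(null >= obs)) / (null.size + 1))


def network_strength_timecourse(frames: EdgeFrameSeries, membership: dict,
                                network: str, z_thresh: float = 2.0,
                                region_labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored within-network FC strength per frame, with ``z > z_thresh`` mask.

    ``membership`` maps region (integer index, or label when
    ``region_labels`` is given) to network name; the timecourse averages the
    FC values of all edges whose both endpoints belong to ``network``.
    """
    if region_labels is not None:
        keys = list(region_labels)
    else:
        keys = list(range(frames.n_regions))
    if len(keys) != frames.n_regions:
        raise ValueError("one region key per region required")
    members = [i for i, key in enumerate(keys) if membership.get(key) == network]
    if len(members) < 2:
        raise ValueError(f"network {network!r} needs at least 2 regions")
    i_idx, j_idx = edge_pairs(frames.n_regions)
    in_net = np.isin(i_idx, members) & np.isin(j_idx, members)
    tc = frames.frames[:, in_net].mean(axis=1)
    sd = tc.std()
    if sd == 0:
        raise ValueError("constant network-strength timecourse; z undefined")
    z = (tc - tc.mean()) / sd
    return z, z > z_thresh
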