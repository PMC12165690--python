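"""Cross-modal recurrence plots (CRPs).

A CRP is the matrix of spatial Pearson correlations between every frame-wise
fMRI connectome pattern (rows) and every frame-wise band-specific
electrophysiological connectome pattern (columns).  Entries are tested
against a spatial null built by 2-D Fourier phase permutation of the fMRI FC
matrices, binarized by Benjamini-Hochberg FDR over all frame pairs, and the
per-band binary layers are overlaid into a multi-frequency CRP.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .signals import EdgeFrameSeries, vec_to_sym
from .surrogates import spatial_phase_permute_frames

__all__ = [
    "AnalysisConfig",
    "CRPStack",
    "cross_modal_correlation",
    "entrywise_null_test",
    "fdr_binarize",
    "overlay_bands",
    "CrossModalRecurrence",
]


@dataclass
class AnalysisConfig:
    """Statistical settings for the CRP pipeline."""

    q: float = 0.05  # FDR level
    n_perm: int = 100  # spatial permutations per CRP entry test
    shifts: tuple[int, ...] = tuple(range(-5, 6))  # diagonal shifts in TR
    prior_scale: float = 0.707  # Cauchy prior scale for the Bayesian t-test
    n_null_crp: int = 100  # surrogate multi-frequency CRPs for ratio nulls
    n_surrogate_states: int = 50  # surrogates for state dissociability

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.n_perm < 20:
            raise ValueError("need at least 20 permutations")


def _frames_array(frames) -> np.ndarray:
    return frames.frames if isinstance(frames, EdgeFrameSeries) else np.asarray(frames, float)


def _row_zscore(x: np.ndarray, strict: bool = True) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if strict and np.any(sd == 0):
        raise ValueError("frame with zero variance across edges")
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def cross_modal_correlation(fmri, eeg) -> np.ndarray:
    """All-pairs spatial correlation between two frame series.

    Entry (a, b) is the Pearson correlation across edges between fMRI frame a
    and electrophysiological frame b.  Both series must share the edge set
    and edge order.
    """
    F = _frames_array(fmri)
    E = _frames_array(eeg)
    if F.shape[1] != E.shape[1]:
        raise ValueError("edge-order mismatch between the two frame series")
    if F.shape[1] < 3:
        raise ValueError("need at least 3 edges")
    if isinstance(fmri, EdgeFrameSeries) and isinstance(eeg, EdgeFrameSeries):
        if fmri.n_regions != eeg.n_regions:
            raise ValueError("edge-order mismatch: different region counts")
    Zf = _row_zscore(F)
    Ze = _row_zscore(E)
    return np.clip(Zf @ Ze.T / F.shape[1], -1.0, 1.0)


def entrywise_null_test(fmri: EdgeFrameSeries, eeg: EdgeFrameSeries,
                        n_perm: int = 100, seed=None) -> np.ndarray:
    """Entry-wise one-tailed empirical p-values for a CRP.

    For each permutation every fMRI frame is re-assembled to its symmetric
    R x R matrix form and spatially phase-permuted, and the full null CRP is
    recomputed; the n_perm null CRPs are shared across entries.  p for entry
    (a, b) is ``(1 + #{null r >= observed r}) / (n_perm + 1)``; entries with
    non-positive observed correlation are assigned p = 1 (anticorrelated
    epochs are excluded by design).
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    R = fmri.n_regions
    if R < 4:
        raise ValueError("need at least 4 regions for 2-D spatial permutation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = cross_modal_correlation(fmri, eeg)
    mats = vec_to_sym(fmri.frames, R, diag=0.0)  # (S_f, R, R)
    Ze = _row_zscore(eeg.frames)
    n_edges = fmri.frames.shape[1]
    i_idx, j_idx = fmri.edge_pairs
    counts = np.zeros(obs.shape, dtype=np.int64)
    for _ in range(n_perm):
        surr = spatial_phase_permute_frames(mats, rng)
        X = surr[:, i_idx, j_idx]
        null_r = _row_zscore(X, strict=False) @ Ze.T / n_edges
        counts += null_r >= obs
    p = (1.0 + counts) / (n_perm + 1.0)
    p[obs <= 0] = 1.0
    return p


def fdr_binarize(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over all entries jointly; boolean output."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def overlay_bands(layers: Union[Mapping[str, np.ndarray], Sequence[np.ndarray]]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-band binary CRPs and form the multi-frequency union.

    Returns ``(stack, union)`` where ``stack`` is (S_f, S_e, B) and ``union``
    the entrywise OR over bands.
    """
    mats = list(layers.values()) if isinstance(layers, Mapping) else list(layers)
    if not mats:
        raise ValueError("no layers given")
    shapes = {np.asarray(m).shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"layer shape mismatch: {sorted(shapes)}")
    stack = np.stack([np.asarray(m, dtype=bool) for m in mats], axis=2)
    return stack, stack.any(axis=2)


@dataclass
class CRPStack:
    """Real-valued CRPs plus binary significance layers for one subject."""

    band_names: list[str]
    r_values: np.ndarray  # (S_f, S_e, B)
    p_values: np.ndarray  # (S_f, S_e, B)
    binary: np.ndarray  # (S_f, S_e, B) boolean
    union: np.ndarray  # (S_f, S_e) boolean
    q: float
    n_perm: int

    def __post_init__(self) -> None:
        if not (self.r_values.shape == self.p_values.shape == self.binary.shape):
            raise ValueError("layer shape mismatch")
        if np.any(self.binary & (self.r_values <= 0)):
            raise ValueError("significant entries must have positive correlation")

    @property
    def shape(self) -> tuple[int, int]:
        return self.union.shape

    def layer(self, band: str) -> np.ndarray:
        return self.binary[:, :, self.band_names.index(band)]

    def density(self, band: Optional[str] = None) -> float:
        """Fraction of significant entries (union by default)."""
        m = self.union if band is None else self.layer(band)
        return float(m.mean())


class CrossModalRecurrence(BaseEstimator):
    """Estimator building a CRP stack from aligned bimodal frame series.

    Parameters
    ----------
    q : float, default 0.05
        FDR level for binarization (applied per band over all frame pairs).
    n_perm : int, default 100
        Spatial phase permutations for the entry-wise null.
    random_state : int, optional

    Attributes
    ----------
    bands_ : list of str
    r_, p_, binary_ : ndarray (S_f, S_e, B)
    union_ : ndarray (S_f, S_e) boolean
    stack_ : CRPStack
    """

    def __init__(self, q: float = 0.05, n_perm: int = 100, random_state: Optional[int] = None):
        self.q = q
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, fmri: EdgeFrameSeries, eeg_by_band: Mapping[str, EdgeFrameSeries]):
        AnalysisConfig(q=self.q, n_perm=self.n_perm)  # validates
        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(len(eeg_by_band))
        r_layers, p_layers, b_layers = [], [], []
        self.bands_ = list(eeg_by_band)
        for child, (band, eeg) in zip(children, eeg_by_band.items()):
            rng = np.random.default_rng(child)
            r = cross_modal_correlation(fmri, eeg)
            p = entrywise_null_test(fmri, eeg, n_perm=self.n_perm, seed=rng)
            r_layers.append(r)
            p_layers.append(p)
            b_layers.append(fdr_binarize(p, self.q))
        self.r_ = np.stack(r_layers, axis=2)
        self.p_ = np.stack(p_layers, axis=2)
        self.binary_, self.union_ = overlay_bands(b_layers)
        self.stack_ = CRPStack(self.bands_, self.r_, self.p_, self.binary_,
                               self.union_, q=self.q, n_perm=self.n_perm)
        return self
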