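"""Frame-wise and static functional connectivity for both modalities.

Implements the three FC measures evaluated at every TR frame:

* BOLD edge time series   ``fMRI_FC_ij(t) = Z(BOLD_i)(t) * Z(BOLD_j)(t)``
* envelope co-fluctuation ``EEG_FC_amp_ij(t) = mean_m Z(env_i)(m) Z(env_j)(m)``
  over the N samples of a TR-long window centred at frame t
* phase-locking value     ``EEG_FC_phase_ij(t) = | mean_m exp(i dphi_ij(m)) |``

Z-scoring uses the population convention (divide by T, not T-1) so that the
time-mean of a BOLD edge series equals the Pearson correlation of the two
region signals exactly, and the self-product has mean exactly 1.
"""
from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional

import numpy as np
from scipy import signal as spsignal
from scipy import stats as spstats
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import (
    CANONICAL_BANDS,
    BandSpec,
    EdgeFrameSeries,
    RegionSignalSet,
    WindowSpec,
    edge_pairs,
)

__all__ = [
    "ChebyBandpass",
    "EdgeTimeSeries",
    "bandpass",
    "hilbert_env_phase",
    "eeg_fc_amp",
    "eeg_fc_phase",
    "fmri_edge_series",
    "apply_hemodynamic_shift",
    "align_series",
    "hrf_convolve",
    "canonical_hrf",
    "static_fc",
]


def _zscore_pop(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Population z-score (ddof=0); raises on zero-variance rows."""
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"zero-variance channel(s): {bad.tolist()}")
    return (x - mu) / sd


class ChebyBandpass(BaseEstimator, TransformerMixin):
    """Zero-phase fourth-order Chebyshev type II band-pass filter.

    The stopband edges are placed a factor ``margin`` outside the passband
    edges so that the passband itself is flat (gain within ±1 dB at the band
    centre) while attenuation one octave outside the band is >= ``rs`` dB per
    pass.  Filtering is applied forward-backward (``sosfiltfilt``), which
    preserves phase — essential for downstream phase-locking estimates.

    Parameters
    ----------
    band : str or BandSpec
        Canonical band name ("delta".."gamma") or an explicit BandSpec.
    fs : float
        Sampling rate in Hz.
    order : int, default 4
    rs : float, default 40.0
        Stopband attenuation in dB (single pass).
    margin : float, default sqrt(2)
        Stopband-edge placement factor (half an octave outside the band).
    """

    def __init__(self, band="alpha", fs: float = 250.0, order: int = 4,
                 rs: float = 40.0, margin: float = float(np.sqrt(2))):
        self.band = band
        self.fs = fs
        self.order = order
        self.rs = rs
        self.margin = margin

    def _band(self) -> BandSpec:
        return CANONICAL_BANDS[self.band] if isinstance(self.band, str) else self.band

    def fit(self, X=None, y=None):
        band = self._band()
        band.validate_fs(self.fs)
        lo = band.low / self.margin
        hi = min(band.high * self.margin, 0.99 * self.fs / 2)
        self.sos_ = spsignal.cheby2(self.order, self.rs, [lo, hi],
                                    btype="bandpass", fs=self.fs, output="sos")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Filter columns of a (n_times, n_regions) array."""
        if not hasattr(self, "sos_"):
            self.fit()
        return spsignal.sosfiltfilt(self.sos_, np.asarray(X, dtype=float), axis=0)


def bandpass(signals: RegionSignalSet, band) -> RegionSignalSet:
    """Band-pass a fast-modality signal set into one canonical band."""
    if signals.modality != "fast":
        raise ValueError("bandpass expects fast-modality signals")
    flt = ChebyBandpass(band=band, fs=signals.fs).fit()
    out = flt.transform(signals.values.T).T
    return signals.with_values(out, band=flt._band())


def hilbert_env_phase(signals: RegionSignalSet) -> tuple[RegionSignalSet, RegionSignalSet]:
    """Envelope and unwrapped phase of band-limited signals (Hilbert transform).

    Channels that are identically zero get zero envelope and NaN phase with a
    warning (phase is undefined there).
    """
    analytic = spsignal.hilbert(signals.values, axis=1)
    env = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=1)
    dead = np.flatnonzero(signals.values.std(axis=1) == 0)
    env_set = signals.with_values(env)
    phase_set = RegionSignalSet(np.nan_to_num(phase), fs=signals.fs,
                                modality=signals.modality,
                                region_labels=signals.region_labels,
                                band=signals.band)
    if dead.size:
        warnings.warn(f"zero signal in channel(s) {dead.tolist()}: phase undefined")
        phase_set.values[dead] = np.nan  # flagged after finite validation
    return env_set, phase_set


class EdgeTimeSeries(BaseEstimator, TransformerMixin):
    """Transform region signals into frame-wise connectome edge patterns.

    Operates on an (n_times, n_regions) array.  For ``coupling="bold"`` the
    input is a BOLD series sampled at TR and every sample is one frame; for
    ``coupling="amp"`` ("phase") the input is the band-limited envelope
    (unwrapped phase) at the fast sampling rate and frames are TR-long
    windows tiling the recording.

    Parameters
    ----------
    coupling : {"bold", "amp", "phase"}
    tr : float
        Repetition time in seconds (frame step).
    fs : float
        Sampling rate of the input in Hz (ignored for "bold": fs = 1/tr).
    """

    def __init__(self, coupling: str = "bold", tr: float = 3.0, fs: float = 250.0):
        self.coupling = coupling
        self.tr = tr
        self.fs = fs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected (n_times, n_regions)")
        self.n_regions_ = X.shape[1]
        if self.coupling == "bold":
            self.window_ = None
        else:
            self.window_ = WindowSpec.from_sampling(self.tr, self.fs, X.shape[0])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).T  # (R, T)
        R = X.shape[0]
        i_idx, j_idx = edge_pairs(R)
        if self.coupling == "bold":
            if X.shape[1] < 8:
                raise ValueError("need at least 8 BOLD frames")
            Z = _zscore_pop(X, axis=1)
            return (Z[i_idx] * Z[j_idx]).T
        win = WindowSpec.from_sampling(self.tr, self.fs, X.shape[1])
        starts = win.sample_starts(self.fs, X.shape[1])
        N = win.n_samples
        if self.coupling == "amp":
            Z = _zscore_pop(X, axis=1)
            frames = np.empty((starts.size, i_idx.size))
            for k, s in enumerate(starts):
                C = Z[:, s:s + N] @ Z[:, s:s + N].T / N
                frames[k] = C[i_idx, j_idx]
            return frames
        if self.coupling == "phase":
            if np.isnan(X).any():
                raise ValueError("undefined phase channel(s); drop them first")
            P = np.exp(1j * X)
            frames = np.empty((starts.size, i_idx.size))
            for k, s in enumerate(starts):
                C = P[:, s:s + N] @ P[:, s:s + N].conj().T / N
                frames[k] = np.abs(C[i_idx, j_idx])
            return np.clip(frames, 0.0, 1.0)
        raise ValueError(f"unknown coupling {self.coupling!r}")

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def _frame_series(frames: np.ndarray, tr: float, coupling: str, R: int,
                  band: Optional[BandSpec]) -> EdgeFrameSeries:
    return EdgeFrameSeries(frames, tr=tr, coupling=coupling, n_regions=R, band=band)


def eeg_fc_amp(envelope: RegionSignalSet, tr: float) -> EdgeFrameSeries:
    """Frame-wise amplitude-coupling connectome from band-limited envelopes."""
    est = EdgeTimeSeries(coupling="amp", tr=tr, fs=envelope.fs)
    frames = est.fit_transform(envelope.values.T)
    return _frame_series(frames, tr, "amp", envelope.n_regions, envelope.band)


def eeg_fc_phase(phase: RegionSignalSet, tr: float) -> EdgeFrameSeries:
    """Frame-wise phase-locking connectome from unwrapped phases."""
    est = EdgeTimeSeries(coupling="phase", tr=tr, fs=phase.fs)
    frames = est.fit_transform(phase.values.T)
    return _frame_series(frames, tr, "phase", phase.n_regions, phase.band)


def fmri_edge_series(bold: RegionSignalSet) -> EdgeFrameSeries:
    """Per-TR BOLD edge time series (products of globally z-scored signals)."""
    if bold.modality != "slow":
        raise ValueError("fmri_edge_series expects slow-modality signals")
    tr = 1.0 / bold.fs
    est = EdgeTimeSeries(coupling="bold", tr=tr)
    frames = est.fit_transform(bold.values.T)
    return _frame_series(frames, tr, "bold", bold.n_regions, None)


def apply_hemodynamic_shift(frames: EdgeFrameSeries, lag: float, tr: Optional[float] = None) -> EdgeFrameSeries:
    """Shift an fMRI-FC frame series backwards in time by ``lag`` seconds.

    The frame that was acquired at time ``t + lag`` is re-indexed to ``t`` so
    that it lines up with electrophysiology at the time the neural activity
    occurred.  ``lag`` must be an integer multiple of TR; overhanging frames
    are dropped.
    """
    tr = frames.tr if tr is None else tr
    k_f = lag / tr
    k = int(round(k_f))
    if abs(k_f - k) > 1e-9:
        raise ValueError(
            f"lag {lag}s is not an integer multiple of TR={tr}s; "
            f"use a lag of k*TR (e.g. {k * tr}s)"
        )
    if k == 0:
        return replace(frames, shifted=True)
    if abs(k) >= frames.n_frames:
        raise ValueError("shift exceeds series length")
    if k > 0:
        new = frames.frames[k:]
        times = frames.frame_times[:-k]
    else:
        new = frames.frames[:k]
        times = frames.frame_times[-k:]
    return EdgeFrameSeries(new, tr=frames.tr, coupling=frames.coupling,
                           n_regions=frames.n_regions, band=frames.band,
                           frame_times=times, shifted=True)


def align_series(a: EdgeFrameSeries, b: EdgeFrameSeries) -> tuple[EdgeFrameSeries, EdgeFrameSeries]:
    """Trim two frame series to a common number of leading frames."""
    s = min(a.n_frames, b.n_frames)
    trim = lambda x: replace(x, frames=x.frames[:s], frame_times=x.frame_times[:s])
    return trim(a), trim(b)


def canonical_hrf(dt: float, peak: float = 6.0, undershoot: float = 16.0,
                  ratio: float = 6.0, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel, unit peak.

    Gamma densities with unit scale and modes at ``peak`` and ``undershoot``
    seconds; the undershoot is subtracted at 1/``ratio`` amplitude and the
    kernel is truncated at ``length`` seconds.
    """
    t = np.arange(0.0, length + dt / 2, dt)
    h = spstats.gamma.pdf(t, peak + 1.0) - spstats.gamma.pdf(t, undershoot + 1.0) / ratio
    return h / h.max()


def hrf_convolve(env: RegionSignalSet, lag: float = 6.0) -> RegionSignalSet:
    """Causal convolution with the canonical HRF, trimmed to input length.

    ``lag`` places the kernel peak (default 6 s, the canonical value); other
    lags time-shift the kernel rigidly.
    """
    dt = 1.0 / env.fs
    h = canonical_hrf(dt, peak=6.0)
    if lag != 6.0:
        shift = int(round((lag - 6.0) / dt))
        if shift > 0:
            h = np.concatenate([np.zeros(shift), h])
        elif shift < 0:
            h = h[-shift:]
    out = np.apply_along_axis(lambda x: np.convolve(x, h)[: x.size], 1, env.values)
    return env.with_values(out)


def static_fc(frames: EdgeFrameSeries) -> np.ndarray:
    """Static connectome: per-edge temporal mean of the frame series."""
    if frames.n_frames < 1:
        raise ValueError("need at least one frame")
    return frames.frames.mean(axis=0)
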