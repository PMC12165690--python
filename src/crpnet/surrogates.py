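"""Fourier phase-permutation surrogates: the package's null-data constructions.

Three spatial/temporal nulls are used throughout:

* ``spatial_phase_permute_fc`` scrambles the spatial organization of one
  symmetric connectivity matrix while preserving its 2-D amplitude spectrum
  (hence mean and total variance) exactly.
* ``temporal_phase_permute_edges`` scrambles each edge timecourse's phases
  independently, preserving the per-edge amplitude spectrum and — because the
  DC component is untouched — the static connectome exactly.
* ``phase_randomize_crp`` scrambles a binary multi-frequency recurrence plot
  band by band, re-binarizing at the quantile that preserves each band's
  significant-entry count exactly.

All routines produce real output by construction: the random phase field is
made antisymmetric under frequency negation (``phi(-u,-v) = -phi(u,v)``), the
symmetry the FFT of a real field itself obeys.  For symmetric matrices the
field is additionally made symmetric under ``(u,v) -> (v,u)`` so the
surrogate matrix stays symmetric without any spectrum-distorting
post-symmetrization.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Union

import numpy as np

from .signals import EdgeFrameSeries

__all__ = [
    "spatial_phase_permute_fc",
    "temporal_phase_permute_edges",
    "phase_randomize_crp",
    "phase_randomize_1d",
]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _negation_antisymmetric(xi: np.ndarray) -> np.ndarray:
    """phi(u,v) = xi(u,v) - xi(-u,-v); antisymmetric under index negation."""
    flip = xi[tuple(np.meshgrid(*[(-np.arange(n)) % n for n in xi.shape],
                                indexing="ij"))]
    return xi - flip


def _random_phase_field(rng: np.random.Generator, shape: tuple[int, ...],
                        swap_symmetric: bool = False) -> np.ndarray:
    xi = rng.uniform(0.0, 2 * np.pi, shape)
    if swap_symmetric:
        xi = xi + xi.T
    return _negation_antisymmetric(xi)


def spatial_phase_permute_fc(fc: np.ndarray, seed: RngLike = None) -> np.ndarray:
    """Spatial-null surrogate of a symmetric connectivity matrix.

    The matrix is symmetrized, transformed to 2-D Fourier space, its phases
    perturbed by a random field (symmetric under transposition, antisymmetric
    under negation, zero at self-conjugate frequencies), and reconstructed by
    the inverse transform.  The amplitude spectrum — and with it the matrix
    mean and total variance — is preserved to machine precision.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.all(np.isfinite(fc)):
        raise ValueError("matrix contains non-finite values")
    rng = _rng(seed)
    sym = (fc + fc.T) / 2.0
    phi = _random_phase_field(rng, sym.shape, swap_symmetric=True)
    F = np.fft.fft2(sym) * np.exp(1j * phi)
    out = np.fft.ifft2(F).real
    return (out + out.T) / 2.0  # numerical clean-up only; already symmetric


def spatial_phase_permute_frames(mats: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized spatial permutation of a (T, R, R) stack, fresh phases per frame."""
    T, R, _ = mats.shape
    xi = rng.uniform(0.0, 2 * np.pi, (T, R, R))
    xi = xi + np.swapaxes(xi, 1, 2)
    neg = (-np.arange(R)) % R
    phi = xi - xi[:, neg[:, None], neg[None, :]]
    F = np.fft.fft2(mats, axes=(1, 2)) * np.exp(1j * phi)
    out = np.fft.ifft2(F, axes=(1, 2)).real
    return (out + np.swapaxes(out, 1, 2)) / 2.0


def temporal_phase_permute_edges(frames: EdgeFrameSeries, seed: RngLike = None) -> EdgeFrameSeries:
    """Dynamics-null surrogate of an edge frame series.

    Each edge timecourse is Fourier phase-randomized independently (DC and
    Nyquist untouched), destroying the frame-to-frame connectome patterns
    while preserving every edge's amplitude spectrum and the static FC.
    """
    if frames.n_frames < 8:
        raise ValueError("need at least 8 frames")
    rng = _rng(seed)
    x = frames.frames
    T, E = x.shape
    F = np.fft.rfft(x, axis=0)
    phi = rng.uniform(0.0, 2 * np.pi, F.shape)
    phi[0] = 0.0
    if T % 2 == 0:
        phi[-1] = 0.0
    surr = np.fft.irfft(F * np.exp(1j * phi), n=T, axis=0)
    return replace(frames, frames=surr)


def phase_randomize_crp(layers: np.ndarray, seed: RngLike = None) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate multi-frequency CRP with per-band density preserved exactly.

    Parameters
    ----------
    layers : boolean array, (S_f, S_e, B)
        One binary significance layer per band.
    seed : int or Generator

    Returns
    -------
    surrogate_layers : boolean array, same shape
    union : boolean array, (S_f, S_e)
        Entrywise OR over the surrogate band layers.

    Each layer is treated as a real 2-D field, FFT phase-randomized, and
    re-binarized by marking exactly the original number of significant
    entries at the top of the randomized field.  Empty and full layers are
    returned unchanged.
    """
    layers = np.asarray(layers)
    if layers.ndim == 2:
        layers = layers[:, :, None]
    if layers.dtype != bool:
        raise ValueError("layers must be boolean")
    rng = _rng(seed)
    out = np.zeros_like(layers)
    S_f, S_e, B = layers.shape
    for b in range(B):
        layer = layers[:, :, b]
        count = int(layer.sum())
        if count == 0 or count == layer.size:
            out[:, :, b] = layer
            continue
        phi = _random_phase_field(rng, (S_f, S_e))
        field = np.fft.ifft2(np.fft.fft2(layer.astype(float)) * np.exp(1j * phi)).real
        flat = field.ravel()
        top = np.argpartition(flat, flat.size - count)[flat.size - count:]
        mask = np.zeros(flat.size, dtype=bool)
        mask[top] = True
        out[:, :, b] = mask.reshape(S_f, S_e)
    return out, out.any(axis=2)


def phase_randomize_1d(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier phase-randomized copy of a 1-D timecourse (spectrum preserved)."""
    x = np.asarray(x, dtype=float)
    T = x.size
    F = np.fft.rfft(x)
    phi = rng.uniform(0.0, 2 * np.pi, F.shape)
    phi[0] = 0.0
    if T % 2 == 0:
        phi[-1] = 0.0
    return np.fft.irfft(F * np.exp(1j * phi), n=T)
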