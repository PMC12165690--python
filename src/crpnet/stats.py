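"""Convergence statistics on binarized CRPs.

Temporal convergence is quantified by the on-/off-diagonal ratio: the rate
of significant entries on the k-shifted diagonal of the (square-trimmed)
multi-frequency CRP divided by the rate elsewhere.  A ratio >> 1 marks
synchronous (temporally convergent) cross-modal similarity; a ratio near 1 —
the value density-matched random CRPs produce — marks asynchronous
convergence.  Evidence for ratio ~ 1 over ratio > 1 is weighed by a
one-tailed JZS paired Bayes factor (Cauchy prior, scale 0.707), reported as
BF01.  Inter-band overlap of significant epochs is measured by the Jaccard
index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as spstats
from sklearn.base import BaseEstimator

from .crp import fdr_binarize
from .signals import EdgeFrameSeries
from .surrogates import phase_randomize_crp, temporal_phase_permute_edges

__all__ = [
    "on_off_ratio",
    "DiagonalProfile",
    "diagonal_profile",
    "DiagonalConvergence",
    "subject_nonparametric_p",
    "bf01_from_t",
    "bayes_paired_ttest_bf01",
    "jaccard",
    "band_jaccard_matrix",
    "static_crossmodal_similarity",
    "edge_temporal_convergence",
]


def _shift_submatrix(binary: np.ndarray, shift: int) -> np.ndarray:
    """Square submatrix on which the k-shifted diagonal is the main diagonal.

    Rows (columns) with no diagonal partner under the shift are cut from both
    the on- and off-diagonal counts.
    """
    S_f, S_e = binary.shape
    r0 = max(0, -shift)
    r1 = min(S_f, S_e - shift)
    if r1 - r0 < 2:
        raise ValueError(f"|shift|={abs(shift)} too large for CRP of shape {binary.shape}")
    return binary[r0:r1, r0 + shift:r1 + shift]


def on_off_ratio(binary: np.ndarray, shift: int = 0) -> float:
    """On-/off-diagonal significance-rate ratio at diagonal shift ``shift``.

    Returns NaN (with a warning) when the off-diagonal rate is zero.
    """
    sub = np.asarray(_shift_submatrix(np.asarray(binary, dtype=bool), shift))
    n = sub.shape[0]
    diag = np.diagonal(sub)
    on_rate = diag.mean()
    off_count = sub.sum() - diag.sum()
    off_rate = off_count / (sub.size - n)
    if off_rate == 0:
        warnings.warn(f"off-diagonal rate is zero at shift {shift}; ratio undefined")
        return float("nan")
    return float(on_rate / off_rate)


@dataclass
class DiagonalProfile:
    """On-/off-diagonal ratios over diagonal shifts, with null ensembles."""

    shifts: np.ndarray  # (n_shifts,) TR offsets
    ratios: np.ndarray  # (n_shifts,)
    null_ratios: np.ndarray  # (n_null, n_shifts)
    p_values: np.ndarray  # (n_shifts,) one-tailed empirical p

    def peak_shift(self) -> int:
        return int(self.shifts[np.nanargmax(self.ratios)])


def subject_nonparametric_p(observed: float, null_values: np.ndarray) -> float:
    """One-tailed empirical p: (1 + #{null >= observed}) / (n_null + 1)."""
    nulls = np.asarray(null_values, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size < 20:
        raise ValueError("need at least 20 null values")
    if not np.isfinite(observed):
        return float("nan")
    return float((1 + np.sum(nulls >= observed)) / (nulls.size + 1))


def diagonal_profile(layers: np.ndarray, shifts: Sequence[int] = tuple(range(-5, 6)),
                     n_null: int = 100, seed=None) -> DiagonalProfile:
    """Ratio profile of a multi-frequency CRP against phase-randomized nulls.

    ``layers`` is the (S_f, S_e, B) binary band stack; ratios are computed on
    its union layer and compared, shift by shift, with the union-layer ratios
    of ``n_null`` density-matched phase-randomized surrogate stacks.
    """
    layers = np.asarray(layers, dtype=bool)
    if layers.ndim == 2:
        layers = layers[:, :, None]
    if min(layers.shape[:2]) <= max(abs(int(s)) for s in shifts) + 1:
        raise ValueError("CRP too small for the requested diagonal shifts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    union = layers.any(axis=2)
    shifts = np.asarray(list(shifts), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratios = np.array([on_off_ratio(union, int(k)) for k in shifts])
        null_ratios = np.empty((n_null, shifts.size))
        for i in range(n_null):
            _, null_union = phase_randomize_crp(layers, rng)
            null_ratios[i] = [on_off_ratio(null_union, int(k)) for k in shifts]
    p = np.array([
        subject_nonparametric_p(ratios[s], null_ratios[:, s])
        if np.isfinite(ratios[s]) else np.nan
        for s in range(shifts.size)
    ])
    return DiagonalProfile(shifts=shifts, ratios=ratios, null_ratios=null_ratios, p_values=p)


class DiagonalConvergence(BaseEstimator):
    """Estimator form of the diagonal-ratio analysis.

    ``fit(layers)`` computes the ratio profile of a binary band stack and its
    phase-randomized null ensemble; results land in ``profile_``,
    ``ratios_``, ``null_ratios_`` and ``p_values_``.
    """

    def __init__(self, shifts: Sequence[int] = tuple(range(-5, 6)),
                 n_null: int = 100, random_state: Optional[int] = None):
        self.shifts = shifts
        self.n_null = n_null
        self.random_state = random_state

    def fit(self, layers: np.ndarray, y=None):
        self.profile_ = diagonal_profile(layers, shifts=self.shifts,
                                         n_null=self.n_null, seed=self.random_state)
        self.ratios_ = self.profile_.ratios
        self.null_ratios_ = self.profile_.null_ratios
        self.p_values_ = self.profile_.p_values
        return self


def bf01_from_t(t: float, n: int, prior_scale: float = 0.707) -> float:
    """One-tailed JZS Bayes factor BF01 from a paired t statistic.

    H1 places a Cauchy(0, ``prior_scale``) prior, truncated to positive
    effects, on the standardized mean difference; H0 fixes it at zero.  The
    marginal likelihood under H1 is evaluated by adaptive quadrature of the
    noncentral-t density over the prior.
    """
    if n < 3:
        raise ValueError("need at least 3 pairs")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return (spstats.nct.pdf(t, nu, delta * sqrt_n)
                * 2.0 * spstats.cauchy.pdf(delta, scale=prior_scale))

    m1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    m0 = spstats.t.pdf(t, nu)
    return float(m0 / m1)


def bayes_paired_ttest_bf01(observed: np.ndarray, null_means: np.ndarray,
                            prior_scale: float = 0.707) -> float:
    """BF01 for H0 (observed ratios = subject null means) vs one-sided H1 (>).

    A returned value above 1 favors the absence of temporal convergence.
    """
    obs = np.asarray(observed, dtype=float)
    null = np.asarray(null_means, dtype=float)
    if obs.shape != null.shape or obs.ndim != 1 or obs.size < 3:
        raise ValueError("need paired 1-D vectors of length >= 3")
    d = obs - null
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate: zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(d.size))
    return bf01_from_t(t, d.size, prior_scale=prior_scale)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index sum(A & B) / sum(A | B) of two binary arrays."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    union = np.sum(a | b)
    if union == 0:
        warnings.warn("both masks empty; Jaccard undefined")
        return float("nan")
    return float(np.sum(a & b) / union)


def band_jaccard_matrix(layers: np.ndarray, band_names: Sequence[str]) -> pd.DataFrame:
    """Pairwise Jaccard overlap of per-band binary CRP layers."""
    layers = np.asarray(layers, dtype=bool)
    B = layers.shape[2]
    out = np.full((B, B), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(B):
            for j in range(B):
                out[i, j] = 1.0 if i == j else jaccard(layers[:, :, i], layers[:, :, j])
    return pd.DataFrame(out, index=list(band_names), columns=list(band_names))


def static_crossmodal_similarity(static_fmri: np.ndarray, static_eeg: np.ndarray) -> float:
    """Pearson correlation of two static connectomes over the shared edge set."""
    a = np.asarray(static_fmri, dtype=float)
    b = np.asarray(static_eeg, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("edge vectors must share shape and order")
    return float(np.corrcoef(a, b)[0, 1])


def group_crp_summary(stacks, shift: int = 0) -> dict:
    """Group summary of per-subject CRP stacks.

    Returns the subject-mean union density (percent), the subject-mean
    on-/off-diagonal ratio of the union layer at ``shift``, and the
    subject-mean band-pair Jaccard matrix — the quantities reported for a
    cohort of per-subject multi-frequency CRPs.
    """
    if not stacks:
        raise ValueError("no CRP stacks given")
    dens = [100.0 * s.density() for s in stacks]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratios = [on_off_ratio(s.union, shift) for s in stacks]
    jac = sum(band_jaccard_matrix(s.binary, s.band_names) for s in stacks) / len(stacks)
    return {
        "union_density_pct": float(np.mean(dens)),
        "on_off_ratio": float(np.nanmean(ratios)),
        "jaccard": jac,
        "n_subjects": len(stacks),
    }


def edge_temporal_convergence(fmri: EdgeFrameSeries, eeg_hrf: EdgeFrameSeries,
                              n_perm: int = 100, q: float = 0.05, seed=None
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connection-level temporal convergence between aligned edge series.

    Per-edge Pearson correlation over frames between the fMRI edge series and
    the HRF-convolved electrophysiological edge series, tested one-tailed
    against ``n_perm`` temporal phase permutations of the latter and
    BH-FDR-corrected across edges.

    Returns ``(r, p, significant)``, each of length E.
    """
    if fmri.n_frames != eeg_hrf.n_frames:
        raise ValueError("series must be frame-aligned (apply the shift first)")
    if fmri.n_frames < 8:
        raise ValueError("need at least 8 frames")
    if fmri.n_edges != eeg_hrf.n_edges:
        raise ValueError("edge-order mismatch")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def col_z(x: np.ndarray) -> np.ndarray:
        sd = x.std(axis=0, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return (x - x.mean(axis=0, keepdims=True)) / sd

    Zf = col_z(fmri.frames)
    r_obs = (Zf * col_z(eeg_hrf.frames)).mean(axis=0)
    counts = np.zeros(fmri.n_edges, dtype=np.int64)
    for _ in range(n_perm):
        surr = temporal_phase_permute_edges(eeg_hrf, rng)
        counts += (Zf * col_z(surr.frames)).mean(axis=0) >= r_obs
    p = (1.0 + counts) / (n_perm + 1.0)
    return r_obs, p, fdr_binarize(p, q)
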