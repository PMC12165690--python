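"""Synthetic bimodal generator with known cross-timescale convergence structure.

Simulates R-region recordings in two modalities driven by a shared library of
K latent network states (symmetric, non-negative, unit-diagonal coupling
templates):

* fast modality — per-band band-limited Gaussian carriers mixed sample-wise
  through the Cholesky factor of the active state's template (cross-faded
  over one TR at state changes), summed over bands, plus white noise;
* slow modality — per-frame state-driven latent region activity convolved
  with the canonical HRF (peak at the configured hemodynamic lag), sampled at
  TR, plus white noise.

Three scenario modes control how the state sequences relate across
timescales: scenario I shares one Markov sequence everywhere (spatial and
temporal convergence), scenario II draws an independent sequence per
timescale from the shared library (spatial convergence only), scenario III
gives the fast and slow modalities disjoint half-libraries (full divergence).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc import ChebyBandpass, canonical_hrf
from .signals import CANONICAL_BANDS, BandSpec, RegionSignalSet, sym_to_vec

__all__ = ["ScenarioConfig", "GroundTruth", "make_state_library", "simulate_bimodal"]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic bimodal recording."""

    scenario: str = "I"  # "I" | "II" | "III"
    n_regions: int = 30
    n_states: int = 4
    tr: float = 3.0
    duration: float = 600.0  # seconds -> 200 frames at TR = 3 s
    fs_fast: float = 250.0
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
    hemo_lag: float = 6.0
    state_dwell: float = 45.0  # mean dwell per state, seconds
    snr: float = 3.0  # state-driven-to-noise amplitude ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("I", "II", "III"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.n_frames < 20:
            raise ValueError("need at least 20 frames (duration/tr)")
        hi = max(CANONICAL_BANDS[b].high for b in self.bands)
        if self.fs_fast <= 2 * hi:
            raise ValueError(f"fs_fast must exceed twice the highest band edge ({hi} Hz)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.state_dwell < self.tr:
            raise ValueError("mean state dwell must be at least one TR")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.tr))

    @property
    def band_specs(self) -> list[BandSpec]:
        return [CANONICAL_BANDS[b] for b in self.bands]

    @property
    def timescales(self) -> list[str]:
        return list(self.bands) + ["slow"]


@dataclass
class GroundTruth:
    """Latent structure of one simulated recording (for recovery tests)."""

    state_sequence_per_timescale: dict[str, np.ndarray]
    state_library: np.ndarray  # (K, R, R), symmetric, unit diagonal
    lag_applied: float  # seconds


def make_state_library(R: int, K: int, seed=None, max_corr: float = 0.5,
                       max_tries: int = 500, n_modules: int = 3,
                       within: float = 0.9, between: float = 0.05) -> np.ndarray:
    """K symmetric PSD unit-diagonal coupling templates with distinct layouts.

    Each template is a modular coupling matrix: regions are randomly
    partitioned into ``n_modules`` communities, coupling is ``within`` inside
    a community and ``between`` elsewhere (unit diagonal).  Such matrices are
    PSD by construction (a between-level rank-one background plus per-module
    blocks plus a positive diagonal), non-negative, and spatially
    distinctive.  Candidates are drawn until every pair of accepted templates
    has upper-triangle spatial correlation below ``max_corr``.
    """
    if R < 4 or K < 2:
        raise ValueError("need R >= 4 and K >= 2")
    if not 0 <= between < within <= 1:
        raise ValueError("need 0 <= between < within <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    vecs: list[np.ndarray] = []
    tries = 0
    while len(accepted) < K:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not decorrelate {K} templates at R={R} "
                f"within {max_tries} draws; increase R or lower K"
            )
        membership = rng.integers(n_modules, size=R)
        if np.unique(membership).size < min(n_modules, R):
            continue
        same = membership[:, None] == membership[None, :]
        C = np.where(same, within, between)
        np.fill_diagonal(C, 1.0)
        v = sym_to_vec(C)
        if v.std() == 0:
            continue
        if all(abs(np.corrcoef(v, u)[0, 1]) < max_corr for u in vecs):
            accepted.append(C)
            vecs.append(v)
    return np.stack(accepted)


def _markov_sequence(n_frames: int, states: np.ndarray, p_stay: float,
                     rng: np.random.Generator) -> np.ndarray:
    """First-order Markov chain over ``states`` with uniform off-diagonal mass."""
    K = states.size
    seq = np.empty(n_frames, dtype=int)
    cur = int(rng.integers(K))
    for t in range(n_frames):
        seq[t] = states[cur]
        if K > 1 and rng.random() > p_stay:
            nxt = int(rng.integers(K - 1))
            cur = nxt if nxt < cur else nxt + 1
    return seq


def _band_carriers(R: int, n_samples: int, band: BandSpec, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Independent unit-variance band-limited Gaussian carriers, (R, n)."""
    white = rng.standard_normal((n_samples, R))
    flt = ChebyBandpass(band=band, fs=fs).fit()
    x = flt.transform(white).T
    return x / x.std(axis=1, keepdims=True)


def _mix_crossfade(carriers: np.ndarray, chols: np.ndarray, seq: np.ndarray,
                   n_win: int) -> np.ndarray:
    """Mix (R, n) carriers through per-frame Cholesky factors.

    The mixing matrix is piecewise-linearly interpolated between the factors
    of consecutive frames across each inter-centre segment (a 1-TR
    cross-fade), avoiding discontinuities at state changes.
    """
    R, n = carriers.shape
    T = seq.size
    out = np.empty_like(carriers)
    x = carriers.T  # (n, R)
    centers = (np.arange(T) + 0.5) * n_win
    # leading segment: pure first frame
    first = int(round(centers[0]))
    out[:, :first] = (x[:first] @ chols[seq[0]].T).T
    for k in range(T - 1):
        a0, a1 = int(round(centers[k])), int(round(centers[k + 1]))
        a1 = min(a1, n)
        w = (np.arange(a0, a1) - centers[k]) / (centers[k + 1] - centers[k])
        seg = x[a0:a1]
        y = (1 - w)[:, None] * (seg @ chols[seq[k]].T) + w[:, None] * (seg @ chols[seq[k + 1]].T)
        out[:, a0:a1] = y.T
    last = int(round(centers[-1]))
    if last < n:
        out[:, last:] = (x[last:] @ chols[seq[-1]].T).T
    return out


def simulate_bimodal(config: ScenarioConfig) -> tuple[RegionSignalSet, RegionSignalSet, GroundTruth]:
    """Simulate one bimodal recording under the configured scenario.

    Returns the fast (electrophysiology-like) signal set, the slow
    (BOLD-like) signal set, and the ground truth used to generate them.
    """
    rng = np.random.default_rng(config.seed)
    R, K, T = config.n_regions, config.n_states, config.n_frames
    library = make_state_library(R, K, rng)
    chols = np.stack([np.linalg.cholesky(C + 1e-9 * np.eye(R)) for C in library])
    p_stay = 1.0 - config.tr / config.state_dwell

    if config.scenario == "III":
        fast_states = np.arange(K // 2)
        slow_states = np.arange(K // 2, K)
    else:
        fast_states = slow_states = np.arange(K)

    sequences: dict[str, np.ndarray] = {}
    if config.scenario == "I":
        shared = _markov_sequence(T, fast_states, p_stay, rng)
        for ts in config.timescales:
            sequences[ts] = shared.copy()
    else:
        for band in config.bands:
            sequences[band] = _markov_sequence(T, fast_states, p_stay, rng)
        sequences["slow"] = _markov_sequence(T, slow_states, p_stay, rng)

    # fast modality: sum of state-mixed band carriers + white noise
    n_win = int(round(config.tr * config.fs_fast))
    n_fast = T * n_win
    fast = np.zeros((R, n_fast))
    for band in config.band_specs:
        carriers = _band_carriers(R, n_fast, band, config.fs_fast, rng)
        fast += _mix_crossfade(carriers, chols, sequences[band.name], n_win)
    fast += rng.standard_normal((R, n_fast)) / config.snr

    # slow modality: per-frame state-driven latents -> HRF -> + noise
    eps = rng.standard_normal((T, R))
    latent = np.einsum("trs,ts->tr", chols[sequences["slow"]], eps)  # (T, R)
    h = canonical_hrf(config.tr, peak=6.0)
    if config.hemo_lag != 6.0:
        shift = int(round((config.hemo_lag - 6.0) / config.tr))
        if shift > 0:
            h = np.concatenate([np.zeros(shift), h])
        elif shift < 0:
            h = h[-shift:]
    bold = np.apply_along_axis(lambda x: np.convolve(x, h)[:T], 0, latent).T  # (R, T)
    bold += rng.standard_normal((R, T)) * (bold.std() / config.snr)

    fast_set = RegionSignalSet(fast, fs=config.fs_fast, modality="fast")
    slow_set = RegionSignalSet(bold, fs=1.0 / config.tr, modality="slow")
    truth = GroundTruth(state_sequence_per_timescale=sequences,
                        state_library=library, lag_applied=config.hemo_lag)
    return fast_set, slow_set, truth
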