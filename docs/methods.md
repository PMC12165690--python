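# Methods

`crpnet` analyzes whether the dynamic reconfigurations of functional
connectomes derived at different neural timescales — hemodynamic (BOLD-like,
sampled at TR) and electrophysiological (five canonical frequency bands) —
traverse similar spatial patterns, and whether they do so synchronously.
This note documents the models, the statistical machinery, the synthetic
study conditions, and the numerical choices, in the order the pipeline runs.

## Frame-wise functional connectivity

Connectome *frames* are vectors of pairwise coupling over the fixed
row-major upper-triangle edge set (E = R(R−1)/2 edges for R regions), one
frame per repetition time (TR).

* **BOLD edge time series.** `fMRI_FC_ij(t) = Z(BOLD_i)(t) · Z(BOLD_j)(t)`,
  the per-volume product of globally z-scored region signals. Averaged over
  time this reduces exactly to the Pearson correlation matrix (the static
  connectome), which the test suite asserts to 1e-12.
* **Amplitude coupling.** The fast signals are band-passed (below), Hilbert
  envelopes are extracted, z-scored over the entire recording, and averaged
  as products over N = round(TR·fs) samples in a TR-long window:
  `EEG_FC_amp_ij(t) = (1/N) Σ_m Z(env_i)(m) Z(env_j)(m)`.
* **Phase coupling.** The phase-locking value over the same windows:
  `EEG_FC_phase_ij(t) = |(1/N) Σ_m exp(i Δφ_ij(m))|`, in [0, 1]. The
  defining sum is complex; we take its modulus (the standard PLV), since a
  complex "consistency" value is not orderable.

**Z-scoring convention.** Population denominators (divide by T, not T−1)
throughout, so the edge-series/Pearson identity and the unit self-product
hold exactly rather than up to a ddof factor.

**Windows.** Window k covers the acquisition interval of fMRI volume k,
`[k·TR, (k+1)·TR)`; centers step by exactly one TR, so frame indices match
fMRI volume indices one-to-one and windows tile the recording with no
partial windows under the default alignment. Windows that would overhang
the recording (non-integer durations) are dropped, not zero-padded, to
avoid envelope edge artifacts.

**Band-pass filter.** Fourth-order Chebyshev type II, 40 dB stopband,
applied forward-backward (zero phase — required for meaningful PLV).
Canonical bands: δ 1–4, θ 5–7, α 8–13, β 14–30, γ 31–60 Hz. The filter
design needs a stopband-edge placement the band definition alone does not
give; edges sit half an octave outside the passband, which leaves the band
centre within ±1 dB of unity while guaranteeing ≥40 dB one octave out
(Chebyshev II stopbands are equiripple at the design attenuation).

**Hemodynamic alignment.** The fMRI-FC frame sequence is shifted 6 s
backwards in time (2 frames at TR = 3 s, 3 frames at TR = 2 s); the lag
must be an integer multiple of TR and overhanging frames are dropped from
both series. For the HRF-convolved replication path, band envelopes are
convolved with a canonical double-gamma kernel: unit-scale gamma densities
with modes at 6 s (peak) and 16 s (undershoot), undershoot weight 1/6,
truncated at 32 s, normalized to unit peak.

## Cross-modal recurrence plots

The CRP is the S_f × S_e matrix of spatial Pearson correlations (across
edges) between every fMRI frame and every band-specific electrophysiological
frame. Entry-wise significance uses a spatial null: each fMRI frame is
re-assembled to its symmetric R × R matrix form (diagonal set to 0 — the
edge vector does not determine it, and the null should randomize exactly the
information the statistic uses), phase-permuted in 2-D Fourier space, and
the full null CRP recomputed; the n_perm = 100 null CRPs are generated once
per band and shared across entries, so each entry is compared against its
own 100 null correlations. One-tailed empirical
p = (1 + #{null ≥ observed}) / (n_perm + 1); entries with non-positive
observed correlation are assigned p = 1 and never enter the significant set
(anticorrelation of whole-connectome patterns is not interpreted).
Benjamini–Hochberg FDR at q = 0.05 is applied per band jointly over all
S_f × S_e entries; binary layers are overlaid (logical OR) into the
multi-frequency CRP.

Because the empirical p cannot fall below 1/(n_perm+1), BH over S² entries
only rejects once roughly a fraction p_min/q ≈ 0.2 of entries beat all 100
permutations; the binary CRP therefore behaves almost all-or-none per band.
This is a property of the prescribed procedure, not of the implementation,
and is why scenario-recovery checks run at the full five-band condition
where the union is robust to single-band dropouts.

## Phase-permutation surrogates

All surrogates preserve amplitude spectra exactly by construction: the
random phase perturbation field is made antisymmetric under frequency
negation, φ(−u,−v) = −φ(u,v) — the symmetry a real field's FFT phase obeys —
so the inverse transform is real without taking a real part (which would
distort the spectrum). Self-conjugate frequencies (DC, Nyquist) get zero
perturbation, so means are preserved exactly.

* **Spatial (matrix) permutation** additionally uses a field symmetric under
  (u,v) → (v,u), so a symmetric input yields a symmetric surrogate with the
  amplitude spectrum preserved to machine precision — no post-hoc
  symmetrization is needed (averaging with the transpose, the naive fix,
  would break the spectrum-preservation guarantee).
* **Temporal (edge timecourse) permutation** randomizes each edge
  independently along time; the untouched DC component preserves the static
  connectome exactly while the frame-to-frame connectome patterns are
  destroyed.
* **Binary CRP randomization** treats each band layer as a real field,
  phase-randomizes it, and re-binarizes by marking exactly the original
  number of significant entries at the top of the randomized field. The
  procedure a binary matrix should undergo is underdetermined; count-matched
  re-binarization preserves density, the quantity the on/off-ratio statistic
  conditions on. Ties in the randomized field are broken deterministically
  by partition order under the given seed.

## Convergence statistics

**On-/off-diagonal ratio.** For diagonal shift k, the CRP is restricted to
the square submatrix on which the k-shifted diagonal is the main diagonal
(rows/columns with no diagonal partner are cut from both counts); the ratio
is the significant fraction on that diagonal over the significant fraction
elsewhere. Ratios are computed on the multi-frequency union layer
(headline) and per band, for shifts −5…+5 TR. A zero off-diagonal rate
leaves the ratio undefined (reported missing, never +∞), and undefined
ratios are excluded from group aggregation with a logged warning.

**Null ensembles and tests.** Each subject's ratio is compared with the
ratios of 100 phase-randomized, density-matched surrogate multi-frequency
CRPs (one-tailed empirical p). At group level a one-tailed JZS paired
Bayes factor weighs H0 (ratio equals the subject's null mean; asynchronous
convergence) against H1 (ratio greater; synchronous convergence), with a
Cauchy(0, 0.707) prior on the standardized effect truncated to positive
values. BF01 = m0/m1 with m1 evaluated by adaptive quadrature of the
noncentral-t density over the folded Cauchy prior; the tests cross-check it
against an independent normal-mixture (g-prior) double quadrature and
against pingouin's two-sided value through the exact identity
BF10_two-sided(t) = (BF10_greater(t) + BF10_greater(−t))/2. Per-shift BF01
values are reported individually (−5…+5), not pooled.

**Band overlap.** Jaccard index Σ(A & B)/Σ(A | B) between the binary CRPs
of band pairs; undefined when both layers are empty.

**Connection-level convergence.** Per-edge Pearson correlation over time
between the (shift-aligned) fMRI edge series and the HRF-convolved
electrophysiological edge series, tested one-tailed against temporal phase
permutations of the latter and BH-FDR-corrected across edges.

## Recurrent states and dissociability

Frames pooled over subjects are clustered with K-means (Euclidean distance
on raw frames; correlation distance available as an option), K = 5 with
K = 7 for replication, 20 restarts keeping the best inertia. Centroids are
computed in the untransformed edge space as per-cluster means. The
proximity matrix is the pairwise Pearson similarity between frames
(similarity, not distance, so block structure is positive); dissociability
is the Pearson correlation between its off-diagonal entries and the binary
within-cluster indicator (diagonal excluded — self-similarity is trivially
1). The empirical dissociability is z-scored against 50 surrogate datasets
built by per-subject temporal phase permutation, re-pooled and re-clustered
with fresh K-means seeds so the null includes clustering variability.
Because per-edge phase randomization leaves each surrogate frame a random
mixture of all frames, surrogate states collapse toward the static
connectome — the property the tests assert.

## Confound checks

The synchronous cross-modal similarity timecourse (CRP diagonal, lag
already applied) is correlated with: overall FC strength (per-frame
root-sum-square over edges), framewise displacement
(FD(t) = Σ|Δtranslation| + r·Σ|Δrotation|, rotations converted to arc
length on a 50 mm sphere — the standard radius for this formulation), and
static-connectome prominence (per-frame correlation with the static FC
vector). Each correlation gets a two-sided empirical p against 100 Fourier
phase-randomized versions of the similarity timecourse (preserving its
autocorrelation). Artifact-epoch overlap uses the Jaccard index between
the binarized similarity timecourse (significance of the union-layer
diagonal) and the artifact mask, against a circular-shift null (non-zero
shifts, drawn without replacement when fewer than requested are available).
Within-network (ICN) strength timecourses average the FC of all edges
inside a network, z-score over frames, and threshold at z > 2.

## Synthetic study conditions

The generator defines the conditions under which the machinery is
validated; it emulates the *structure* of bimodal recordings, not their
biophysics.

A library of K latent network states is built as random modular coupling
templates: regions are randomly partitioned into 3 modules; coupling is
0.9 within and 0.05 between modules, unit diagonal. Such matrices are
positive semidefinite by construction, non-negative (so envelope coupling —
which loses sign — remains monotonically related to the template), and
spatially distinctive; candidates are redrawn until all pairwise
upper-triangle correlations are below 0.5. State dynamics follow a
first-order Markov chain with uniform off-diagonal transition mass.

* **Fast modality:** per band, R independent unit-variance band-limited
  Gaussian carriers mixed sample-wise through the Cholesky factor of the
  active template, the mixing matrix linearly cross-faded over one TR
  between consecutive frames; bands are summed and white Gaussian noise
  with standard deviation 1/snr (relative to the unit per-band carrier) is
  added.
* **Slow modality:** one state-driven latent draw per frame
  (x_k = L_{s_k} ε_k), convolved region-wise with the canonical HRF sampled
  at TR and scaled so the kernel peak sits at the configured hemodynamic
  lag (default 6 s, the canonical peak; other lags shift the kernel
  rigidly), plus white noise at 1/snr of the signal's standard deviation.

Scenario I shares one state sequence across all timescales (spatial and
temporal convergence); scenario II draws an independent sequence per
timescale from the shared library (spatial convergence at asynchronous
times); scenario III splits the library into disjoint halves for the fast
and slow modalities (no convergence).

**Defaults** (chosen once as realistic study conditions): R = 30 regions,
200 frames at TR = 3 s (600 s recording), fs = 250 Hz, all five bands,
hemodynamic lag 6 s, K = 4 states (matching the reported number of
hemodynamic connectome states), mean dwell 45 s (within the range reported
for fMRI dFC states), snr = 3 (amplitude ratio of state-driven signal to
noise; region-averaged signals are relatively clean). All randomness flows
from a single seed through `numpy.random.SeedSequence`; identical
configurations reproduce bitwise-identical outputs.

**What the generator does not emulate:** 1/f aperiodic background, volume
conduction/source leakage, epileptiform events, subject-to-subject
anatomical variability, physiological noise with temporal structure, or
biophysical neurovascular coupling (no balloon model). Passing recovery
tests therefore demonstrates that the statistics detect (and refuse to
hallucinate) cross-timescale convergence of the modelled kind — not that
real recordings contain such structure.

## Problem sizes in the shipped checks

The automated checks run the full pipeline at the study conditions above:
20 scenario-I replicates and 10 scenario-II replicates (five bands,
n_perm = 100, 100 surrogate CRPs each), 3 near-zero-snr scenario-III
replicates for FDR calibration, 100-surrogate null-ratio calibration on a
scenario-II multi-frequency CRP, and state-dissociability checks on
10-region/5-state structured frames with 50 clustering surrogates (16
self-null repetitions). Unit tests use smaller toys with oracle values
computed in-test.

## Known limitations

* The empirical-p floor makes per-band binary CRPs nearly all-or-none at
  n_perm = 100 (see above); densities should be compared across conditions
  only at matched n_perm.
* The spatial null randomizes fMRI frames only (as specified); the
  electrophysiological frames are treated as fixed.
* K-means with Euclidean distance is scale-sensitive across edges; frames
  are used raw, matching the headline procedure.
* `snr` controls broadband white noise; in-band noise after filtering is
  smaller by the band's share of the Nyquist range.
* Iterated phase randomization progressively Gaussianizes edge
  timecourses, so surrogates of already-permuted data score marginally
  higher dissociability than the permuted input itself; self-null z-scores
  carry a small negative offset that shrinks with the number of frames.
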