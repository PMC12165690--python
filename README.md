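# crpnet

Cross-modal recurrence-plot analysis of functional connectome dynamics.

Hemodynamic (fMRI/BOLD) and electrophysiological (EEG/iEEG) recordings see
brain network coupling at very different timescales: infraslow
co-fluctuations on one side, band-limited (δ–γ) amplitude and phase coupling
on the other. A central question in multimodal network neuroscience is
whether the frame-by-frame reconfigurations of these connectomes converge —
do both modalities traverse similar connectivity patterns, and if so, do
they traverse them at the same time?

`crpnet` implements the analysis machinery for that question, for
methodologists and multimodal-imaging researchers:

- **frame-wise FC** at every repetition time (TR): BOLD edge time series
  `fMRI_FC_ij(t) = Z(BOLD_i)(t)·Z(BOLD_j)(t)`, band-limited envelope
  coupling `EEG_FC_amp_ij(t) = (1/N) Σ_m Z(env_i)(m) Z(env_j)(m)` over
  TR-long windows, and phase-locking values
  `|(1/N) Σ_m exp(i Δφ_ij(m))|`;
- the **cross-modal recurrence plot (CRP)**: spatial correlation between
  every fMRI connectome frame and every band-specific electrophysiological
  frame, with entry-wise significance from spatial Fourier phase-permutation
  nulls, Benjamini–Hochberg FDR (q = 0.05), and the per-band layers overlaid
  into a multi-frequency CRP;
- **convergence statistics**: the on-/off-diagonal ratio over diagonal
  shifts (−5…+5 TR) against density-matched phase-randomized surrogate
  CRPs, one-tailed JZS paired Bayes factors (Cauchy prior, scale 0.707)
  reported as BF01, inter-band Jaccard overlap, static cross-modal
  similarity, and connection-level temporal convergence;
- **recurrent-state clustering** (K-means, K = 5/7) with proximity-matrix
  dissociability z-scored against temporally phase-permuted surrogates;
- **confound checks**: FC strength, framewise displacement,
  static-connectome prominence, artifact-epoch overlap, ICN strength
  timecourses;
- a **synthetic bimodal generator** with three ground-truth scenarios —
  I: shared state sequence across timescales (synchronous convergence),
  II: shared state repertoire with independent sequences (asynchronous
  convergence), III: disjoint repertoires (no convergence) — used to
  validate the whole chain end-to-end.

The core analyses are exposed as scikit-learn-style estimators
(`CrossModalRecurrence`, `DiagonalConvergence`, `ConnectomeStates`,
`ChebyBandpass`, `EdgeTimeSeries`) with plain-function wrappers, plus a
`crpnet` command-line interface (`simulate`, `fc`, `crp`, `stats`,
`states`, `confounds`, `run-all`).

See `docs/methods.md` for the full model and parameter documentation.

## Worked example

Simulate an asynchronously convergent recording (scenario II: both
modalities visit the same four network states, but on independent
schedules) and run the subject-level analysis:

```python
import numpy as np
from crpnet import ScenarioConfig, simulate_bimodal, analyze_subject

cfg = ScenarioConfig(scenario="II", seed=7)   # five bands, R=30, 200 frames
fast, slow, truth = simulate_bimodal(cfg)
res = analyze_subject(fast, slow, bands=cfg.bands, lag=cfg.hemo_lag, seed=7)

prof = res["profile"]
k0 = list(prof.shifts).index(0)
jac = res["jaccard"].to_numpy()
np.fill_diagonal(jac, np.nan)
print(f"union CRP density: {res['density']:.3f}")
print(f"on/off ratio at zero shift: {prof.ratios[k0]:.2f} "
      f"(null mean {prof.null_ratios[:, k0].mean():.2f}, p = {prof.p_values[k0]:.3f})")
print(f"largest inter-band Jaccard overlap: {np.nanmax(jac):.3f}")
```

Output:

```
union CRP density: 0.417
on/off ratio at zero shift: 1.14 (null mean 1.01, p = 0.178)
largest inter-band Jaccard overlap: 0.077
```

Read: 41.7% of frame pairs show significant cross-modal spatial correlation
in at least one band (spatial convergence — rules out scenario III), but the
on-diagonal rate is statistically indistinguishable from the off-diagonal
rate (ratio ≈ 1, inside the surrogate null), so the convergence is
asynchronous — scenario II, as simulated. The small inter-band overlap
shows the five frequency bands converge with the hemodynamic connectome at
largely distinct times. A scenario-I simulation instead yields ratios
around 2.5 with p = 1/101 at the configured 6 s lag.

The same analysis from the shell:

```bash
crpnet simulate --scenario II --seed 7 --out sim.h5
crpnet run-all --config analysis.yaml
```

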