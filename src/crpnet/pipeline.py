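"""End-to-end orchestration: simulate/load -> FC -> CRP -> stats -> states -> confounds.

All randomness flows from one master seed: stage generators are spawned from
``numpy.random.SeedSequence(master_seed)`` in a fixed order, so a rerun with
the same configuration reproduces every deterministic output bitwise.
"""
from __future__ import annotations

import dataclasses
import warnings
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, confounds as conf, fc, io, states as st, stats
from .crp import AnalysisConfig, CrossModalRecurrence
from .signals import EdgeFrameSeries, RegionSignalSet
from .synth import ScenarioConfig, simulate_bimodal

__all__ = ["RunManifest", "run_full_analysis", "analyze_subject", "load_config"]

_REQUIRED_KEYS = ("out_dir", "seed", "subjects")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    master_seed: int
    versions: dict
    outputs: dict = field(default_factory=dict)  # name -> path
    checksums: dict = field(default_factory=dict)  # path -> sha256

    def register(self, name: str, path: Path) -> None:
        self.outputs[name] = str(path)
        self.checksums[str(path)] = hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def load_config(path) -> dict:
    """Read a JSON or YAML pipeline configuration and validate required keys."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise ValueError(f"missing required configuration key: {key!r}")
    return cfg


def _subject_inputs(entry: dict, seed_seq: np.random.SeedSequence,
                    bands, lag: float):
    """Resolve one subject entry (simulate block or file paths)."""
    if "simulate" in entry:
        sim = dict(entry["simulate"])
        sim.setdefault("bands", tuple(bands))
        sim.setdefault("hemo_lag", lag)
        sim.setdefault("seed", int(np.random.default_rng(seed_seq).integers(2**31)))
        cfg = ScenarioConfig(**sim)
        fast, slow, truth = simulate_bimodal(cfg)
        return fast, slow, None, None, truth
    for key in ("fast", "slow", "fs_fast", "tr"):
        if key not in entry:
            raise ValueError(f"missing required subject key: {key!r}")
    fast, slow, motion, artifact = io.load_subject(
        entry["fast"], entry["slow"], fs_fast=entry["fs_fast"], tr=entry["tr"],
        motion_path=entry.get("motion"), artifact_path=entry.get("artifact"))
    return fast, slow, motion, artifact, None


def analyze_subject(fast: RegionSignalSet, slow: RegionSignalSet, bands,
                    lag: float = 6.0, coupling: str = "amp",
                    analysis: Optional[AnalysisConfig] = None,
                    seed: Optional[int] = None,
                    motion: Optional[np.ndarray] = None,
                    artifact: Optional[np.ndarray] = None) -> dict:
    """Run FC -> CRP -> convergence statistics -> confounds for one subject.

    Returns a dict with the frame series, the fitted CRP stack, the diagonal
    ratio profile, the band-pair Jaccard matrix, static cross-modal
    similarity per band, and (when nuisance inputs exist) confound tests.
    """
    analysis = analysis or AnalysisConfig()
    ss = np.random.SeedSequence(seed)
    crp_seed, null_seed, conf_seed = [
        int(np.random.default_rng(s).integers(2**31)) for s in ss.spawn(3)]
    tr = 1.0 / slow.fs

    bold = fc.fmri_edge_series(slow)
    bold_shift = fc.apply_hemodynamic_shift(bold, lag, tr)
    eeg = {}
    for band in bands:
        filtered = fc.bandpass(fast, band)
        env, phase = fc.hilbert_env_phase(filtered)
        if coupling == "amp":
            eeg[band] = fc.eeg_fc_amp(env, tr)
        elif coupling == "phase":
            eeg[band] = fc.eeg_fc_phase(phase, tr)
        else:
            raise ValueError(f"unknown electrophysiological coupling {coupling!r}")
    n_frames = min([bold_shift.n_frames] + [e.n_frames for e in eeg.values()])
    bold_a = dataclasses.replace(bold_shift, frames=bold_shift.frames[:n_frames],
                                 frame_times=bold_shift.frame_times[:n_frames])
    eeg_a = {b: dataclasses.replace(e, frames=e.frames[:n_frames],
                                    frame_times=e.frame_times[:n_frames])
             for b, e in eeg.items()}

    crp_est = CrossModalRecurrence(q=analysis.q, n_perm=analysis.n_perm,
                                   random_state=crp_seed).fit(bold_a, eeg_a)
    profile = stats.diagonal_profile(crp_est.binary_, shifts=analysis.shifts,
                                     n_null=analysis.n_null_crp, seed=null_seed)
    jac = stats.band_jaccard_matrix(crp_est.binary_, crp_est.bands_)
    static_sim = {b: stats.static_crossmodal_similarity(
        fc.static_fc(bold_a), fc.static_fc(e)) for b, e in eeg_a.items()}

    result = {
        "bold_frames": bold_a, "eeg_frames": eeg_a, "crp": crp_est.stack_,
        "profile": profile, "jaccard": jac, "static_similarity": static_sim,
        "density": crp_est.stack_.density(),
    }

    rng = np.random.default_rng(conf_seed)
    sim_tc = conf.similarity_timecourse(crp_est.r_[:, :, 0])
    nuis = {"fc_strength": conf.fc_strength_timecourse(bold_a),
            "static_prominence": conf.static_prominence_timecourse(bold_a)}
    if motion is not None:
        fd = conf.framewise_displacement(motion)
        nuis["fd"] = fd[-sim_tc.size:] if fd.size >= sim_tc.size else None
    confound_tests = {}
    if sim_tc.size >= 16:
        for name, tc in nuis.items():
            if tc is not None and tc.size == sim_tc.size:
                r, p = conf.timecourse_null_correlation(
                    sim_tc, tc, n_perm=analysis.n_perm, seed=rng)
                confound_tests[name] = {"r": r, "p": p}
    if artifact is not None:
        sim_binary = np.diagonal(crp_est.union_).copy()
        if artifact.size >= sim_binary.size:
            jacc, p = conf.artifact_overlap_test(
                sim_binary, artifact[:sim_binary.size], seed=rng)
            confound_tests["artifact_overlap"] = {"jaccard": jacc, "p": p}
    result["confounds"] = confound_tests
    return result


def run_full_analysis(config, out_dir=None) -> RunManifest:
    """Execute the full pipeline described by a configuration mapping/path.

    Writes per-subject CRP bundles, tidy CSV statistics, optional state
    clustering results and a JSON manifest; returns the manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config["seed"])
    bands = list(config.get("bands", ["delta", "theta", "alpha", "beta", "gamma"]))
    lag = float(config.get("lag", 6.0))
    coupling = config.get("coupling", "amp")
    analysis = AnalysisConfig(
        q=float(config.get("q", 0.05)),
        n_perm=int(config.get("n_perm", 100)),
        shifts=tuple(config.get("shifts", range(-5, 6))),
        n_null_crp=int(config.get("n_null_crp", 100)),
        n_surrogate_states=int(config.get("n_surrogate_states", 50)),
    )
    manifest = RunManifest(
        config=config, master_seed=master_seed,
        versions={"crpnet": __version__, "numpy": np.__version__,
                  "python": platform.python_version()})

    root_ss = np.random.SeedSequence(master_seed)
    subject_seeds = root_ss.spawn(len(config["subjects"]) + 1)
    rows, jac_frames, results = [], [], []
    for s_idx, entry in enumerate(config["subjects"]):
        try:
            fast, slow, motion, artifact, truth = _subject_inputs(
                entry, subject_seeds[s_idx], bands, lag)
            res = analyze_subject(
                fast, slow, bands, lag=lag, coupling=coupling, analysis=analysis,
                seed=int(np.random.default_rng(subject_seeds[s_idx]).integers(2**31)),
                motion=motion, artifact=artifact)
        except Exception as exc:  # annotate failures with stage context
            raise RuntimeError(f"subject {s_idx}: {exc}") from exc
        results.append(res)
        crp_path = out / f"subject{s_idx:02d}_crp.h5"
        io.write_crp_hdf5(res["crp"], crp_path, seed=master_seed, lag=lag)
        manifest.register(f"crp_subject{s_idx:02d}", crp_path)
        prof = res["profile"]
        for k, shift in enumerate(prof.shifts):
            nulls = prof.null_ratios[:, k]
            nulls = nulls[np.isfinite(nulls)]
            rows.append({
                "subject": s_idx, "shift_tr": int(shift),
                "ratio": prof.ratios[k],
                "null_mean": nulls.mean() if nulls.size else np.nan,
                "null_sd": nulls.std() if nulls.size else np.nan,
                "p": prof.p_values[k],
                "union_density": res["density"],
            })
        jac_frames.append(res["jaccard"])

    ratio_df = pd.DataFrame(rows)
    ratio_path = out / "ratios.csv"
    ratio_df.to_csv(ratio_path, index=False)
    manifest.register("ratios", ratio_path)

    jac_mean = sum(jac_frames) / len(jac_frames)
    jac_path = out / "jaccard.csv"
    jac_mean.to_csv(jac_path)
    manifest.register("jaccard", jac_path)

    if len(results) >= 3:
        bf_rows = []
        for k, shift in enumerate(analysis.shifts):
            obs = np.array([r["profile"].ratios[k] for r in results])
            nul = np.array([
                np.mean(v[np.isfinite(v)]) if np.isfinite(v).any() else np.nan
                for v in (r["profile"].null_ratios[:, k] for r in results)])
            ok = np.isfinite(obs) & np.isfinite(nul)
            bf01 = np.nan
            if ok.sum() >= 3 and np.std(obs[ok] - nul[ok], ddof=1) > 0:
                bf01 = stats.bayes_paired_ttest_bf01(obs[ok], nul[ok],
                                                     prior_scale=analysis.prior_scale)
            elif ok.sum() < len(results):
                warnings.warn(f"shift {shift}: undefined ratios excluded "
                              f"({len(results) - int(ok.sum())} subject(s))")
            bf_rows.append({"shift_tr": int(shift), "bf01": bf01, "n": int(ok.sum())})
        bf_path = out / "bayes_factors.csv"
        pd.DataFrame(bf_rows).to_csv(bf_path, index=False)
        manifest.register("bayes_factors", bf_path)

    states_cfg = config.get("states")
    if states_cfg and states_cfg.get("enable", True):
        state_seed = int(np.random.default_rng(subject_seeds[-1]).integers(2**31))
        srows = []
        for K in states_cfg.get("k", [5]):
            series = [r["bold_frames"] for r in results]
            z, real, _ = st.dissociability_zscore(
                series, n_states=int(K),
                n_surrogates=int(states_cfg.get("n_surrogates",
                                                analysis.n_surrogate_states)),
                seed=state_seed)
            srows.append({"timescale": "slow", "k": int(K),
                          "dissociability": real, "z_vs_null": z})
        st_path = out / "state_dissociability.csv"
        pd.DataFrame(srows).to_csv(st_path, index=False)
        manifest.register("states", st_path)

    conf_rows = []
    for s_idx, res in enumerate(results):
        for name, d in res["confounds"].items():
            conf_rows.append({"subject": s_idx, "test": name, **d})
    if conf_rows:
        conf_path = out / "confounds.csv"
        pd.DataFrame(conf_rows).to_csv(conf_path, index=False)
        manifest.register("confounds", conf_path)

    manifest.write(out / "manifest.json")
    return manifest
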