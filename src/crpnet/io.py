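"""Readers and writers for region signals, frame series and CRP stacks.

Plain-text side: region x time CSV/TSV tables (regions as rows, header =
timestamps), whitespace/CSV motion tables, two-column region,network
membership tables.  Binary side: HDF5 bundles via h5py.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .crp import CRPStack
from .signals import CANONICAL_BANDS, EdgeFrameSeries, RegionSignalSet

__all__ = [
    "read_signals_csv", "write_signals_csv",
    "read_signals_hdf5", "write_signals_hdf5",
    "write_frames_hdf5", "read_frames_hdf5",
    "write_crp_hdf5", "read_crp_hdf5",
    "save_crp_heatmap",
    "read_motion_table", "read_membership_table",
    "write_simulation_bundle", "load_subject",
]


def read_signals_csv(path, fs: float, modality: str = "fast") -> RegionSignalSet:
    """Region x time table: one row per region, header row of timestamps."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return RegionSignalSet(df.to_numpy(dtype=float), fs=fs, modality=modality,
                           region_labels=[str(i) for i in df.index])


def write_signals_csv(signals: RegionSignalSet, path) -> None:
    df = pd.DataFrame(signals.values, index=signals.region_labels,
                      columns=np.round(signals.times, 6))
    df.to_csv(path)


def write_signals_hdf5(signals: RegionSignalSet, path, group: str = "/") -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for key in ("signals", "fs", "labels"):
            if key in g:
                del g[key]
        g.create_dataset("signals", data=signals.values, track_times=False)
        g.create_dataset("fs", data=signals.fs, track_times=False)
        g.create_dataset("labels", data=np.array(signals.region_labels, dtype="S"), track_times=False)
        g.attrs["modality"] = signals.modality
        if signals.band is not None:
            g.attrs["band"] = signals.band.name


def read_signals_hdf5(path, group: str = "/") -> RegionSignalSet:
    with h5py.File(path, "r") as f:
        g = f[group]
        band = CANONICAL_BANDS.get(g.attrs.get("band"))
        return RegionSignalSet(
            g["signals"][()], fs=float(g["fs"][()]),
            modality=str(g.attrs.get("modality", "fast")),
            region_labels=[s.decode() for s in g["labels"][()]],
            band=band,
        )


def write_frames_hdf5(frames: EdgeFrameSeries, path, group: str = "/") -> None:
    i_idx, j_idx = frames.edge_pairs
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for key in ("frames", "frame_times", "edge_i", "edge_j"):
            if key in g:
                del g[key]
        g.create_dataset("frames", data=frames.frames, track_times=False)
        g.create_dataset("frame_times", data=frames.frame_times, track_times=False)
        g.create_dataset("edge_i", data=i_idx, track_times=False)
        g.create_dataset("edge_j", data=j_idx, track_times=False)
        g.attrs.update({"tr": frames.tr, "coupling": frames.coupling,
                        "n_regions": frames.n_regions, "shifted": frames.shifted})
        if frames.band is not None:
            g.attrs["band"] = frames.band.name


def read_frames_hdf5(path, group: str = "/") -> EdgeFrameSeries:
    with h5py.File(path, "r") as f:
        g = f[group]
        return EdgeFrameSeries(
            g["frames"][()], tr=float(g.attrs["tr"]),
            coupling=str(g.attrs["coupling"]), n_regions=int(g.attrs["n_regions"]),
            band=CANONICAL_BANDS.get(g.attrs.get("band")),
            frame_times=g["frame_times"][()], shifted=bool(g.attrs["shifted"]),
        )


def write_crp_hdf5(stack: CRPStack, path, seed: Optional[int] = None,
                   lag: Optional[float] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("union", data=stack.union, track_times=False)
        for b, band in enumerate(stack.band_names):
            f.create_dataset(f"r/{band}", data=stack.r_values[:, :, b], track_times=False)
            f.create_dataset(f"p/{band}", data=stack.p_values[:, :, b], track_times=False)
            f.create_dataset(f"binary/{band}", data=stack.binary[:, :, b], track_times=False)
        f.attrs["bands"] = np.array(stack.band_names, dtype="S")
        f.attrs["q"] = stack.q
        f.attrs["n_perm"] = stack.n_perm
        if seed is not None:
            f.attrs["seed"] = seed
        if lag is not None:
            f.attrs["lag"] = lag


def read_crp_hdf5(path) -> CRPStack:
    with h5py.File(path, "r") as f:
        bands = [s.decode() for s in f.attrs["bands"]]
        r = np.stack([f[f"r/{b}"][()] for b in bands], axis=2)
        p = np.stack([f[f"p/{b}"][()] for b in bands], axis=2)
        binary = np.stack([f[f"binary/{b}"][()].astype(bool) for b in bands], axis=2)
        return CRPStack(bands, r, p, binary, f["union"][()].astype(bool),
                        q=float(f.attrs["q"]), n_perm=int(f.attrs["n_perm"]))


def save_crp_heatmap(stack: CRPStack, path, band: Optional[str] = None) -> None:
    """PNG heatmap of a CRP (real values with significant entries overlaid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = stack.band_names.index(band) if band else 0
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(stack.r_values[:, :, b], cmap="RdBu_r", vmin=-0.5, vmax=0.5,
                   origin="lower", aspect="auto")
    ys, xs = np.nonzero(stack.union if band is None else stack.binary[:, :, b])
    ax.plot(xs, ys, ".k", ms=1, alpha=0.4)
    ax.set_xlabel("electrophysiology frame")
    ax.set_ylabel("fMRI frame")
    fig.colorbar(im, ax=ax, label="spatial r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_motion_table(path) -> np.ndarray:
    """6-column motion-parameter table (whitespace or comma separated)."""
    arr = pd.read_csv(path, sep=None, engine="python", header=None).to_numpy(dtype=float)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, found {arr.shape[1]}")
    return arr


def read_membership_table(path) -> dict:
    """Two-column region,network CSV -> mapping."""
    df = pd.read_csv(path, header=None, names=["region", "network"])
    return dict(zip(df["region"].astype(str), df["network"].astype(str)))


def write_simulation_bundle(path, fast: RegionSignalSet, slow: RegionSignalSet,
                            truth, config) -> None:
    """HDF5 bundle: both signal sets, ground truth and a config echo."""
    path = Path(path)
    if path.exists():
        path.unlink()
    write_signals_hdf5(fast, path, group="fast")
    write_signals_hdf5(slow, path, group="slow")
    with h5py.File(path, "a") as f:
        g = f.create_group("ground_truth")
        g.create_dataset("state_library", data=truth.state_library, track_times=False)
        g.attrs["lag_applied"] = truth.lag_applied
        for ts, seq in truth.state_sequence_per_timescale.items():
            g.create_dataset(f"sequence/{ts}", data=seq, track_times=False)
        from dataclasses import asdict
        f.attrs["config"] = json.dumps(asdict(config), default=list)


def load_subject(fast_path, slow_path, fs_fast: float, tr: float,
                 motion_path=None, artifact_path=None):
    """Load one subject's bimodal bundle from CSV or HDF5 files.

    Returns ``(fast, slow, motion, artifact_mask)``; the last two are None
    when not provided.  Region label sets must agree between modalities.
    """
    def load(path, fs, modality):
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            s = read_signals_hdf5(path)
            if s.modality != modality:
                s = RegionSignalSet(s.values, fs=s.fs, modality=modality,
                                    region_labels=s.region_labels, band=s.band)
            return s
        return read_signals_csv(path, fs=fs, modality=modality)

    fast = load(fast_path, fs_fast, "fast")
    slow = load(slow_path, 1.0 / tr, "slow")
    if set(fast.region_labels) != set(slow.region_labels):
        raise ValueError("region labels differ between modalities")
    motion = read_motion_table(motion_path) if motion_path else None
    artifact = None
    if artifact_path:
        artifact = pd.read_csv(artifact_path, header=None).to_numpy().ravel().astype(bool)
    return fast, slow, motion, artifact
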