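"""Plain-text (TSV/YAML/JSON) and HDF5 readers/writers shared by the CLI."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .intervals import ClipSpec
from .synthetic import PowerDataset, grid_coordinates


def write_grid_tsv(path, coords: np.ndarray, region_labels=None, is_cerebellum=None) -> None:
    """Grid/atlas table: voxel_id, x_cm, y_cm, z_cm, region_label, is_cerebellum."""
    n = coords.shape[0]
    df = pd.DataFrame(
        {
            "voxel_id": np.arange(n),
            "x_cm": coords[:, 0],
            "y_cm": coords[:, 1],
            "z_cm": coords[:, 2],
            "region_label": region_labels if region_labels is not None else ["unlabeled"] * n,
            "is_cerebellum": np.asarray(
                is_cerebellum if is_cerebellum is not None else np.zeros(n, bool)
            ).astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_grid_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"voxel_id", "x_cm", "y_cm", "z_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"grid TSV missing columns: {sorted(missing)}")
    return df


def grid_coords_from_tsv(df: pd.DataFrame) -> np.ndarray:
    return df[["x_cm", "y_cm", "z_cm"]].to_numpy(float)


def read_clips_yaml(path) -> list:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ClipSpec(c["clip_id"], float(c["start"]), float(c["end"])) for c in raw["clips"]]


def write_clips_yaml(path, clips) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"clips": [{"clip_id": c.clip_id, "start": c.start, "end": c.end} for c in clips]},
            fh,
        )


def write_power_h5(path, datasets: dict) -> None:
    """``datasets`` maps a group name to a PowerDataset; layout
    /power/<group>[subject, condition, voxel] with condition order (BI, NBI)."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("power")
        for name, ds in datasets.items():
            d = grp.create_dataset(name, data=ds.power)
            d.attrs["grid_shape"] = np.asarray(ds.grid_shape)
            d.attrs["grid_spacing"] = ds.grid_spacing
            d.attrs["conditions"] = ",".join(PowerDataset.CONDITIONS)


def read_power_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        for name, d in fh["power"].items():
            out[name] = PowerDataset(
                d[...],
                tuple(int(v) for v in d.attrs["grid_shape"]),
                float(d.attrs["grid_spacing"]),
            )
    return out


def write_segments_h5(path, segments: np.ndarray, sampling_rate: float = 300.0,
                      leadfield: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("segments", data=segments)
        d.attrs["sampling_rate"] = sampling_rate
        if leadfield is not None:
            fh.create_dataset("leadfield", data=leadfield)


def read_segments_h5(path):
    with h5py.File(path, "r") as fh:
        segments = fh["segments"][...]
        rate = float(fh["segments"].attrs.get("sampling_rate", 300.0))
        leadfield = fh["leadfield"][...] if "leadfield" in fh else None
    return segments, rate, leadfield


def write_clusters_json(path, result, coords=None) -> None:
    """CBPT result as JSON: per cluster the voxel ids, sign, Tsum and p."""
    payload = {
        "n_perm": result.n_perm,
        "seed": result.seed,
        "alpha": result.alpha,
        "cluster_forming_alpha": result.cluster_forming_alpha,
        "clusters": [
            {
                "voxels": c.voxels.tolist(),
                "sign": int(c.sign),
                "t_sum": c.t_sum,
                "p": float(p),
            }
            for c, p in zip(result.clusters, result.p_values)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def default_grid_tsv(path, grid_shape=(10, 10, 10), grid_spacing=0.5, seed=0) -> None:
    """Convenience: a toy atlas over a regular grid with a handful of regions
    and a cerebellum block in the lowest z-slab."""
    coords = grid_coordinates(grid_shape, grid_spacing)
    rng = np.random.default_rng(seed)
    n_regions = 8
    centers = coords[rng.choice(len(coords), n_regions, replace=False)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    labels = [f"region_{i}" for i in d2.argmin(axis=1)]
    cere = coords[:, 2] < grid_spacing  # lowest slab
    write_grid_tsv(path, coords, labels, cere)
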