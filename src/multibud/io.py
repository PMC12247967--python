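"""File I/O: CSV tables, NPZ lattices, multi-page TIFF stacks, JSON metadata.

Schemas
-------
Bud-volume CSV columns: ``mother_id, mother_volume, bud_index, bud_volume,
label, maturity`` (volumes µm³).  Growth-series CSV columns: ``mother_id,
bud_index, time_min, volume``.  Lattices (concentration fields, actin
fields) round-trip through NPZ bit-for-bit; image stacks through
multi-page TIFF with one page per z-slice, frames stacked.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .budstats import BudVolumeTable, GrowthSeries
from .imaging import SegmentationMasks, TwoChannelStack

__all__ = [
    "write_bud_volume_csv",
    "read_bud_volume_csv",
    "write_growth_series_csv",
    "read_growth_series_csv",
    "save_field_npz",
    "load_field_npz",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_json",
]

BUD_VOLUME_COLUMNS = ["mother_id", "mother_volume", "bud_index", "bud_volume", "label", "maturity"]


def write_bud_volume_csv(table: BudVolumeTable, path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def read_bud_volume_csv(path) -> BudVolumeTable:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in BUD_VOLUME_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"bud-volume CSV missing required columns: {missing}")
    return BudVolumeTable.from_frame(df)


def write_growth_series_csv(series: GrowthSeries, path) -> Path:
    rows = []
    for mid, t, traj in zip(series.mother_ids, series.times, series.trajectories):
        for b, v in enumerate(np.atleast_2d(traj)):
            for tt, vv in zip(t, v):
                rows.append({"mother_id": mid, "bud_index": b, "time_min": tt, "volume": vv})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_growth_series_csv(path) -> GrowthSeries:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"mother_id", "bud_index", "time_min", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth-series CSV missing required columns: {sorted(missing)}")
    ids, times, trajs = [], [], []
    for mid, g in df.groupby("mother_id", sort=False):
        t = np.sort(g["time_min"].unique())
        buds = sorted(g["bud_index"].unique())
        traj = np.zeros((len(buds), len(t)))
        for i, b in enumerate(buds):
            gb = g[g["bud_index"] == b].sort_values("time_min")
            traj[i] = gb["volume"].to_numpy()
        ids.append(mid)
        times.append(t)
        trajs.append(traj)
    return GrowthSeries(mother_ids=tuple(ids), times=tuple(times), trajectories=tuple(trajs))


def save_field_npz(path, **arrays) -> Path:
    path = Path(path)
    np.savez_compressed(path, **arrays)
    return path


def load_field_npz(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def write_stack_tiff(stack: TwoChannelStack, masks: SegmentationMasks, directory) -> dict:
    """Write channels and masks as multi-page TIFFs; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, arr in (("cable", stack.cable), ("cytosol", stack.cytosol)):
        f = directory / f"{name}.tiff"
        tifffile.imwrite(f, arr.astype(np.float32))
        files[name] = f
    f = directory / "cell_mask.tiff"
    tifffile.imwrite(f, masks.cell_mask.astype(np.uint8))
    files["cell_mask"] = f
    for i, bm in enumerate(masks.bud_masks):
        f = directory / f"bud_mask_{i}.tiff"
        tifffile.imwrite(f, bm.astype(np.uint8))
        files[f"bud_mask_{i}"] = f
    meta = {
        "voxel_sizes": list(stack.voxel_sizes),
        "frame_interval": stack.frame_interval,
        "n_buds": masks.nbud,
    }
    write_json(meta, directory / "stack_meta.json")
    return files


def read_stack_tiff(directory) -> tuple[TwoChannelStack, SegmentationMasks]:
    directory = Path(directory)
    with open(directory / "stack_meta.json") as fh:
        meta = json.load(fh)
    cable = tifffile.imread(directory / "cable.tiff").astype(float)
    cytosol = tifffile.imread(directory / "cytosol.tiff").astype(float)
    cell = tifffile.imread(directory / "cell_mask.tiff").astype(bool)
    buds = tuple(
        tifffile.imread(directory / f"bud_mask_{i}.tiff").astype(bool)
        for i in range(meta["n_buds"])
    )
    stack = TwoChannelStack(
        cable=cable,
        cytosol=cytosol,
        voxel_sizes=tuple(meta["voxel_sizes"]),
        frame_interval=meta["frame_interval"],
    )
    return stack, SegmentationMasks(cell_mask=cell, bud_masks=buds)


def write_json(obj, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
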