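"""Reading and writing the pipeline's on-disk formats.

Masks travel as multi-page TIFF (uint8, 0/255), one file per cell, one
page per time point.  Tables are RFC-4180 CSV (UTF-8) whose first line
is a ``#``-prefixed header comment carrying units, the coordinate
convention and the configuration hash.  A ``manifest.yaml`` echoes the
full simulation / pipeline configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def config_to_dict(obj):
    """Recursively convert dataclass configs to plain YAML-able dicts."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: config_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): config_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [config_to_dict(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config) -> str:
    """Short stable hash of a configuration (recorded in every artifact)."""
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_mask_stack(path, masks: np.ndarray) -> None:
    """Write a (n, H, W) boolean stack as a multi-page uint8 0/255 TIFF."""
    tifffile.imwrite(str(path), (np.asarray(masks, dtype=bool)
                                 .astype(np.uint8) * 255))


def read_mask_stack(path) -> np.ndarray:
    """Read a multi-page TIFF into a (n, H, W) boolean stack."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr > 0


def write_csv(path, df: pd.DataFrame, comment: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_cell_tiff(outdir, cell, config) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{cell.cell_id}.tif"
    write_mask_stack(path, cell.masks)
    return path


def write_dataset_tables(outdir, dataset) -> None:
    """Write truth.csv, annotations.csv and manifest.yaml for a simulated
    dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    h = config_hash(cfg)
    truth = pd.concat([
        pd.DataFrame({"cell_id": c.cell_id,
                      "frame": np.arange(len(c.states)),
                      "state": c.states,
                      "x_um": c.track_um[:, 0], "y_um": c.track_um[:, 1]})
        for c in dataset.cells], ignore_index=True)
    write_csv(outdir / "truth.csv", truth,
              f"ground truth; x=column,y=row origin top-left, um; config={h}")
    ann = pd.concat([c.annotations.assign(cell_id=c.cell_id)
                     for c in dataset.cells], ignore_index=True)
    ann = ann[["cell_id", "frame", "contact", "dividing"]]
    write_csv(outdir / "annotations.csv", ann,
              f"per-frame annotation flags; config={h}")
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"config": config_to_dict(cfg), "config_hash": h}, fh)
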