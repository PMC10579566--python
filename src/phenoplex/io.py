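"""File-format plumbing: multi-page TIFF tiles (one page per channel,
channel order = panel order, 16-bit unsigned), CSV truth/result tables, and
YAML run manifests. Output tables carry explicit unit suffixes in their
column names (``_px`` vs ``_um``) to prevent geometry confusion."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .panels import PanelDefinition
from .simulate import MultichannelTile, TileGeometry

PathLike = Union[str, Path]


def write_tile_tiff(path: PathLike, tile: MultichannelTile) -> None:
    """Write a tile as multi-page uint16 TIFF (values clipped to range)."""
    data = np.clip(np.round(tile.stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_tile_tiff(
    path: PathLike,
    panel: PanelDefinition,
    geometry: Optional[TileGeometry] = None,
    tile_id: Optional[str] = None,
    case_type: str = "",
) -> MultichannelTile:
    """Read a multi-page TIFF tile; channel count must match the panel."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != panel.n_channels:
        raise ValueError(
            f"tile {Path(path).name!r}: {data.shape[0]} channels but panel "
            f"{panel.name!r} has {panel.n_channels}"
        )
    if geometry is None:
        geometry = TileGeometry(width_px=data.shape[2], height_px=data.shape[1])
    return MultichannelTile(
        stack=data.astype(np.float32),
        geometry=geometry,
        panel=panel,
        tile_id=tile_id or Path(path).stem,
        case_type=case_type,
    )


def write_truth_csv(path: PathLike, truth: pd.DataFrame) -> None:
    out = truth.copy()
    if "contact_neighbors" in out.columns:
        out["contact_neighbors"] = out["contact_neighbors"].map(
            lambda ns: ";".join(str(int(n)) for n in ns)
        )
    out.to_csv(path, index=False)


def read_truth_csv(path: PathLike) -> pd.DataFrame:
    truth = pd.read_csv(path)
    if "contact_neighbors" in truth.columns:
        truth["contact_neighbors"] = truth["contact_neighbors"].map(
            lambda s: [int(x) for x in str(s).split(";")] if pd.notna(s) and str(s) else []
        )
    return truth


def write_cells_csv(path: PathLike, cells: pd.DataFrame) -> None:
    out = cells.copy()
    if "labels" in out.columns:
        out["labels"] = out["labels"].map(lambda ls: ";".join(ls))
    out.to_csv(path, index=False)


def read_cells_csv(path: PathLike) -> pd.DataFrame:
    cells = pd.read_csv(path)
    if "labels" in cells.columns:
        cells["labels"] = cells["labels"].map(
            lambda s: str(s).split(";") if pd.notna(s) and str(s) else []
        )
    return cells


def write_manifest(path: PathLike, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
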