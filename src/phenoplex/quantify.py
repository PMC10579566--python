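"""Tile-level phenotype fractions, LP-cell identification and LP-to-phenotype
nearest-neighbour (LPNN) distances.

The sampling unit is the image tile: each phenotype's abundance is the
fraction of its parent population within one tile, and statistics are taken
over tiles. Neoplastic LP cells are identified morphologically: CD20
resolved-positive with a nucleus conspicuously larger than the tile's
typical nucleus.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .panels import PhenotypeDefinition, evaluate_phenotype_frame


def identify_lp_cells(
    cells: pd.DataFrame,
    alpha: float = 2.5,
    *,
    min_cells: int = 10,
    marker: str = "CD20",
) -> pd.DataFrame:
    """Flag LP cells: ``marker`` positive AND nucleus area >= alpha x the
    tile median nucleus area. Adds an ``is_lp_called`` column.

    Tiles with fewer than ``min_cells`` cells have an unstable median; the
    flag is still computed but a warning is emitted.
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    out = cells.copy()
    if out.empty:
        out["is_lp_called"] = pd.Series(dtype=bool)
        return out
    flags = np.zeros(len(out), dtype=bool)
    has_marker = marker in out.columns
    for tile, idx in out.groupby("tile_id").groups.items():
        areas = out.loc[idx, "nucleus_area_px"].to_numpy(dtype=float)
        if len(idx) < min_cells:
            warnings.warn(
                f"tile {tile!r} has {len(idx)} cells; LP size threshold "
                "is unstable",
                stacklevel=2,
            )
        med = np.median(areas)
        big = areas >= alpha * med
        pos = out.loc[idx, marker].to_numpy(dtype=bool) if has_marker else False
        flags[out.index.get_indexer(idx)] = big & pos
    out["is_lp_called"] = flags
    return out


def phenotype_fractions(
    cells: pd.DataFrame,
    phenotypes: Sequence[PhenotypeDefinition],
) -> pd.DataFrame:
    """Per-tile phenotype fractions relative to each phenotype's parent.

    One record per (tile, phenotype): counts of the phenotype and of its
    parent population, and their ratio (NaN when the parent is empty —
    the record is retained). A phenotype with an empty parent expression is
    reported over all segmented cells of the tile.
    """
    records = []
    for tile_id, grp in cells.groupby("tile_id", sort=True):
        case = grp["case_type"].iloc[0] if "case_type" in grp else ""
        for ph in phenotypes:
            in_parent = (
                evaluate_phenotype_frame(ph.parent_expression, grp)
                if ph.parent_expression
                else np.ones(len(grp), dtype=bool)
            )
            hit = evaluate_phenotype_frame(ph.expression, grp) & in_parent
            n_parent = int(in_parent.sum())
            n_ph = int(hit.sum())
            records.append(
                {
                    "tile_id": tile_id,
                    "case_type": case,
                    "phenotype": ph.display_name,
                    "parent": ph.parent_expression or "all cells",
                    "n_phenotype": n_ph,
                    "n_parent": n_parent,
                    "fraction": (n_ph / n_parent) if n_parent else np.nan,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "tile_id", "case_type", "phenotype", "parent",
            "n_phenotype", "n_parent", "fraction",
        ],
    )


def lp_nearest_neighbor(
    cells: pd.DataFrame,
    target_phenotype: str,
) -> pd.DataFrame:
    """Distance from each LP cell to the nearest (non-LP) cell bearing
    ``target_phenotype``, per tile, centroid-to-centroid in µm.

    Distance is NaN exactly when the tile contains no target cells.
    Requires ``identify_lp_cells`` to have been applied.
    """
    if "is_lp_called" not in cells.columns:
        raise ValueError("run identify_lp_cells first")
    records = []
    for tile_id, grp in cells.groupby("tile_id", sort=True):
        lp = grp[grp["is_lp_called"]]
        if lp.empty:
            continue
        is_target = grp["labels"].map(lambda ls: target_phenotype in ls)
        targets = grp[is_target & ~grp["is_lp_called"]]
        if targets.empty:
            dists = np.full(len(lp), np.nan)
        else:
            tree = cKDTree(targets[["x_um", "y_um"]].to_numpy())
            dists, _ = tree.query(lp[["x_um", "y_um"]].to_numpy())
        for cid, d in zip(lp["cell_id"], np.atleast_1d(dists)):
            records.append(
                {
                    "tile_id": tile_id,
                    "lp_cell_id": cid,
                    "target_phenotype": target_phenotype,
                    "nearest_distance_um": float(d),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["tile_id", "lp_cell_id", "target_phenotype", "nearest_distance_um"],
    )


def histogram_density(
    distances: Sequence[float],
    bin_width_um: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density of a distance sample (integrates to 1 over the
    observed range). Returns (bin_edges, density); empty input gives empty
    arrays."""
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    d = np.asarray([x for x in distances if np.isfinite(x)], dtype=float)
    if d.size == 0:
        return np.array([]), np.array([])
    top = max(bin_width_um, np.ceil(d.max() / bin_width_um) * bin_width_um)
    edges = np.arange(0.0, top + bin_width_um / 2, bin_width_um)
    density, edges = np.histogram(d, bins=edges, density=True)
    return edges, density
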