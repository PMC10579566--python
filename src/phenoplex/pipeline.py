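"""End-to-end per-tile pipeline: dynamic thresholding -> nuclear detection
-> cell expansion -> marker calling -> double-positive resolution ->
phenotype assignment -> LP flagging."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .panels import PanelDefinition, PhenotypeDefinition
from .phenotype import (
    DEFAULT_F_MIN,
    assign_phenotypes,
    call_markers,
    resolve_double_positives,
)
from .quantify import identify_lp_cells
from .segment import detect_nuclei, expand_to_cells
from .simulate import MultichannelTile
from .threshold import dynamic_threshold


@dataclass
class PipelineConfig:
    """Tunable parameters of the phenotyping pipeline (defaults as used
    throughout the validation battery)."""

    k_marker: float = 6.0
    k_counterstain: float = 4.0
    k_per_marker: dict = field(default_factory=dict)
    f_min: dict = field(default_factory=lambda: dict(DEFAULT_F_MIN))
    min_nucleus_area_px: int = 30
    seed_split: bool = True
    expansion_um: float = 3.0
    ring_px: int = 2
    sectors: int = 12
    c_min: float = 0.5
    tau: float = 0.5
    ambiguous_policy: str = "revoke"
    lp_alpha: float = 2.5
    significance_level: float = 0.001


@dataclass
class TileResult:
    cells: pd.DataFrame
    calls: pd.DataFrame
    seg: object
    threshold_log: pd.DataFrame


def run_tile(
    tile: MultichannelTile,
    phenotypes: Sequence[PhenotypeDefinition],
    config: Optional[PipelineConfig] = None,
) -> TileResult:
    """Run the full phenotyping pipeline on one multichannel tile."""
    cfg = config or PipelineConfig()
    panel = tile.panel
    cs = panel.counterstain
    nuclei = detect_nuclei(
        tile.stack[cs.channel_index],
        min_nucleus_area_px=cfg.min_nucleus_area_px,
        seed_split=cfg.seed_split,
        k=cfg.k_counterstain,
    )
    seg = expand_to_cells(
        nuclei, expansion_um=cfg.expansion_um, geometry=tile.geometry,
        ring_px=cfg.ring_px,
    )
    masks = {}
    log_rows = []
    for m in panel.markers:
        if m.is_counterstain:
            continue
        k = cfg.k_per_marker.get(m.name, cfg.k_marker)
        th = dynamic_threshold(tile.stack[m.channel_index], k=k)
        masks[m.name] = th.mask
        log_rows.append(
            {
                "tile_id": tile.tile_id,
                "channel": m.name,
                "threshold_value": th.threshold_value,
                "background_median": th.background_median,
                "background_mad": th.background_mad,
                "k": th.k_used,
                "degenerate": th.degenerate,
            }
        )
    calls = call_markers(seg, masks, panel, f_min=cfg.f_min)
    calls = resolve_double_positives(
        seg, calls, masks, panel,
        sectors=cfg.sectors, c_min=cfg.c_min, tau=cfg.tau,
        ambiguous_policy=cfg.ambiguous_policy,
    )
    cells = assign_phenotypes(
        calls, list(phenotypes), panel, seg, tile.geometry,
        tile_id=tile.tile_id, case_type=tile.case_type,
    )
    return TileResult(
        cells=cells, calls=calls, seg=seg,
        threshold_log=pd.DataFrame(log_rows),
    )


def run_tiles(
    tiles: Iterable[MultichannelTile],
    phenotypes: Sequence[PhenotypeDefinition],
    config: Optional[PipelineConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pipeline over tiles (any iterable, consumed lazily);
    returns (cells, threshold log) with LP flags attached across the whole
    cell table."""
    cfg = config or PipelineConfig()
    cell_frames, logs = [], []
    for tile in tiles:
        res = run_tile(tile, phenotypes, cfg)
        cell_frames.append(res.cells)
        logs.append(res.threshold_log)
    cells = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else pd.DataFrame()
    )
    if len(cells):
        cells = identify_lp_cells(cells, alpha=cfg.lp_alpha)
    log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()
    return cells, log
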