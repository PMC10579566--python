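"""Synthetic multichannel tile generator with per-cell ground truth.

Emulates multiplexed immunofluorescence tiles of lymphoid tissue: crowded
fields of round cells (nucleus disc + cytoplasm + membrane ring), sparse
large CD20+ neoplastic LP cells, B-cell nodules, per-tile background/gain
drift, Poisson photon noise, and signal spillover between touching cell
membranes. Every rendered cell is recorded in a ground-truth table (position,
radii, true binary marker states, LP flag, contact neighbours) so the whole
downstream pipeline can be scored against truth.

All generation is a pure function of (preset, geometry, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .panels import CASE_TYPES, CaseTypePreset, PanelDefinition

# every marker the generator knows about, across all three panels
ALL_MARKERS = (
    "CD20", "CD4", "CD8", "PD1", "FOXP3",
    "CD16", "CD56", "NKG2A", "GZMB", "GNLY",
    "CD68", "CD163", "CD206", "PDL1",
)

TRUTH_COLUMNS = (
    "cell_id", "x_px", "y_px", "nucleus_radius_um", "cell_radius_um",
    "lineage", "is_lp",
) + ALL_MARKERS + ("contact_neighbors",)


@dataclass(frozen=True)
class TileGeometry:
    """Raster geometry of one tile (defaults: 1348x1008 px, 670x501 µm)."""

    width_px: int = 1348
    height_px: int = 1008
    microns_per_px: float = 670.0 / 1348.0

    def __post_init__(self):
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("tile must be at least 64x64 px")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")

    @property
    def width_um(self) -> float:
        return self.width_px * self.microns_per_px

    @property
    def height_um(self) -> float:
        return self.height_px * self.microns_per_px

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


@dataclass
class TechnicalVariation:
    """Per-tile affine intensity drift and noise parameters."""

    gain: float = 1.0
    offset: float = 0.0
    noise_read_sd: float = 2.0
    photon_scale: float = 1.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass
class MultichannelTile:
    """Channel stack (channels x height x width) plus geometry metadata."""

    stack: np.ndarray
    geometry: TileGeometry
    panel: PanelDefinition
    tile_id: str = "tile"
    case_type: str = ""

    def __post_init__(self):
        if self.stack.ndim != 3:
            raise ValueError("stack must be (channels, height, width)")
        if self.stack.shape[0] != self.panel.n_channels:
            raise ValueError(
                f"channel count {self.stack.shape[0]} does not match panel "
                f"{self.panel.name!r} ({self.panel.n_channels} channels)"
            )
        if not np.all(np.isfinite(self.stack)) or self.stack.min() < 0:
            raise ValueError("intensities must be finite and >= 0")

    def channel(self, marker: str) -> np.ndarray:
        return self.stack[self.panel.channel_of(marker)]


# --------------------------------------------------------------------------
# case-type presets (composition parameters; conditional proportions are
# parent-relative, mirroring how published medians are tabulated)
# --------------------------------------------------------------------------

# (b_cell_fraction, nodularity, lp_density per mm²,
#  lineage fractions of CD20- cells: CD4+, CD8+, NK, macrophage,
#  parent-relative phenotype proportions)
_PRESET_TABLE: dict[str, dict] = {
    "tonsil": dict(
        b=0.55, nod=0.70, lp=0.0,
        lineage={"CD4+": 0.60, "CD8+": 0.15, "NK-cell": 0.05, "Macrophage": 0.10},
        props={
            "CD4+FOXP3+": 0.038, "CD4+PD1+": 0.034, "CD8+PD1+": 0.004,
            "CD4+CD8+PD1+": 0.000,
            "CD56+NKG2A+": 0.49, "CD16+GZMB+": 0.086,
            "CD8+NKG2A+": 0.006, "CD8+CD16+": 0.000, "CD8+GZMB+": 0.011,
            "CD163+": 0.49, "CD163+PDL1+": 0.003, "CD68+": 0.63,
        },
    ),
    "NLPHL-pA": dict(
        b=0.50, nod=0.80, lp=30.0,
        lineage={"CD4+": 0.60, "CD8+": 0.20, "NK-cell": 0.04, "Macrophage": 0.08},
        props={
            "CD4+FOXP3+": 0.008, "CD4+PD1+": 0.11, "CD8+PD1+": 0.026,
            "CD4+CD8+PD1+": 0.0002,
            "CD56+NKG2A+": 0.46, "CD16+GZMB+": 0.16,
            "CD8+NKG2A+": 0.012, "CD8+CD16+": 0.000, "CD8+GZMB+": 0.016,
            "CD163+": 0.42, "CD163+PDL1+": 0.01, "CD68+": 0.68,
        },
    ),
    "NLPHL-pC": dict(
        b=0.35, nod=0.50, lp=40.0,
        lineage={"CD4+": 0.50, "CD8+": 0.25, "NK-cell": 0.06, "Macrophage": 0.10},
        props={
            "CD4+FOXP3+": 0.006, "CD4+PD1+": 0.12, "CD8+PD1+": 0.020,
            "CD4+CD8+PD1+": 0.0001,
            "CD56+NKG2A+": 0.39, "CD16+GZMB+": 0.36,
            "CD8+NKG2A+": 0.014, "CD8+CD16+": 0.003, "CD8+GZMB+": 0.024,
            "CD163+": 0.62, "CD163+PDL1+": 0.06, "CD68+": 0.49,
        },
    ),
    "NLPHL-pE": dict(
        b=0.15, nod=0.20, lp=50.0,
        lineage={"CD4+": 0.45, "CD8+": 0.30, "NK-cell": 0.05, "Macrophage": 0.12},
        props={
            "CD4+FOXP3+": 0.004, "CD4+PD1+": 0.060, "CD8+PD1+": 0.075,
            "CD4+CD8+PD1+": 0.0005,
            "CD56+NKG2A+": 0.093, "CD16+GZMB+": 0.64,
            "CD8+NKG2A+": 0.010, "CD8+CD16+": 0.011, "CD8+GZMB+": 0.090,
            "CD163+": 0.73, "CD163+PDL1+": 0.11, "CD68+": 0.40,
        },
    ),
    "THRLBCL": dict(
        b=0.10, nod=0.05, lp=50.0,
        lineage={"CD4+": 0.40, "CD8+": 0.30, "NK-cell": 0.05, "Macrophage": 0.18},
        props={
            "CD4+FOXP3+": 0.004, "CD4+PD1+": 0.13, "CD8+PD1+": 0.12,
            "CD4+CD8+PD1+": 0.004,
            "CD56+NKG2A+": 0.008, "CD16+GZMB+": 0.61,
            "CD8+NKG2A+": 0.002, "CD8+CD16+": 0.040, "CD8+GZMB+": 0.11,
            "CD163+": 0.82, "CD163+PDL1+": 0.24, "CD68+": 0.42,
        },
    ),
    "LRcHL": dict(
        b=0.30, nod=0.40, lp=0.0,
        lineage={"CD4+": 0.55, "CD8+": 0.20, "NK-cell": 0.04, "Macrophage": 0.12},
        props={
            "CD4+FOXP3+": 0.060, "CD4+PD1+": 0.074, "CD8+PD1+": 0.025,
            "CD4+CD8+PD1+": 0.0007,
            "CD56+NKG2A+": 0.00, "CD16+GZMB+": 0.11,
            "CD8+NKG2A+": 0.001, "CD8+CD16+": 0.000, "CD8+GZMB+": 0.025,
            "CD163+": 0.26, "CD163+PDL1+": 0.01, "CD68+": 0.84,
        },
    ),
}

# default analysed-tile counts per (case type, panel)
TILE_COUNTS: dict[tuple[str, str], int] = {
    ("tonsil", "lymphocyte"): 15,
    ("tonsil", "cytotoxic_nk"): 55,
    ("tonsil", "macrophage"): 62,
    ("NLPHL-pA", "lymphocyte"): 160,
    ("NLPHL-pA", "cytotoxic_nk"): 285,
    ("NLPHL-pA", "macrophage"): 174,
    ("NLPHL-pC", "lymphocyte"): 58,
    ("NLPHL-pC", "cytotoxic_nk"): 89,
    ("NLPHL-pC", "macrophage"): 98,
    ("NLPHL-pE", "lymphocyte"): 219,
    ("NLPHL-pE", "cytotoxic_nk"): 181,
    ("NLPHL-pE", "macrophage"): 278,
    ("THRLBCL", "lymphocyte"): 187,
    ("THRLBCL", "cytotoxic_nk"): 95,
    ("THRLBCL", "macrophage"): 152,
    ("LRcHL", "lymphocyte"): 302,
    ("LRcHL", "cytotoxic_nk"): 313,
    ("LRcHL", "macrophage"): 288,
}


def build_preset(case_type: str, **overrides) -> CaseTypePreset:
    """Composition preset for a case type; any proportion is overridable.

    Keyword overrides: ``b_cell_fraction``, ``lp_density``, ``nodularity``,
    or any phenotype-proportion key (e.g. ``**{"CD16+GZMB+": 0.5}``).
    """
    if case_type not in _PRESET_TABLE:
        raise ValueError(
            f"unknown case type {case_type!r}; valid types: {list(CASE_TYPES)}"
        )
    raw = _PRESET_TABLE[case_type]
    props = dict(raw["lineage"])
    props.update(raw["props"])
    kwargs = dict(
        b_cell_fraction=raw["b"], nodularity=raw["nod"], lp_density=raw["lp"],
    )
    for key, val in overrides.items():
        if key in kwargs:
            kwargs[key] = float(val)
        elif key in props:
            props[key] = float(val)
        else:
            raise ValueError(f"unknown preset override {key!r}")
    return CaseTypePreset(
        case_type=case_type, phenotype_proportions=props, **kwargs
    )


# --------------------------------------------------------------------------
# marker-state sampling (hierarchical: lineage class, then conditional
# activation markers, so parent-relative proportions hold in expectation)
# --------------------------------------------------------------------------

_LINEAGES = ("B", "DPT", "CD4T", "CD8T", "NK", "MAC", "other")


def sample_cell_states(
    preset: CaseTypePreset, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw lineages and binary marker states for ``n`` non-LP cells."""
    props = preset.phenotype_proportions
    b = preset.b_cell_fraction
    p_dpt = props.get("CD4+CD8+PD1+", 0.0)
    p_cd4 = props.get("CD4+", 0.0)
    p_cd8 = props.get("CD8+", 0.0)
    p_nk = props.get("NK-cell", 0.0)
    p_mac = props.get("Macrophage", 0.0)
    nonb = np.array([p_dpt, p_cd4, p_cd8, p_nk, p_mac])
    if nonb.sum() > 1.0 + 1e-9:
        raise ValueError("non-B lineage fractions sum to more than 1")
    probs = np.concatenate(([b], (1.0 - b) * nonb, [(1.0 - b) * (1.0 - nonb.sum())]))
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    lineage_idx = rng.choice(len(_LINEAGES), size=n, p=probs)
    lineage = np.array(_LINEAGES)[lineage_idx]

    states = {m: np.zeros(n, dtype=bool) for m in ALL_MARKERS}
    is_b = lineage == "B"
    states["CD20"][is_b] = True

    def cond(parent_key: str, joint_key: str) -> float:
        parent = props.get(parent_key, 0.0)
        if parent <= 0:
            return 0.0
        return min(1.0, props.get(joint_key, 0.0) / parent)

    # CD4+ T cells: FOXP3 and PD1 drawn independently at conditional rates
    cd4 = lineage == "CD4T"
    n4 = int(cd4.sum())
    states["CD4"][cd4] = True
    states["FOXP3"][cd4] = rng.random(n4) < cond("CD4+", "CD4+FOXP3+")
    states["PD1"][cd4] = rng.random(n4) < cond("CD4+", "CD4+PD1+")

    # CD8+ T cells: PD1 (lymphocyte panel) and NKG2A/CD16/GZMB (cytotoxic
    # panel) drawn independently at conditional rates
    cd8 = lineage == "CD8T"
    n8 = int(cd8.sum())
    states["CD8"][cd8] = True
    states["PD1"][cd8] = rng.random(n8) < cond("CD8+", "CD8+PD1+")
    states["NKG2A"][cd8] = rng.random(n8) < cond("CD8+", "CD8+NKG2A+")
    states["CD16"][cd8] = rng.random(n8) < cond("CD8+", "CD8+CD16+")
    states["GZMB"][cd8] = rng.random(n8) < cond("CD8+", "CD8+GZMB+")

    # genuine double-positive T cells
    dpt = lineage == "DPT"
    states["CD4"][dpt] = True
    states["CD8"][dpt] = True
    states["PD1"][dpt] = True

    # NK cells: CD56+NKG2A+ subset, CD16+GZMB+ subset, remainder CD56+GNLY+
    nk = lineage == "NK"
    nnk = int(nk.sum())
    p1 = props.get("CD56+NKG2A+", 0.0)
    p2 = props.get("CD16+GZMB+", 0.0)
    if p1 + p2 > 1.0 + 1e-9:
        raise ValueError("NK subset proportions sum to more than 1")
    sub = rng.choice(3, size=nnk, p=[p1, p2, max(0.0, 1.0 - p1 - p2)])
    idx = np.flatnonzero(nk)
    states["CD56"][idx[sub == 0]] = True
    states["NKG2A"][idx[sub == 0]] = True
    states["CD16"][idx[sub == 1]] = True
    states["GZMB"][idx[sub == 1]] = True
    states["CD56"][idx[sub == 2]] = True
    states["GNLY"][idx[sub == 2]] = True

    # macrophages: CD163 / CD68 with union 1 among detections, PDL1 on CD163+
    mac = lineage == "MAC"
    nm = int(mac.sum())
    p163 = props.get("CD163+", 0.0)
    p68 = props.get("CD68+", 0.0)
    both = max(0.0, p163 + p68 - 1.0)
    has163 = rng.random(nm) < p163
    has68 = np.where(
        has163,
        rng.random(nm) < (both / p163 if p163 > 0 else 0.0),
        True,
    )
    midx = np.flatnonzero(mac)
    states["CD163"][midx[has163]] = True
    states["CD68"][midx[has68]] = True
    pdl1_rate = cond("CD163+", "CD163+PDL1+")
    on163 = midx[has163]
    states["PDL1"][on163[rng.random(on163.size) < pdl1_rate]] = True
    states["CD206"][midx[rng.random(nm) < 0.005]] = True

    out = pd.DataFrame({"lineage": lineage})
    for m in ALL_MARKERS:
        out[m] = states[m]
    return out


# --------------------------------------------------------------------------
# cell placement
# --------------------------------------------------------------------------

class PlacementError(RuntimeError):
    """Requested density could not be realised within bounded attempts."""


def place_cells(
    preset: CaseTypePreset,
    geometry: TileGeometry = TileGeometry(),
    seed: Optional[int] = None,
    *,
    n_cells: Optional[int] = None,
    cells_per_mm2: float = 2000.0,
    contact_fraction: float = 0.4,
    nucleus_radius_um: tuple[float, float] = (2.5, 4.5),
    lp_nucleus_radius_um: tuple[float, float] = (7.0, 11.0),
    cyto_width_um: float = 2.5,
    nodule_radius_um: float = 80.0,
    max_attempts: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Place cells by dart-throwing and sample their true marker states.

    Cells are hard discs (nucleus radius + ``cyto_width_um``). A fraction
    ``contact_fraction`` of placements is anchored against an existing cell
    so that membranes touch (centre distance 0.92 x radius sum), producing
    the membrane interfaces that drive signal spillover. B cells are drawn
    towards nodule centres with probability ``nodularity``. LP cells are
    placed first with nucleus radii from ``lp_nucleus_radius_um``.

    Returns the ground-truth table (one row per cell). Raises
    ``PlacementError`` when the density is infeasible for the geometry.
    """
    if rng is None:
        if seed is None:
            raise ValueError("an explicit seed (or rng) is required")
        rng = np.random.default_rng(seed)
    mpp = geometry.microns_per_px
    if n_cells is None:
        n_cells = int(round(cells_per_mm2 * geometry.area_mm2))
    if n_cells == 0:
        return pd.DataFrame(columns=list(TRUTH_COLUMNS))

    n_lp = min(n_cells, int(round(preset.lp_density * geometry.area_mm2)))
    n_std = n_cells - n_lp
    states = sample_cell_states(preset, n_std, rng)

    nuc_r = np.empty(n_cells)
    nuc_r[:n_lp] = rng.uniform(*lp_nucleus_radius_um, size=n_lp)
    nuc_r[n_lp:] = rng.uniform(*nucleus_radius_um, size=n_std)
    cell_r = nuc_r + cyto_width_um
    R_px = cell_r / mpp
    r_max = R_px.max()

    W, H = geometry.width_px, geometry.height_px
    n_nodules = max(1, int(round(3.0 * geometry.area_mm2)) + 1)
    nodule_centers = rng.uniform([0, 0], [W, H], size=(n_nodules, 2))
    nod_sigma_px = nodule_radius_um / mpp / 2.0

    lineages = np.concatenate(
        (np.array(["LP"] * n_lp), states["lineage"].to_numpy())
    )
    is_b_like = lineages == "B"

    # spatial hash grid for collision queries
    cell_size = 2.0 * r_max + 1.0
    grid: dict[tuple[int, int], list[int]] = {}
    xs = np.empty(n_cells)
    ys = np.empty(n_cells)
    nodule_members: list[int] = []

    def neighbors_of(px, py):
        gx, gy = int(px // cell_size), int(py // cell_size)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                yield from grid.get((gx + dx, gy + dy), ())

    placed = 0
    for i in range(n_cells):
        Ri = R_px[i]
        ok = False
        for attempt in range(max_attempts):
            contact = placed > 0 and rng.random() < contact_fraction
            if contact:
                if is_b_like[i] and nodule_members and rng.random() < preset.nodularity:
                    j = nodule_members[int(rng.integers(len(nodule_members)))]
                else:
                    j = int(rng.integers(placed))
                theta = rng.uniform(0, 2 * np.pi)
                d = 0.92 * (Ri + R_px[j])
                px = xs[j] + d * math.cos(theta)
                py = ys[j] + d * math.sin(theta)
                if not (Ri <= px <= W - 1 - Ri and Ri <= py <= H - 1 - Ri):
                    continue
                min_gap = 0.92
            elif is_b_like[i] and rng.random() < preset.nodularity:
                c = nodule_centers[int(rng.integers(n_nodules))]
                px = float(np.clip(c[0] + rng.normal(0, nod_sigma_px), Ri, W - 1 - Ri))
                py = float(np.clip(c[1] + rng.normal(0, nod_sigma_px), Ri, H - 1 - Ri))
                min_gap = 1.05
            else:
                px = rng.uniform(Ri, W - 1 - Ri)
                py = rng.uniform(Ri, H - 1 - Ri)
                min_gap = 1.05
            collision = False
            for k in neighbors_of(px, py):
                dk = math.hypot(px - xs[k], py - ys[k])
                if dk < min_gap * (Ri + R_px[k]) - 1e-9:
                    if contact and k == j and dk >= 0.92 * (Ri + R_px[k]) - 1e-6:
                        continue
                    collision = True
                    break
            if not collision:
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place cell {i} of {n_cells} after {max_attempts} "
                "attempts; density infeasible for this geometry"
            )
        xs[i], ys[i] = px, py
        grid.setdefault((int(px // cell_size), int(py // cell_size)), []).append(i)
        if is_b_like[i]:
            nodule_members.append(i)
        placed += 1

    # contact map: membranes touch when centre distance <= radius sum
    tree = cKDTree(np.column_stack((xs, ys)))
    pairs = tree.query_pairs(r=2.0 * r_max + 1.0, output_type="ndarray")
    contacts: list[list[int]] = [[] for _ in range(n_cells)]
    if pairs.size:
        d = np.hypot(xs[pairs[:, 0]] - xs[pairs[:, 1]], ys[pairs[:, 0]] - ys[pairs[:, 1]])
        touching = d <= R_px[pairs[:, 0]] + R_px[pairs[:, 1]] + 1e-6
        for a, b_ in pairs[touching]:
            contacts[a].append(int(b_))
            contacts[b_].append(int(a))

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x_px": xs,
            "y_px": ys,
            "nucleus_radius_um": nuc_r,
            "cell_radius_um": cell_r,
            "lineage": lineages,
            "is_lp": np.arange(n_cells) < n_lp,
        }
    )
    for m in ALL_MARKERS:
        col = np.zeros(n_cells, dtype=bool)
        col[n_lp:] = states[m].to_numpy()
        truth[m] = col
    truth.loc[truth["is_lp"], "CD20"] = True  # LP cells are CD20-true
    truth["contact_neighbors"] = [sorted(c) for c in contacts]
    return truth


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _paint(img, cx, cy, r_out, value, r_in=0.0, clip_center=None, clip_r=None):
    """Add ``value`` to an annulus (r_in..r_out) around (cx, cy); optionally
    restricted to within ``clip_r`` of ``clip_center`` (spillover arcs)."""
    H, W = img.shape
    x0 = max(0, int(math.floor(cx - r_out - 1)))
    x1 = min(W, int(math.ceil(cx + r_out + 2)))
    y0 = max(0, int(math.floor(cy - r_out - 1)))
    y1 = min(H, int(math.ceil(cy + r_out + 2)))
    if x0 >= x1 or y0 >= y1:
        return
    yy = np.arange(y0, y1, dtype=np.float32)[:, None] - cy
    xx = np.arange(x0, x1, dtype=np.float32)[None, :] - cx
    d2 = xx * xx + yy * yy
    mask = d2 <= r_out * r_out
    if r_in > 0:
        mask &= d2 >= r_in * r_in
    if clip_center is not None:
        ex, ey = clip_center
        d2c = (np.arange(x0, x1, dtype=np.float32)[None, :] - ex) ** 2 + (
            np.arange(y0, y1, dtype=np.float32)[:, None] - ey
        ) ** 2
        mask &= d2c <= clip_r * clip_r
    img[y0:y1, x0:x1][mask] += value


def _ideal_channel(
    truth: pd.DataFrame,
    marker: str,
    localization: str,
    is_counterstain: bool,
    geometry: TileGeometry,
    *,
    signal_amplitude: float,
    ring_width_px: float,
    spillover_beta: float,
    interface_margin_px: float = 0.5,
) -> np.ndarray:
    """Noise-free photon image of one channel (marker compartments plus
    membrane-interface spillover for membranous markers)."""
    img = np.zeros((geometry.height_px, geometry.width_px), dtype=np.float32)
    if len(truth) == 0:
        return img
    mpp = geometry.microns_per_px
    xs = truth["x_px"].to_numpy()
    ys = truth["y_px"].to_numpy()
    rn = truth["nucleus_radius_um"].to_numpy() / mpp
    rc = truth["cell_radius_um"].to_numpy() / mpp
    pos = (
        np.ones(len(truth), dtype=bool)
        if is_counterstain
        else truth[marker].to_numpy(dtype=bool)
    )
    if localization == "nuclear":
        for i in np.flatnonzero(pos):
            _paint(img, xs[i], ys[i], rn[i], signal_amplitude)
    elif localization == "cytoplasmic":
        for i in np.flatnonzero(pos):
            _paint(img, xs[i], ys[i], rc[i], signal_amplitude, r_in=rn[i])
    elif localization == "membranous":
        for i in np.flatnonzero(pos):
            _paint(
                img, xs[i], ys[i], rc[i], signal_amplitude,
                r_in=max(0.0, rc[i] - ring_width_px),
            )
        if spillover_beta > 0:
            neighbors = truth["contact_neighbors"].to_numpy()
            id_to_row = {int(c): k for k, c in enumerate(truth["cell_id"])}
            for i in range(len(truth)):
                for nb in neighbors[i]:
                    k = id_to_row.get(int(nb))
                    if k is None or not pos[k]:
                        continue
                    # arc of cell i's ring abutting positive neighbour k
                    _paint(
                        img, xs[i], ys[i], rc[i],
                        spillover_beta * signal_amplitude,
                        r_in=max(0.0, rc[i] - ring_width_px),
                        clip_center=(xs[k], ys[k]),
                        clip_r=rc[k] + interface_margin_px,
                    )
    return img


def truth_marker_mask(
    truth: pd.DataFrame,
    marker: str,
    localization: str,
    geometry: TileGeometry,
    *,
    ring_width_px: float = 2.0,
) -> np.ndarray:
    """Boolean raster of where a marker's true (pre-noise, pre-spillover)
    signal lives; the oracle for threshold-mask overlap tests."""
    img = _ideal_channel(
        truth, marker, localization, marker == "DAPI", geometry,
        signal_amplitude=1.0, ring_width_px=ring_width_px, spillover_beta=0.0,
    )
    return img > 0


def render_tile(
    truth: pd.DataFrame,
    panel: PanelDefinition,
    geometry: TileGeometry = TileGeometry(),
    variation: Optional[TechnicalVariation] = None,
    spillover_beta: float = 0.3,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    blur_sigma_px: float = 0.7,
    signal_amplitude: float = 100.0,
    ambient: float = 10.0,
    ring_width_px: float = 2.0,
    noise: bool = True,
    tile_id: str = "tile",
    case_type: str = "",
) -> MultichannelTile:
    """Render a ground-truth table into a multichannel intensity stack.

    Nuclear markers fill the nucleus disc, membranous markers a ring of
    ``ring_width_px`` just inside the cell boundary, cytoplasmic markers the
    cell-minus-nucleus annulus. The ideal image is blurred (PSF), Poisson
    photon noise and Gaussian read noise are added, then the per-tile affine
    drift ``x -> gain*x + offset`` is applied.
    """
    if not (0.0 <= spillover_beta < 1.0):
        raise ValueError("spillover_beta must be in [0, 1)")
    if variation is None:
        variation = TechnicalVariation()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    planes = []
    for m in panel.markers:
        ideal = _ideal_channel(
            truth, m.name, m.localization, m.is_counterstain, geometry,
            signal_amplitude=signal_amplitude, ring_width_px=ring_width_px,
            spillover_beta=spillover_beta,
        )
        if blur_sigma_px > 0:
            ideal = ndi.gaussian_filter(ideal, sigma=blur_sigma_px)
        ideal += ambient  # expected photons
        if noise:
            if variation.photon_scale != 1.0:
                ideal *= variation.photon_scale
            signal = _poisson_field(
                ideal, variation.photon_scale * ambient, rng
            ).astype(np.float32)
            if variation.photon_scale != 1.0:
                signal /= variation.photon_scale
            signal += variation.noise_read_sd * rng.standard_normal(
                signal.shape, dtype=np.float32
            )
        else:
            signal = ideal
        signal *= variation.gain
        signal += variation.offset
        np.clip(signal, 0.0, None, out=signal)
        planes.append(signal)
    return MultichannelTile(
        stack=np.stack(planes), geometry=geometry, panel=panel,
        tile_id=tile_id, case_type=case_type,
    )


def _poisson_field(
    lam: np.ndarray, base_lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson sample of a rate field that is constant (= ``base_lam``)
    over most pixels: constant-rate pixels are drawn by inverse-CDF lookup
    (exact, and much faster than per-pixel rejection sampling), the rest
    with the generator's Poisson sampler."""
    flat = lam.ravel()
    const = flat == base_lam
    out = np.empty(flat.shape, dtype=np.int64)
    n_const = int(const.sum())
    if n_const:
        from scipy import stats as sps

        k_max = int(base_lam + 12.0 * math.sqrt(base_lam + 1.0) + 20.0)
        cdf = sps.poisson.cdf(np.arange(k_max), base_lam)
        out[const] = np.searchsorted(cdf, rng.random(n_const))
    if n_const < flat.size:
        out[~const] = rng.poisson(flat[~const])
    return out.reshape(lam.shape)


def sample_variation(rng: np.random.Generator) -> TechnicalVariation:
    """Per-tile technical drift: gain log-uniform in [0.5, 2], offset
    uniform in [50, 300] (arbitrary units) — wide enough that no fixed
    global threshold works across tiles."""
    gain = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    offset = float(rng.uniform(50.0, 300.0))
    return TechnicalVariation(gain=gain, offset=offset)


def iter_case_set(
    case_type: str,
    panel: PanelDefinition,
    n_tiles: Optional[int] = None,
    seed: int = 0,
    geometry: TileGeometry = TileGeometry(),
    *,
    preset: Optional[CaseTypePreset] = None,
    preset_overrides: Optional[dict] = None,
    spillover_beta: float = 0.3,
    vary_technical: bool = True,
    place_kwargs: Optional[dict] = None,
    render_kwargs: Optional[dict] = None,
):
    """Lazily yield ``n_tiles`` (tile, truth) pairs sharing one case preset.

    Each tile draws independent cell positions, marker states and technical
    variation (gain/offset) so that per-tile adaptive thresholding is
    genuinely exercised. ``n_tiles`` defaults to the packaged per-panel
    analysed-tile count for the case type. The generator form keeps only
    one rendered tile in memory at a time; ``generate_case_set`` returns
    the materialised list.
    """
    if preset is None:
        preset = build_preset(case_type, **(preset_overrides or {}))
    if n_tiles is None:
        key = (case_type, panel.name)
        if key not in TILE_COUNTS:
            raise ValueError(
                f"no default tile count for {key}; pass n_tiles explicitly"
            )
        n_tiles = TILE_COUNTS[key]
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    root = np.random.SeedSequence(seed)
    for t, child in enumerate(root.spawn(n_tiles)):
        place_ss, render_ss, var_ss = child.spawn(3)
        truth = place_cells(
            preset, geometry, rng=np.random.default_rng(place_ss),
            **(place_kwargs or {}),
        )
        variation = (
            sample_variation(np.random.default_rng(var_ss))
            if vary_technical
            else TechnicalVariation()
        )
        tile = render_tile(
            truth, panel, geometry, variation, spillover_beta,
            rng=np.random.default_rng(render_ss),
            tile_id=f"{case_type}-{t:04d}", case_type=case_type,
            **(render_kwargs or {}),
        )
        yield tile, truth


def generate_case_set(
    case_type: str,
    panel: PanelDefinition,
    n_tiles: Optional[int] = None,
    seed: int = 0,
    geometry: TileGeometry = TileGeometry(),
    **kwargs,
) -> list[tuple[MultichannelTile, pd.DataFrame]]:
    """Materialised form of :func:`iter_case_set` (same seed derivation)."""
    return list(
        iter_case_set(case_type, panel, n_tiles, seed, geometry, **kwargs)
    )
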