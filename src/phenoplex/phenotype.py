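"""Per-cell binary marker calls and membranous double-positive resolution.

Calling is *non-hierarchical*: each marker is scored independently in the
compartment its biology dictates (nuclear markers in the nucleus, membranous
in the membrane ring, cytoplasmic in the cytoplasm) and a cell is
provisionally positive when the positive-pixel fraction of that compartment
reaches a localisation-specific floor.

In crowded tissue, membrane signal from one cell contaminates the abutting
ring pixels of its touching neighbour, producing spurious provisional
double-positives for pairs of membranous markers. The resolution step
adjudicates each provisionally double-positive pair using (i) angular sector
coverage of the weaker marker around the ring, (ii) the pixel overlap
coefficient of the two markers' positive ring pixels, and (iii) whether the
weaker marker's signal is confined to interfaces with touching neighbours
that carry that marker. Resolution can only revoke positivity, never grant
it; nuclear and cytoplasmic markers are never revoked.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .panels import PanelDefinition, PhenotypeDefinition, evaluate_phenotype_frame
from .segment import CellSegmentation, cell_adjacency
from .simulate import TileGeometry

DEFAULT_F_MIN = {"nuclear": 0.30, "membranous": 0.20, "cytoplasmic": 0.20}

RESOLUTION_CODES = ("not_applicable", "genuine", "spurious_spillover", "ambiguous")


def call_markers(
    seg: CellSegmentation,
    masks: Mapping[str, np.ndarray],
    panel: PanelDefinition,
    f_min: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Provisional binary marker status for every (cell, marker).

    ``masks`` maps marker name to its thresholded binary raster. Returns a
    long table: cell_id, marker, localization, fraction (positive pixels /
    compartment pixels), provisional. An empty compartment yields fraction 0
    and a negative status, with a warning.
    """
    fmin = dict(DEFAULT_F_MIN)
    if f_min:
        fmin.update(f_min)
    n = int(max(seg.labels, default=0))
    frames = []
    for m in panel.markers:
        if m.is_counterstain:
            continue
        comp = seg.compartment_labels(m.localization)
        total = np.bincount(comp.ravel(), minlength=n + 1)[1:]
        mask = np.asarray(masks[m.name], dtype=bool)
        pos = np.bincount(comp.ravel()[mask.ravel()], minlength=n + 1)[1:]
        labels = seg.labels
        tot = total[labels - 1]
        if np.any(tot == 0) and len(labels):
            warnings.warn(
                f"{int((tot == 0).sum())} cells have an empty "
                f"{m.localization} compartment for {m.name}; scored negative",
                stacklevel=2,
            )
        frac = np.where(tot > 0, pos[labels - 1] / np.maximum(tot, 1), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": labels,
                    "marker": m.name,
                    "localization": m.localization,
                    "fraction": frac,
                    "provisional": frac >= fmin[m.localization],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["cell_id", "marker", "localization", "fraction", "provisional"]
        )
    return pd.concat(frames, ignore_index=True)


def _ring_pixels_by_cell(ring_labels: np.ndarray):
    """Map label -> (ys, xs) arrays of its ring pixels."""
    flat = ring_labels.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return {}
    labs = flat[nz]
    order = np.argsort(labs, kind="stable")
    nz, labs = nz[order], labs[order]
    ys, xs = np.unravel_index(nz, ring_labels.shape)
    starts = np.searchsorted(labs, np.unique(labs))
    out = {}
    uniq = np.unique(labs)
    bounds = np.searchsorted(labs, uniq, side="left")
    bounds = np.append(bounds, labs.size)
    for i, lab in enumerate(uniq):
        sl = slice(bounds[i], bounds[i + 1])
        out[int(lab)] = (ys[sl], xs[sl])
    return out


def resolve_double_positives(
    seg: CellSegmentation,
    calls: pd.DataFrame,
    masks: Mapping[str, np.ndarray],
    panel: PanelDefinition,
    *,
    sectors: int = 12,
    c_min: float = 0.5,
    tau: float = 0.5,
    ambiguous_policy: str = "revoke",
    neighbor_margin_sectors: int = 1,
) -> pd.DataFrame:
    """Adjudicate provisional membranous double-positives.

    For each cell provisionally positive for two membranous markers the
    ring is cut into ``sectors`` equal angular sectors about the centroid.
    Per marker, *sector coverage* is the fraction of ring-bearing sectors
    containing positive pixels; the *overlap coefficient* is
    ``|M1+ ∩ M2+| / min(|M1+|, |M2+|)`` over ring pixels. The weaker marker
    is the one with the smaller compartment-positive fraction (ties broken
    lexicographically).

    Decision per pair: (a) weaker coverage >= ``c_min`` and overlap >=
    ``tau`` -> genuine, both statuses stand; (b) else, if every positive
    sector of the weaker marker lies within ``neighbor_margin_sectors`` of
    an interface with a touching neighbour provisionally positive for that
    marker -> spurious spillover, the weaker status is revoked; (c) else
    ambiguous, decided by ``ambiguous_policy`` ('revoke' or 'keep').

    Pairs are processed strongest-first and iterated to a fixpoint; since
    decisions only revoke, at most ``n_markers`` sweeps are needed. Returns
    ``calls`` with added ``resolved`` and ``resolution`` columns.
    """
    if sectors < 8:
        raise ValueError("sectors must be >= 8")
    if ambiguous_policy not in ("revoke", "keep"):
        raise ValueError("ambiguous_policy must be 'revoke' or 'keep'")
    out = calls.copy()
    out["resolved"] = out["provisional"]
    out["resolution"] = "not_applicable"
    memb = [
        m.name
        for m in panel.markers
        if m.localization == "membranous" and not m.is_counterstain
    ]
    if len(memb) < 2 or out.empty:
        return out

    sub = out[out["marker"].isin(memb)]
    frac = sub.pivot(index="cell_id", columns="marker", values="fraction")
    prov = sub.pivot(index="cell_id", columns="marker", values="provisional")
    dp_cells = prov.index[prov.sum(axis=1) >= 2]
    if len(dp_cells) == 0:
        return out

    adj = cell_adjacency(seg.cell_labels)
    ring_px = _ring_pixels_by_cell(seg.ring_labels)
    centroids = seg.table.set_index("label")[["x_px", "y_px"]]
    sector_width = 2.0 * np.pi / sectors

    # resolved state / codes held in dicts, written back at the end
    resolved: dict[tuple[int, str], bool] = {}
    codes: dict[tuple[int, str], str] = {}
    for cid in dp_cells:
        for m in memb:
            resolved[(int(cid), m)] = bool(prov.loc[cid, m])

    structure = np.ones((3, 3), dtype=bool)
    lab_raster = seg.cell_labels

    for cid in sorted(int(c) for c in dp_cells):
        pos_markers = [m for m in memb if prov.loc[cid, m]]
        if cid not in ring_px:
            continue
        ys, xs = ring_px[cid]
        cx, cy = centroids.loc[cid, "x_px"], centroids.loc[cid, "y_px"]
        theta = np.arctan2(ys - cy, xs - cx)
        sec = np.minimum((theta + np.pi) / sector_width, sectors - 1e-9).astype(int)
        sectors_present = np.unique(sec)
        marker_pos = {m: np.asarray(masks[m], dtype=bool)[ys, xs] for m in pos_markers}

        # interface sectors per touching neighbour (computed lazily)
        nb_sector_cache: dict[int, np.ndarray] = {}

        def interface_sectors(nb: int) -> np.ndarray:
            if nb not in nb_sector_cache:
                y0, y1 = ys.min(), ys.max() + 1
                x0, x1 = xs.min(), xs.max() + 1
                y0, x0 = max(0, y0 - 1), max(0, x0 - 1)
                win = lab_raster[y0: y1 + 1, x0: x1 + 1] == nb
                win = ndi.binary_dilation(win, structure=structure)
                near = win[ys - y0, xs - x0]
                nb_sector_cache[nb] = np.unique(sec[near])
            return nb_sector_cache[nb]

        pairs = sorted(
            itertools.combinations(sorted(pos_markers), 2),
            key=lambda p: -(frac.loc[cid, p[0]] + frac.loc[cid, p[1]]),
        )
        decided: set[tuple[str, str]] = set()
        for _ in range(len(memb)):
            changed = False
            for m1, m2 in pairs:
                if (m1, m2) in decided:
                    continue
                if not (resolved[(cid, m1)] and resolved[(cid, m2)]):
                    continue
                f1, f2 = frac.loc[cid, m1], frac.loc[cid, m2]
                weaker, stronger = (
                    (m1, m2) if (f1, m1) <= (f2, m2) else (m2, m1)
                )
                pos_w = marker_pos[weaker]
                pos_s = marker_pos[stronger]
                n_present = max(1, len(sectors_present))
                cov_w = len(np.unique(sec[pos_w])) / n_present
                inter = np.count_nonzero(pos_w & pos_s)
                denom = max(1, min(pos_w.sum(), pos_s.sum()))
                oc = inter / denom
                if cov_w >= c_min and oc >= tau:
                    for m in (m1, m2):
                        if codes.get((cid, m), "not_applicable") == "not_applicable":
                            codes[(cid, m)] = "genuine"
                    decided.add((m1, m2))
                    continue
                w_sectors = np.unique(sec[pos_w])
                iface: set[int] = set()
                for nb in sorted(adj.get(cid, ())):
                    if nb in prov.index and weaker in prov.columns and bool(
                        prov.loc[nb].get(weaker, False)
                    ):
                        for s in interface_sectors(nb):
                            for d in range(
                                -neighbor_margin_sectors, neighbor_margin_sectors + 1
                            ):
                                iface.add(int((s + d) % sectors))
                if w_sectors.size and iface and set(w_sectors.tolist()) <= iface:
                    resolved[(cid, weaker)] = False
                    codes[(cid, weaker)] = "spurious_spillover"
                    if codes.get((cid, stronger), "not_applicable") == "not_applicable":
                        codes[(cid, stronger)] = "genuine"
                else:
                    codes[(cid, weaker)] = "ambiguous"
                    if codes.get((cid, stronger), "not_applicable") == "not_applicable":
                        codes[(cid, stronger)] = "genuine"
                    if ambiguous_policy == "revoke":
                        resolved[(cid, weaker)] = False
                decided.add((m1, m2))
                changed = True
            if not changed:
                break

    key = pd.MultiIndex.from_frame(out[["cell_id", "marker"]])
    res_map = pd.Series(resolved)
    code_map = pd.Series(codes)
    if len(res_map):
        res_map.index = pd.MultiIndex.from_tuples(res_map.index)
        code_map.index = pd.MultiIndex.from_tuples(code_map.index)
        upd = pd.Series(np.asarray(key.map(res_map)), index=out.index)
        sel = upd.notna()
        out.loc[sel, "resolved"] = upd[sel].astype(bool)
        updc = pd.Series(np.asarray(key.map(code_map)), index=out.index)
        selc = updc.notna()
        out.loc[selc, "resolution"] = updc[selc]
    # invariant: resolution never grants positivity
    out["resolved"] = out["resolved"].astype(bool) & out["provisional"].astype(bool)
    return out


def assign_phenotypes(
    records: pd.DataFrame,
    phenotypes: list[PhenotypeDefinition],
    panel: PanelDefinition,
    seg: CellSegmentation,
    geometry: TileGeometry,
    tile_id: str = "tile",
    case_type: str = "",
) -> pd.DataFrame:
    """Build the per-cell table: resolved marker vector, phenotype labels,
    centroid in µm, nucleus area. Cells matching no packaged phenotype get
    the label 'other'."""
    if records.empty:
        cols = (
            ["cell_id", "tile_id", "case_type", "x_um", "y_um", "nucleus_area_px"]
            + list(panel.phenotype_marker_names)
            + ["labels"]
        )
        return pd.DataFrame(columns=cols)
    wide = records.pivot(index="cell_id", columns="marker", values="resolved")
    wide = wide.astype(bool)
    mpp = geometry.microns_per_px
    geom = seg.table.set_index("label").loc[wide.index]
    cells = pd.DataFrame(
        {
            "cell_id": wide.index,
            "tile_id": tile_id,
            "case_type": case_type,
            "x_um": geom["x_px"].to_numpy() * mpp,
            "y_um": geom["y_px"].to_numpy() * mpp,
            "nucleus_area_px": geom["nucleus_area_px"].to_numpy(),
        }
    ).reset_index(drop=True)
    for m in panel.phenotype_marker_names:
        cells[m] = wide[m].to_numpy()
    label_lists = [[] for _ in range(len(cells))]
    for ph in phenotypes:
        hit = evaluate_phenotype_frame(ph.expression, cells)
        for i in np.flatnonzero(hit):
            label_lists[i].append(ph.display_name)
    cells["labels"] = [ls if ls else ["other"] for ls in label_lists]
    return cells
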