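"""Workflow-validation battery against simulator ground truth.

Reproduces, on synthetic tiles, the checks a curated-annotation validation
would make on real tissue: (i) per-marker accuracy of provisional binary
calls over detected cells matched 1:1 to truth cells; (ii) accuracy of the
membranous double-positive resolution step at separating genuine
double-positives from interface spillover, against an accept-all baseline;
(iii) cross-panel precision, as the correlation of per-tile CD8+ cell
fractions between independent renders of the same ground-truth cell maps
under the lymphocyte versus cytotoxic/NK panels. Truth here is the
simulator, not manual annotation; the report header says so.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .panels import CASE_TYPES, load_default_panel
from .pipeline import PipelineConfig, run_tile, run_tiles
from .simulate import (
    TileGeometry,
    build_preset,
    generate_case_set,
    iter_case_set,
    place_cells,
    render_tile,
    sample_variation,
)


@dataclass
class MatchResult:
    pairs: np.ndarray  # (n_matched, 2): detected index, truth index
    n_detected: int
    n_truth: int

    @property
    def recall(self) -> float:
        return self.pairs.shape[0] / self.n_truth if self.n_truth else np.nan

    @property
    def precision(self) -> float:
        return self.pairs.shape[0] / self.n_detected if self.n_detected else np.nan


def match_cells(
    detected_xy_um: np.ndarray,
    truth_xy_um: np.ndarray,
    d_match_um: float = 3.0,
) -> MatchResult:
    """Greedy 1:1 nearest-pair matching under a distance cap."""
    det = np.asarray(detected_xy_um, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth_xy_um, dtype=float).reshape(-1, 2)
    if det.shape[0] == 0 or tru.shape[0] == 0:
        return MatchResult(np.empty((0, 2), dtype=int), det.shape[0], tru.shape[0])
    tree = cKDTree(tru)
    cand = []
    dists, idxs = tree.query(det, k=min(4, tru.shape[0]), distance_upper_bound=d_match_um)
    dists = np.atleast_2d(dists.T).T
    idxs = np.atleast_2d(idxs.T).T
    for i in range(det.shape[0]):
        for d, j in zip(np.atleast_1d(dists[i]), np.atleast_1d(idxs[i])):
            if np.isfinite(d) and d <= d_match_um:
                cand.append((float(d), i, int(j)))
    cand.sort()
    used_det, used_tru, pairs = set(), set(), []
    for d, i, j in cand:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        pairs.append((i, j))
    return MatchResult(
        np.asarray(pairs, dtype=int).reshape(-1, 2), det.shape[0], tru.shape[0]
    )


def score_marker_calls(
    cells: pd.DataFrame,
    truth: pd.DataFrame,
    match: MatchResult,
    markers: Sequence[str],
    status_columns: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Accuracy/sensitivity/specificity per marker over matched cells.

    ``cells`` holds the pipeline's per-cell statuses (boolean marker
    columns, row order defining detected indices); ``truth`` the simulator
    table. ``status_columns`` can override which frame supplies the calls
    (e.g. a provisional-status frame with the same row order as ``cells``).
    """
    calls = status_columns if status_columns is not None else cells
    rows = []
    for m in markers:
        pred = calls[m].to_numpy(dtype=bool)[match.pairs[:, 0]]
        true = truth[m].to_numpy(dtype=bool)[match.pairs[:, 1]]
        n = pred.size
        if n == 0:
            rows.append({"marker": m, "n": 0, "accuracy": np.nan,
                         "sensitivity": np.nan, "specificity": np.nan})
            continue
        acc = float((pred == true).mean())
        pos, neg = true.sum(), (~true).sum()
        sens = float((pred & true).sum() / pos) if pos else np.nan
        spec = float((~pred & ~true).sum() / neg) if neg else np.nan
        rows.append({"marker": m, "n": int(n), "accuracy": acc,
                     "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def _provisional_wide(calls: pd.DataFrame) -> pd.DataFrame:
    return calls.pivot(index="cell_id", columns="marker", values="provisional")


def _round_robin_presets(case_types: Sequence[str], n: int) -> list[str]:
    return [case_types[i % len(case_types)] for i in range(n)]


def marker_call_validation(
    seed: int,
    n_tiles_per_panel: int = 20,
    *,
    panels: Sequence[str] = ("lymphocyte", "cytotoxic_nk", "macrophage"),
    case_types: Sequence[str] = CASE_TYPES,
    geometry: TileGeometry = TileGeometry(),
    config: Optional[PipelineConfig] = None,
    d_match_um: float = 3.0,
    place_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Provisional per-marker call accuracy on default-difficulty tiles.

    Tiles cycle through the case-type presets; confusion counts are pooled
    across a panel's tiles before computing per-marker accuracy. Returns one
    row per (panel, marker).
    """
    cfg = config or PipelineConfig()
    root = np.random.SeedSequence(seed)
    panel_children = root.spawn(len(panels))
    out = []
    for p_i, panel_name in enumerate(panels):
        panel, phenos = load_default_panel(panel_name)
        markers = list(panel.phenotype_marker_names)
        correct = {m: 0 for m in markers}
        total = {m: 0 for m in markers}
        cases = _round_robin_presets(list(case_types), n_tiles_per_panel)
        children = panel_children[p_i].spawn(n_tiles_per_panel)
        for case, child in zip(cases, children):
            pairs = generate_case_set(
                case, panel, n_tiles=1,
                seed=int(child.generate_state(1)[0] % 2**31),
                geometry=geometry, place_kwargs=place_kwargs,
            )
            tile, truth = pairs[0]
            res = run_tile(tile, phenos, cfg)
            if res.cells.empty:
                continue
            prov = _provisional_wide(res.calls).loc[res.cells["cell_id"]]
            mpp = geometry.microns_per_px
            match = match_cells(
                res.cells[["x_um", "y_um"]].to_numpy(),
                truth[["x_px", "y_px"]].to_numpy() * mpp,
                d_match_um=d_match_um,
            )
            scores = score_marker_calls(
                res.cells, truth, match, markers, status_columns=prov.reset_index()
            )
            for _, r in scores.iterrows():
                if r["n"]:
                    correct[r["marker"]] += int(round(r["accuracy"] * r["n"]))
                    total[r["marker"]] += int(r["n"])
        for m in markers:
            out.append(
                {
                    "panel": panel_name,
                    "marker": m,
                    "n": total[m],
                    "accuracy": correct[m] / total[m] if total[m] else np.nan,
                }
            )
    return pd.DataFrame(out)


def score_resolution(
    calls: pd.DataFrame,
    cells: pd.DataFrame,
    truth: pd.DataFrame,
    match: MatchResult,
    membranous_markers: Sequence[str],
) -> pd.DataFrame:
    """Per provisionally double-positive (cell, marker-pair): predicted
    genuine (both statuses stood) vs truth genuine (both markers true for
    the matched truth cell). Returns one row per scored pair."""
    prov = calls.pivot(index="cell_id", columns="marker", values="provisional")
    res = calls.pivot(index="cell_id", columns="marker", values="resolved")
    det_ids = cells["cell_id"].to_numpy()
    rows = []
    for di, tj in match.pairs:
        cid = det_ids[di]
        pm = [m for m in membranous_markers if bool(prov.loc[cid].get(m, False))]
        if len(pm) < 2:
            continue
        for m1, m2 in itertools.combinations(pm, 2):
            pred_genuine = bool(res.loc[cid, m1]) and bool(res.loc[cid, m2])
            true_genuine = bool(truth[m1].iloc[tj]) and bool(truth[m2].iloc[tj])
            rows.append(
                {
                    "cell_id": cid,
                    "pair": f"{m1}/{m2}",
                    "predicted_genuine": pred_genuine,
                    "truth_genuine": true_genuine,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "pair", "predicted_genuine", "truth_genuine"])


def resolution_validation(
    seed: int,
    n_tiles: int = 30,
    *,
    case_type: str = "NLPHL-pE",
    genuine_dp_fraction: float = 0.02,
    contact_fraction: float = 0.4,
    spillover_beta: float = 0.3,
    geometry: TileGeometry = TileGeometry(),
    config: Optional[PipelineConfig] = None,
    d_match_um: float = 3.0,
    place_kwargs: Optional[dict] = None,
) -> dict:
    """Accuracy of genuine-vs-spillover adjudication on crowded lymphocyte-
    panel tiles, with a truth subpopulation of genuine CD4+CD8+ cells
    (``genuine_dp_fraction`` of CD20-negative cells) so both outcome classes
    are represented. Baseline is accept-all (every provisional
    double-positive treated as genuine)."""
    panel, phenos = load_default_panel("lymphocyte")
    cfg = config or PipelineConfig()
    memb = [
        m.name for m in panel.markers
        if m.localization == "membranous" and not m.is_counterstain
    ]
    pk = dict(place_kwargs or {})
    pk.setdefault("contact_fraction", contact_fraction)
    pairs = iter_case_set(
        case_type, panel, n_tiles=n_tiles, seed=seed, geometry=geometry,
        preset_overrides={"CD4+CD8+PD1+": genuine_dp_fraction},
        spillover_beta=spillover_beta, place_kwargs=pk,
    )
    scored = []
    mpp = geometry.microns_per_px
    for tile, truth in pairs:
        res = run_tile(tile, phenos, cfg)
        if res.cells.empty:
            continue
        match = match_cells(
            res.cells[["x_um", "y_um"]].to_numpy(),
            truth[["x_px", "y_px"]].to_numpy() * mpp,
            d_match_um=d_match_um,
        )
        scored.append(score_resolution(res.calls, res.cells, truth, match, memb))
    allp = pd.concat(scored, ignore_index=True) if scored else pd.DataFrame()
    if allp.empty:
        return {"n_pairs": 0, "accuracy": np.nan, "baseline_accuracy": np.nan,
                "superior": False}
    correct = (allp["predicted_genuine"] == allp["truth_genuine"]).mean()
    baseline = allp["truth_genuine"].mean()  # accept-all predicts genuine
    return {
        "n_pairs": int(len(allp)),
        "n_truth_genuine": int(allp["truth_genuine"].sum()),
        "accuracy": float(correct),
        "baseline_accuracy": float(baseline),
        "superior": bool(correct > baseline),
    }


def cross_panel_correlation(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> float:
    """Pearson R between matched per-tile fraction series; NaN when fewer
    than 3 tiles or a series has zero variance."""
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size != b.size:
        raise ValueError("fraction series must be matched (equal length)")
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(sps.pearsonr(a, b).statistic)


def cross_panel_validation(
    seed: int,
    n_maps: int = 60,
    *,
    case_types: Sequence[str] = CASE_TYPES,
    geometry: TileGeometry = TileGeometry(),
    config: Optional[PipelineConfig] = None,
    place_kwargs: Optional[dict] = None,
) -> dict:
    """Render the same ground-truth cell maps under the lymphocyte and
    cytotoxic/NK panels with independently drawn per-tile technical
    variation and noise, run the pipeline on each render, and correlate the
    per-tile CD8+ fractions (of all detected cells)."""
    cfg = config or PipelineConfig()
    panel_l, phenos_l = load_default_panel("lymphocyte")
    panel_c, phenos_c = load_default_panel("cytotoxic_nk")
    cases = _round_robin_presets(list(case_types), n_maps)
    root = np.random.SeedSequence(seed)
    fr_l, fr_c = [], []
    for case, child in zip(cases, root.spawn(n_maps)):
        place_ss, ra, rb, va, vb = child.spawn(5)
        preset = build_preset(case)
        truth = place_cells(
            preset, geometry, rng=np.random.default_rng(place_ss),
            **(place_kwargs or {}),
        )
        row = []
        for panel, phenos, rss, vss in (
            (panel_l, phenos_l, ra, va),
            (panel_c, phenos_c, rb, vb),
        ):
            tile = render_tile(
                truth, panel, geometry,
                variation=sample_variation(np.random.default_rng(vss)),
                rng=np.random.default_rng(rss), case_type=case,
            )
            res = run_tile(tile, phenos, cfg)
            frac = (
                float(res.cells["CD8"].mean()) if len(res.cells) else np.nan
            )
            row.append(frac)
        fr_l.append(row[0])
        fr_c.append(row[1])
    r = cross_panel_correlation(fr_l, fr_c)
    return {
        "n_tiles": n_maps,
        "pearson_r": r,
        "fractions": pd.DataFrame(
            {"case_type": cases, "cd8_fraction_lymphocyte": fr_l,
             "cd8_fraction_cytotoxic": fr_c}
        ),
    }


def composition_recovery(
    seed: int,
    case_type: str = "NLPHL-pC",
    n_tiles: int = 50,
    *,
    phenotype: str = "CD16+GZMB+",
    panel_name: str = "cytotoxic_nk",
    geometry: TileGeometry = TileGeometry(),
    config: Optional[PipelineConfig] = None,
    place_kwargs: Optional[dict] = None,
) -> dict:
    """End-to-end parameter recovery: generate a case set from a packaged
    preset, run the full pipeline, and report the median across tiles of a
    phenotype's parent-relative fraction (in percent)."""
    from .panels import load_default_panel as _ldp
    from .quantify import phenotype_fractions

    panel, phenos = _ldp(panel_name)
    pairs = iter_case_set(
        case_type, panel, n_tiles=n_tiles, seed=seed, geometry=geometry,
        place_kwargs=place_kwargs,
    )
    cells, _ = run_tiles((t for t, _ in pairs), phenos, config)
    fractions = phenotype_fractions(cells, phenos)
    sub = fractions.loc[fractions["phenotype"] == phenotype, "fraction"].dropna()
    return {
        "phenotype": phenotype,
        "case_type": case_type,
        "n_tiles": n_tiles,
        "median_percent": float(100.0 * sub.median()),
        "fractions": fractions,
    }


def group_comparison(
    seed: int,
    group_a: str = "tonsil",
    group_b: str = "NLPHL-pA",
    *,
    phenotype: str = "CD4+FOXP3+",
    n_tiles_a: Optional[int] = None,
    n_tiles_b: Optional[int] = None,
    panel_name: str = "lymphocyte",
    geometry: TileGeometry = TileGeometry(),
    config: Optional[PipelineConfig] = None,
    place_kwargs: Optional[dict] = None,
) -> dict:
    """Differential power check: generate two case sets, run the pipeline,
    and test one phenotype's per-tile fractions between groups with the
    panel's comparison family (every parent-relative phenotype of the
    panel x this group pair) as the Bonferroni family.

    Tile counts default to the packaged per-panel analysed-tile counts.
    """
    from .panels import load_default_panel as _ldp
    from .quantify import phenotype_fractions
    from .stats import differential_table

    panel, phenos = _ldp(panel_name)
    root = np.random.SeedSequence(seed)
    sa, sb = (int(c.generate_state(1)[0] % 2**31) for c in root.spawn(2))

    def tile_stream():
        for case, n, s in ((group_a, n_tiles_a, sa), (group_b, n_tiles_b, sb)):
            for tile, _ in iter_case_set(
                case, panel, n_tiles=n, seed=s, geometry=geometry,
                place_kwargs=place_kwargs,
            ):
                yield tile

    cells, _ = run_tiles(tile_stream(), phenos, config)
    fractions = phenotype_fractions(cells, phenos)
    family = [p.display_name for p in phenos if p.parent_expression]
    plan = [(ph, group_a, group_b) for ph in family]
    results = differential_table(fractions, plan=plan)
    target = next(r for r in results if r.phenotype == phenotype)
    return {
        "result": target,
        "all_results": results,
        "m_comparisons": len(plan),
        "fractions": fractions,
    }


@dataclass
class ValidationReport:
    """Bundle of the validation battery's metric families. All metrics are
    computed against simulator ground truth (synthetic analogue of a
    manual-annotation validation)."""

    marker_calls: pd.DataFrame
    resolution: dict
    cross_panel: dict
    seed: int

    @property
    def min_marker_accuracy(self) -> float:
        return float(self.marker_calls["accuracy"].min())

    def to_text(self) -> str:
        lines = [
            "Validation battery (truth = synthetic tile simulator)",
            f"root seed: {self.seed}",
            "",
            "[1] provisional marker-call accuracy (per panel/marker):",
            self.marker_calls.to_string(index=False),
            f"    minimum accuracy: {self.min_marker_accuracy:.4f}",
            "",
            "[2] membranous double-positive resolution:",
            f"    pairs scored: {self.resolution['n_pairs']}",
            f"    accuracy: {self.resolution['accuracy']:.4f}",
            f"    accept-all baseline: {self.resolution['baseline_accuracy']:.4f}",
            f"    superior to accept-all: {self.resolution['superior']}",
            "",
            "[3] cross-panel CD8+ fraction correlation:",
            f"    tiles: {self.cross_panel['n_tiles']}",
            f"    Pearson R: {self.cross_panel['pearson_r']:.4f}",
        ]
        return "\n".join(lines)


def run_validation_battery(
    seed: int,
    *,
    n_tiles_per_panel: int = 20,
    n_resolution_tiles: int = 30,
    n_cross_panel_maps: int = 60,
    geometry: TileGeometry = TileGeometry(),
    config: Optional[PipelineConfig] = None,
    place_kwargs: Optional[dict] = None,
) -> ValidationReport:
    """Run the full validation battery from one root seed."""
    root = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(c.generate_state(1)[0] % 2**31) for c in root.spawn(3))
    marker_calls = marker_call_validation(
        s1, n_tiles_per_panel, geometry=geometry, config=config,
        place_kwargs=place_kwargs,
    )
    resolution = resolution_validation(
        s2, n_resolution_tiles, geometry=geometry, config=config,
        place_kwargs=place_kwargs,
    )
    cross = cross_panel_validation(
        s3, n_cross_panel_maps, geometry=geometry, config=config,
        place_kwargs=place_kwargs,
    )
    return ValidationReport(
        marker_calls=marker_calls, resolution=resolution,
        cross_panel=cross, seed=seed,
    )
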