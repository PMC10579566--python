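"""Marker calling and membranous double-positive resolution: compartment
fractions, the revoke-only invariant, and adjudication of constructed
genuine vs spillover cases."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phenoplex.panels import load_default_panel
from phenoplex.phenotype import (
    assign_phenotypes,
    call_markers,
    resolve_double_positives,
)
from phenoplex.segment import detect_nuclei, expand_to_cells
from phenoplex.simulate import TileGeometry


def _two_cell_seg(geom=TileGeometry(96, 96, 0.5)):
    """Two touching cells built from synthetic nuclei."""
    nuc = np.zeros((96, 96), dtype=np.int32)
    yy, xx = np.indices(nuc.shape)
    nuc[(xx - 38) ** 2 + (yy - 48) ** 2 <= 25] = 1
    nuc[(xx - 60) ** 2 + (yy - 48) ** 2 <= 25] = 2
    return expand_to_cells(nuc, expansion_um=3.0, geometry=geom), nuc


def _mask_like(seg, fill=False):
    return np.full(seg.cell_labels.shape, fill, dtype=bool)


def _ring_arc_mask(seg, label, toward_label):
    """Ring pixels of `label` within 6 px of the `toward_label` region."""
    from scipy import ndimage as ndi

    near = ndi.binary_dilation(seg.cell_labels == toward_label, iterations=6)
    return (seg.ring_labels == label) & near


@pytest.fixture(scope="module")
def lymph_panel():
    return load_default_panel("lymphocyte")


class TestCallMarkers:
    def test_full_ring_positive_fraction_one(self, lymph_panel):
        panel, _ = lymph_panel
        seg, _ = _two_cell_seg()
        masks = {m: _mask_like(seg, False) for m in panel.phenotype_marker_names}
        masks["CD4"] = seg.ring_labels == 1
        calls = call_markers(seg, masks, panel)
        row = calls[(calls.cell_id == 1) & (calls.marker == "CD4")].iloc[0]
        assert row.fraction == 1.0 and bool(row.provisional)
        other = calls[(calls.cell_id == 2) & (calls.marker == "CD4")].iloc[0]
        assert other.fraction == 0.0 and not bool(other.provisional)

    def test_all_negative_mask_negative_status(self, lymph_panel):
        panel, _ = lymph_panel
        seg, _ = _two_cell_seg()
        masks = {m: _mask_like(seg, False) for m in panel.phenotype_marker_names}
        calls = call_markers(seg, masks, panel)
        assert (~calls.provisional).all()
        assert (calls.fraction == 0.0).all()

    def test_empty_compartment_warns_and_scores_negative(self, lymph_panel):
        panel, _ = lymph_panel
        nuc = np.zeros((64, 64), dtype=np.int32)
        yy, xx = np.indices(nuc.shape)
        nuc[(xx - 32) ** 2 + (yy - 32) ** 2 <= 25] = 1
        seg = expand_to_cells(nuc, 0.0, TileGeometry(64, 64, 0.5))  # no ring/cyto
        masks = {m: np.ones((64, 64), dtype=bool) for m in panel.phenotype_marker_names}
        with pytest.warns(UserWarning):
            calls = call_markers(seg, masks, panel)
        memb = calls[calls.localization == "membranous"]
        assert (~memb.provisional).all()
        assert (memb.fraction == 0.0).all()

    def test_localization_selects_compartment(self, lymph_panel):
        panel, _ = lymph_panel
        seg, _ = _two_cell_seg()
        masks = {m: _mask_like(seg, False) for m in panel.phenotype_marker_names}
        masks["FOXP3"] = seg.nucleus_labels == 1  # nuclear marker, nuclear mask
        calls = call_markers(seg, masks, panel)
        foxp3 = calls[(calls.cell_id == 1) & (calls.marker == "FOXP3")].iloc[0]
        assert foxp3.fraction == 1.0 and bool(foxp3.provisional)


class TestResolution:
    def test_single_marker_not_applicable(self, lymph_panel):
        panel, _ = lymph_panel
        seg, _ = _two_cell_seg()
        masks = {m: _mask_like(seg, False) for m in panel.phenotype_marker_names}
        masks["CD4"] = seg.ring_labels > 0
        calls = call_markers(seg, masks, panel)
        out = resolve_double_positives(seg, calls, masks, panel)
        assert (out.resolution == "not_applicable").all()
        assert (out.resolved == out.provisional).all()

    def test_full_ring_double_positive_genuine(self, lymph_panel):
        """Both markers over the whole ring with complete overlap: the
        double positive stands as genuine."""
        panel, _ = lymph_panel
        seg, _ = _two_cell_seg()
        masks = {m: _mask_like(seg, False) for m in panel.phenotype_marker_names}
        masks["CD4"] = seg.ring_labels == 1
        masks["CD8"] = seg.ring_labels == 1
        calls = call_markers(seg, masks, panel)
        out = resolve_double_positives(seg, calls, masks, panel)
        c1 = out[out.cell_id == 1].set_index("marker")
        assert c1.loc["CD4", "resolution"] == "genuine"
        assert c1.loc["CD8", "resolution"] == "genuine"
        assert bool(c1.loc["CD4", "resolved"]) and bool(c1.loc["CD8", "resolved"])

    def test_interface_confined_signal_revoked_as_spillover(self, lymph_panel):
        """Cell 1 truly CD4+; cell 2 truly CD8+ with CD4 spillover confined
        to the interface arc: cell 2's CD4 is revoked as spurious."""
        panel, _ = lymph_panel
        seg, _ = _two_cell_seg()
        masks = {m: _mask_like(seg, False) for m in panel.phenotype_marker_names}
        masks["CD4"] = (seg.ring_labels == 1) | _ring_arc_mask(seg, 2, 1)
        masks["CD8"] = seg.ring_labels == 2
        calls = call_markers(seg, masks, panel)
        arc_row = calls[(calls.cell_id == 2) & (calls.marker == "CD4")].iloc[0]
        assert bool(arc_row.provisional), "constructed arc must be provisionally positive"
        out = resolve_double_positives(seg, calls, masks, panel)
        c2 = out[out.cell_id == 2].set_index("marker")
        assert c2.loc["CD4", "resolution"] == "spurious_spillover"
        assert not bool(c2.loc["CD4", "resolved"])
        assert bool(c2.loc["CD8", "resolved"])

    def test_resolution_only_revokes(self, medium_run):
        calls = medium_run["result"].calls
        assert not (calls.resolved & ~calls.provisional).any()

    def test_nuclear_and_cytoplasmic_never_revoked(self, medium_run):
        calls = medium_run["result"].calls
        nonmemb = calls[calls.localization != "membranous"]
        assert (nonmemb.resolved == nonmemb.provisional).all()

    def test_deterministic(self, medium_run, lymph_panel):
        panel, _ = lymph_panel
        res = medium_run["result"]
        seg = res.seg
        masks = {
            m.name: np.zeros(seg.cell_labels.shape, dtype=bool)
            for m in panel.markers if not m.is_counterstain
        }
        # reconstruct masks cheaply is not possible here; instead rerun the
        # resolution twice on identical inputs and compare
        from phenoplex.threshold import dynamic_threshold

        tile = medium_run["tile"]
        masks = {
            m.name: dynamic_threshold(tile.stack[m.channel_index], k=6.0).mask
            for m in panel.markers if not m.is_counterstain
        }
        base = call_markers(seg, masks, panel)
        a = resolve_double_positives(seg, base, masks, panel)
        b = resolve_double_positives(seg, base.sample(frac=1, random_state=0), masks, panel)
        b = b.sort_values(["marker", "cell_id"]).reset_index(drop=True)
        a = a.sort_values(["marker", "cell_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_sector_count_floor(self, lymph_panel):
        panel, _ = lymph_panel
        seg, _ = _two_cell_seg()
        masks = {m: _mask_like(seg, False) for m in panel.phenotype_marker_names}
        calls = call_markers(seg, masks, panel)
        with pytest.raises(ValueError):
            resolve_double_positives(seg, calls, masks, panel, sectors=4)


class TestAssignPhenotypes:
    def _records(self, panel, vector):
        rows = []
        for m in panel.markers:
            if m.is_counterstain:
                continue
            rows.append(
                dict(cell_id=1, marker=m.name, localization=m.localization,
                     fraction=1.0 if vector.get(m.name) else 0.0,
                     provisional=bool(vector.get(m.name)),
                     resolved=bool(vector.get(m.name)),
                     resolution="not_applicable")
            )
        return pd.DataFrame(rows)

    def test_effector_nk_gets_parent_and_subset_labels(self):
        panel, phenos = load_default_panel("cytotoxic_nk")
        nuc = np.zeros((64, 64), dtype=np.int32)
        yy, xx = np.indices(nuc.shape)
        nuc[(xx - 32) ** 2 + (yy - 32) ** 2 <= 25] = 1
        seg = expand_to_cells(nuc, 3.0, TileGeometry(64, 64, 0.5))
        records = self._records(panel, dict(CD16=True, GZMB=True))
        cells = assign_phenotypes(records, phenos, panel, seg, seg.geometry)
        labels = cells.labels.iloc[0]
        assert "NK-cell" in labels and "CD16+GZMB+" in labels

    def test_cd8_cd16_cell_is_t_not_nk(self):
        panel, phenos = load_default_panel("cytotoxic_nk")
        nuc = np.zeros((64, 64), dtype=np.int32)
        yy, xx = np.indices(nuc.shape)
        nuc[(xx - 32) ** 2 + (yy - 32) ** 2 <= 25] = 1
        seg = expand_to_cells(nuc, 3.0, TileGeometry(64, 64, 0.5))
        records = self._records(panel, dict(CD8=True, CD16=True))
        cells = assign_phenotypes(records, phenos, panel, seg, seg.geometry)
        labels = cells.labels.iloc[0]
        assert "CD8+CD16+" in labels and "NK-cell" not in labels

    def test_all_negative_gets_other(self):
        panel, phenos = load_default_panel("lymphocyte")
        nuc = np.zeros((64, 64), dtype=np.int32)
        yy, xx = np.indices(nuc.shape)
        nuc[(xx - 32) ** 2 + (yy - 32) ** 2 <= 25] = 1
        seg = expand_to_cells(nuc, 3.0, TileGeometry(64, 64, 0.5))
        records = self._records(panel, {})
        cells = assign_phenotypes(records, phenos, panel, seg, seg.geometry)
        assert cells.labels.iloc[0] == ["other"]

    def test_labels_match_expressions_exactly(self, medium_run):
        from phenoplex.panels import evaluate_phenotype_frame

        cells = medium_run["result"].cells
        for ph in medium_run["phenotypes"]:
            hit = evaluate_phenotype_frame(ph.expression, cells)
            labelled = cells.labels.map(lambda ls: ph.display_name in ls).to_numpy()
            np.testing.assert_array_equal(hit, labelled)
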