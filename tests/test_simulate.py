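"""Synthetic tile generator: determinism, composition recovery, spillover
structure, and the affine gain/offset model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenoplex.panels import load_default_panel
from phenoplex.simulate import (
    ALL_MARKERS,
    TileGeometry,
    build_preset,
    generate_case_set,
    place_cells,
    render_tile,
    sample_cell_states,
    truth_marker_mask,
)

from conftest import SMALL_GEOM


class TestGeometry:
    def test_default_tile_matches_acquisition_format(self):
        g = TileGeometry()
        assert (g.width_px, g.height_px) == (1348, 1008)
        assert g.width_um == pytest.approx(670.0, abs=0.5)
        assert g.height_um == pytest.approx(501.0, abs=1.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TileGeometry(32, 1008)
        with pytest.raises(ValueError):
            TileGeometry(microns_per_px=0.0)


class TestPlacement:
    def test_zero_density_gives_empty_table(self):
        truth = place_cells(build_preset("tonsil"), SMALL_GEOM, seed=1, n_cells=0)
        assert len(truth) == 0

    def test_same_seed_identical(self):
        a = place_cells(build_preset("NLPHL-pC"), SMALL_GEOM, seed=7)
        b = place_cells(build_preset("NLPHL-pC"), SMALL_GEOM, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_centroids_inside_bounds_and_lp_is_cd20(self):
        truth = place_cells(build_preset("NLPHL-pE"), SMALL_GEOM, seed=3)
        assert truth["x_px"].between(0, SMALL_GEOM.width_px - 1).all()
        assert truth["y_px"].between(0, SMALL_GEOM.height_px - 1).all()
        assert truth.loc[truth["is_lp"], "CD20"].all()

    def test_contact_fraction_realised(self):
        truth = place_cells(
            build_preset("THRLBCL"), TileGeometry(674, 504), seed=5,
            contact_fraction=0.4,
        )
        touching = truth["contact_neighbors"].map(len).gt(0).mean()
        assert touching >= 0.3

    def test_marker_proportions_within_binomial_bounds(self):
        """500 placed cells: realised counts of key marker states fall
        within the exact binomial 99% interval of the preset rates."""
        preset = build_preset("tonsil")
        truth = place_cells(
            preset, TileGeometry(1348, 1008), seed=11, n_cells=500,
        )
        n = len(truth)
        b = preset.b_cell_fraction
        nonb = 1.0 - b
        expected = {
            "CD20": b,
            "CD4": nonb * (
                preset.phenotype_proportions["CD4+"]
                + preset.phenotype_proportions["CD4+CD8+PD1+"]
            ),
            "CD8": nonb * (
                preset.phenotype_proportions["CD8+"]
                + preset.phenotype_proportions["CD4+CD8+PD1+"]
            ),
            "CD163": nonb * preset.phenotype_proportions["Macrophage"]
            * preset.phenotype_proportions["CD163+"],
        }
        for marker, p in expected.items():
            count = int(truth[marker].sum())
            lo = sps.binom.ppf(0.005, n, p)
            hi = sps.binom.ppf(0.995, n, p)
            assert lo <= count <= hi, f"{marker}: {count} outside [{lo}, {hi}]"

    def test_lineage_conditionals_recover_parent_relative_rates(self):
        """Large-sample state draw: conditional (parent-relative) rates
        converge to the preset values."""
        preset = build_preset("NLPHL-pC")
        rng = np.random.default_rng(17)
        states = sample_cell_states(preset, 40_000, rng)
        nk = states["lineage"] == "NK"
        sub = states["CD16"] & states["GZMB"] & nk
        assert sub.sum() / nk.sum() == pytest.approx(0.36, abs=0.02)
        mac = states["lineage"] == "MAC"
        assert (states["CD163"] & mac).sum() / mac.sum() == pytest.approx(0.62, abs=0.02)

    def test_infeasible_density_raises(self):
        from phenoplex.simulate import PlacementError

        with pytest.raises(PlacementError):
            place_cells(
                build_preset("tonsil"), TileGeometry(64, 64), seed=1,
                n_cells=400, max_attempts=20,
            )


class TestRender:
    def test_empty_truth_is_background_noise_around_offset(self):
        panel, _ = load_default_panel("lymphocyte")
        truth = place_cells(build_preset("tonsil"), SMALL_GEOM, seed=1, n_cells=0)
        from phenoplex.simulate import TechnicalVariation

        var = TechnicalVariation(gain=1.0, offset=200.0)
        tile = render_tile(truth, panel, SMALL_GEOM, var, seed=2)
        med = np.median(tile.stack)
        assert med == pytest.approx(200.0 + 10.0, abs=3.0)  # offset + ambient

    def test_spillover_beta_validation(self):
        panel, _ = load_default_panel("lymphocyte")
        truth = place_cells(build_preset("tonsil"), SMALL_GEOM, seed=1, n_cells=5)
        with pytest.raises(ValueError):
            render_tile(truth, panel, SMALL_GEOM, spillover_beta=1.0, seed=1)

    def test_isolated_cells_signal_confined_to_own_compartments(self):
        """With no contacts and no spillover, each marker's supra-background
        signal lies only where that marker's truth compartments are."""
        panel, _ = load_default_panel("lymphocyte")
        truth = place_cells(
            build_preset("tonsil"), SMALL_GEOM, seed=9, contact_fraction=0.0,
            n_cells=25,
        )
        tile = render_tile(
            truth, panel, SMALL_GEOM, spillover_beta=0.0, seed=10,
            noise=False, blur_sigma_px=0.0,
        )
        for m in panel.markers:
            if m.is_counterstain:
                continue
            plane = tile.stack[m.channel_index]
            mask = truth_marker_mask(truth, m.name, m.localization, SMALL_GEOM)
            assert not (plane[~mask] > 10.0 + 1e-6).any(), m.name

    def test_affine_gain_offset_relation_before_noise(self):
        panel, _ = load_default_panel("lymphocyte")
        truth = place_cells(build_preset("NLPHL-pA"), SMALL_GEOM, seed=4, n_cells=30)
        from phenoplex.simulate import TechnicalVariation

        t1 = render_tile(
            truth, panel, SMALL_GEOM, TechnicalVariation(gain=1.0, offset=0.0),
            seed=5, noise=False,
        )
        t2 = render_tile(
            truth, panel, SMALL_GEOM, TechnicalVariation(gain=2.0, offset=100.0),
            seed=5, noise=False,
        )
        np.testing.assert_allclose(t2.stack, 2.0 * t1.stack + 100.0, rtol=1e-5)

    def test_spillover_adds_foreign_signal_on_interface_only(self):
        """A marker-negative cell touching a marker-positive neighbour shows
        supra-background foreign signal on its ring near the interface and
        none on the far side (controlled two-cell construction)."""
        panel, _ = load_default_panel("lymphocyte")
        geom = TileGeometry(320, 240)
        mpp = geom.microns_per_px
        r_um = 6.0  # cell radius
        d_px = 0.92 * 2 * r_um / mpp
        truth = pd.DataFrame(
            {
                "cell_id": [0, 1],
                "x_px": [100.0, 100.0 + d_px],
                "y_px": [120.0, 120.0],
                "nucleus_radius_um": [r_um - 2.5] * 2,
                "cell_radius_um": [r_um] * 2,
                "lineage": ["CD4T", "other"],
                "is_lp": [False, False],
            }
        )
        for m in ALL_MARKERS:
            truth[m] = [m == "CD4", False]
        truth["contact_neighbors"] = [[1], [0]]
        tile = render_tile(
            truth, panel, geom, spillover_beta=0.3, seed=7, noise=False,
            blur_sigma_px=0.0,
        )
        plane = tile.stack[panel.channel_of("CD4")]
        rc = r_um / mpp
        yy, xx = np.ogrid[: geom.height_px, : geom.width_px]
        d2 = (xx - truth.x_px[1]) ** 2 + (yy - 120.0) ** 2
        ring = (d2 <= rc**2) & (d2 >= (rc - 2) ** 2)
        d2n = (xx - 100.0) ** 2 + (yy - 120.0) ** 2
        near = ring & (d2n <= (rc + 0.5) ** 2)
        far = ring & (d2n >= (rc + 6.0) ** 2)
        assert near.sum() >= 3 and far.sum() >= 3
        ambient = 10.0
        assert plane[near].max() >= ambient + 0.3 * 100.0 - 1.0
        assert plane[far].max() <= ambient + 1e-6


class TestCaseSets:
    def test_default_tonsil_lymphocyte_count(self):
        panel, _ = load_default_panel("lymphocyte")
        pairs = generate_case_set("tonsil", panel, seed=1, geometry=SMALL_GEOM)
        assert len(pairs) == 15

    def test_single_tile_and_determinism(self):
        panel, _ = load_default_panel("macrophage")
        a = generate_case_set("THRLBCL", panel, n_tiles=2, seed=42, geometry=SMALL_GEOM)
        b = generate_case_set("THRLBCL", panel, n_tiles=2, seed=42, geometry=SMALL_GEOM)
        assert len(a) == 2
        for (ta, tra), (tb, trb) in zip(a, b):
            np.testing.assert_array_equal(ta.stack, tb.stack)
            pd.testing.assert_frame_equal(tra, trb)

    def test_tiles_draw_independent_technical_variation(self):
        panel, _ = load_default_panel("lymphocyte")
        pairs = generate_case_set("tonsil", panel, n_tiles=4, seed=9, geometry=SMALL_GEOM)
        bg_medians = [float(np.median(t.stack[panel.channel_of("FOXP3")])) for t, _ in pairs]
        assert np.ptp(bg_medians) > 20.0  # offsets genuinely differ tile-to-tile

    def test_channel_count_matches_panel(self):
        panel, _ = load_default_panel("cytotoxic_nk")
        (tile, _), = generate_case_set("tonsil", panel, n_tiles=1, seed=2, geometry=SMALL_GEOM)
        assert tile.stack.shape[0] == panel.n_channels == 7
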