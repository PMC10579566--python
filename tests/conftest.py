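import warnings

import numpy as np
import pytest

from phenoplex.pipeline import run_tile
from phenoplex.simulate import (
    TileGeometry,
    build_preset,
    place_cells,
    render_tile,
    sample_variation,
)
from phenoplex.panels import load_default_panel

# quarter-linear-scale tile used by most rendered-image tests: same
# microns-per-pixel and generator defaults as the full tile, smaller field
SMALL_GEOM = TileGeometry(320, 240)
MEDIUM_GEOM = TileGeometry(674, 504)


@pytest.fixture(scope="session")
def medium_run():
    """One rendered pattern-E lymphocyte-panel tile (with technical drift)
    plus its truth table and full pipeline result; shared across tests."""
    geom = MEDIUM_GEOM
    panel, phenos = load_default_panel("lymphocyte")
    truth = place_cells(build_preset("NLPHL-pE"), geom, seed=101)
    variation = sample_variation(np.random.default_rng(102))
    tile = render_tile(truth, panel, geom, variation, seed=103)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_tile(tile, phenos)
    return {
        "geometry": geom,
        "panel": panel,
        "phenotypes": phenos,
        "truth": truth,
        "tile": tile,
        "result": res,
    }
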