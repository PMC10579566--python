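# phenoplex

Single-cell phenotyping for multiplexed immunofluorescence (mIF) tissue
images, built for studies of the lymphoma tumour microenvironment — in
particular nodular lymphocyte predominant Hodgkin lymphoma (NLPHL) and
T-cell/histiocyte-rich large B-cell lymphoma (THRLBCL), where sparse large
CD20+ neoplastic "LP" cells sit in a crowded reactive infiltrate of T cells,
NK cells and macrophages.

The package implements the complete analysis chain for multichannel tiles
(one fluorescence plane per marker plus a DAPI counterstain), together with
a synthetic tile simulator that provides per-cell ground truth, so every
stage can be validated end to end without patient material.

## What it does

1. **Dynamic per-tile thresholding.** Each channel is binarised at
   `median(background) + k · MAD(background)`, with the background pool found
   by a parameter-free seed split (Otsu on percentile-normalised,
   log-compressed intensities) guarded by a separation test. Because every
   statistic used is affine-equivariant, the binary mask is *invariant* under
   per-tile gain/offset drift `x → a·x + b` — the formal version of
   "insensitive to technical variation", and a tested property.
2. **Segmentation by nuclear expansion.** Nuclei are detected on the
   counterstain (connected components above an area floor, touching nuclei
   split by a distance-transform watershed) and grown outward by a fixed
   radius (default 3 µm), halting equidistantly where neighbours collide.
   Each cell is partitioned into nucleus, membrane ring and cytoplasm.
3. **Non-hierarchical binary marker calls.** Each marker is scored in the
   compartment its biology dictates (nuclear / membranous / cytoplasmic); a
   cell is provisionally positive when the positive-pixel fraction of that
   compartment reaches a localisation-specific floor.
4. **Colocalisation-based resolution of membranous double-positives.** In
   crowded tissue, membrane signal bleeds across cell–cell interfaces and
   creates spurious double-positives. For each provisionally double-positive
   pair the ring is cut into angular sectors; the pair is kept as *genuine*
   when the weaker marker covers enough sectors and the two markers'
   positive pixels colocalise (overlap coefficient), and revoked as
   *spillover* when the weaker marker is confined to interfaces with
   touching neighbours carrying that marker. Resolution can only revoke
   positivity, never grant it.
5. **Phenotype assignment** from boolean rules over resolved marker states,
   e.g. the NK-cell rule
   `CD8- AND [CD16+ AND/OR CD56+] AND [NKG2A+ AND/OR GZMB+ AND/OR GNLY+]`.
6. **Quantification and statistics.** Per-tile phenotype fractions relative
   to a parent population (e.g. NK subsets over all NK cells, T-cell
   phenotypes over CD20-negative cells), morphological LP-cell detection
   (CD20+ with nucleus ≥ α × tile median area), LP-to-phenotype
   nearest-neighbour distances, and two-sided Mann-Whitney U comparisons
   between case types with Bonferroni adjustment (significance p < 0.001).

Three staining panels are packaged: lymphocyte (CD20, CD4, CD8, PD1, FOXP3,
DAPI), cytotoxic/NK (CD8, CD16, CD56, NKG2A, GZMB, GNLY, DAPI) and
macrophage (CD68, CD163, CD206, PDL1, DAPI), with the corresponding
phenotype rules and parent populations.

## Worked example

```python
import numpy as np
from phenoplex import (
    load_default_panel, build_preset, generate_case_set, run_tiles,
)
from phenoplex.quantify import phenotype_fractions

panel, phenotypes = load_default_panel("cytotoxic_nk")
pairs = generate_case_set("NLPHL-pC", panel, n_tiles=10, seed=4)
cells, log = run_tiles([tile for tile, _ in pairs], phenotypes)
fractions = phenotype_fractions(cells, phenotypes)
sub = fractions[fractions.phenotype == "CD16+GZMB+"]
print(f"median CD16+GZMB+ fraction of NK cells: "
      f"{100 * sub.fraction.median():.0f}%")
print(sub[["tile_id", "n_phenotype", "n_parent", "fraction"]].head(3))
```

Output:

```
median CD16+GZMB+ fraction of NK cells: 37%
          tile_id  n_phenotype  n_parent  fraction
3   NLPHL-pC-0000           10        28  0.357143
10  NLPHL-pC-0001            7        25  0.280000
17  NLPHL-pC-0002           10        33  0.303030
```

Each row is one simulated 670×501 µm tile: `n_parent` NK cells were
detected, of which `n_phenotype` were CD16+GZMB+ effector NK cells. Across
the ten tiles the median fraction (37%) recovers the pattern-C generating
value of 36% through the whole detection→thresholding→calling chain.

The same workflow is available from the shell:

```bash
phenoplex simulate --case-type NLPHL-pC --panel cytotoxic_nk \
    --n-tiles 10 --seed 4 --out-dir tiles/
phenoplex run --panel cytotoxic_nk --tile-dir tiles/ --out-dir out/
phenoplex validate --seed 1 --out-dir validation/
phenoplex compare --fractions out/fractions.csv --out-dir cmp/
```

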