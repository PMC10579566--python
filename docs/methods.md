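# Methods

This note documents the models, parameter choices and numerical conventions
behind phenoplex, and what the synthetic-data validation does and does not
demonstrate.

## Image and cell model

Tiles are multichannel rasters, one plane per marker plus a nuclear
counterstain, with default geometry 1348×1008 px covering 670×501 µm
(0.497 µm/px). Coordinates are 0-based, pixel-centre convention, x = column,
y = row; physical distances are pixel distances × microns-per-pixel.

Cells are modelled as discs: a nucleus of radius 2.5–4.5 µm (uniform),
surrounded by 2.5 µm of cytoplasm, with the membrane a 2 px ring at the
cell boundary. Neoplastic LP cells are conspicuously large: nucleus radius
7–11 µm, always CD20-positive. These radii make the morphological LP rule
(CD20+ AND nucleus area ≥ 2.5 × tile median) cleanly separable — the
largest normal nucleus is ~1.7× the median area, the smallest LP ~4×.

## Synthetic tile generator

The generator is first-class, tested code; it defines the study conditions
under which the pipeline is validated.

**Placement.** Cells are dart-thrown as hard discs at a default density of
2000 cells/mm² (~670 per default tile, ~26% area coverage — a
representative lymphoid-tissue crowding that keeps a desk-scale validation
run tractable). A configurable fraction of placements (default 0.4) is
anchored against an existing cell at centre distance 0.92 × the radius sum,
so membranes overlap slightly and form the contact interfaces that drive
spillover; un-anchored cells keep a 5% clearance. B cells are drawn toward
Poisson-scattered nodule centres (σ = 40 µm) with probability equal to the
case type's nodularity. Placement failure after 100 attempts per cell
raises an error (density infeasible).

**Marker states.** Sampling is hierarchical: first a lineage class
(B cell / CD4 T / CD8 T / genuine CD4+CD8+ T / NK / macrophage / other)
with lineage fractions of the CD20-negative compartment fixed per case
type; then activation markers at conditional rates chosen so the
*parent-relative* phenotype proportions match the per-case-type medians the
presets encode (e.g. CD16+GZMB+ = 36% of NK cells in pattern-C). NK cells
are drawn from three sub-states (CD56+NKG2A+, CD16+GZMB+, remainder
CD56+GNLY+) so the NK-defining disjunction is always satisfied; macrophage
CD68/CD163 states are coupled so their union covers every macrophage
detection. Case-type presets cover tonsil, NLPHL patterns A/C/E, THRLBCL
and lymphocyte-rich classical Hodgkin lymphoma; every preset value is
overridable per call.

**Rendering.** Nuclear markers fill the nucleus disc, cytoplasmic markers
the cell-minus-nucleus annulus, membranous markers the boundary ring.
Signal amplitude is 100 photons over an ambient background of 10 (the 10:1
contrast regime), blurred with a σ = 0.7 px Gaussian PSF, then Poisson
photon noise and Gaussian read noise (σ = 2) are added, and finally the
per-tile affine drift `x → gain·x + offset` is applied, with gain
log-uniform in [0.5, 2] and offset uniform in [50, 300] — deliberately wide
enough that no fixed global threshold can work across tiles. At each
contact interface, a fraction β (default 0.3) of a neighbour's membranous
amplitude is added to the abutting ring pixels (the arc of the ring within
the neighbour's disc plus a 0.5 px margin; a single such arc covers ~15% of
a ring).

**What the simulator does not emulate.** No autofluorescence, no spectral
overlap between fluorophores (channels are independent apart from membrane
spillover), no irregular cell shapes or dendritic macrophage processes, no
tissue-level autocorrelation beyond B-cell nodules, no whole-slide context.
Passing validation therefore demonstrates that the algorithms are correct
and robust to the modelled difficulty (intensity drift, crowding, membrane
spillover, sparse markers) — not that real-tissue accuracy would reach the
same numbers, since real tiles add segmentation-model mismatch and optical
artefacts the simulator omits.

## Dynamic thresholding

Two passes per channel. (1) Seed split: intensities are normalised by their
1st–99th percentiles, log-compressed (`log1p(99·x')`) and split by Otsu.
Otsu always returns a split, even of a unimodal noise histogram, so the
seed foreground is kept only if its median exceeds the seed background's
median by at least 8 background MADs (with a global-MAD fallback when the
background MAD is 0); otherwise the whole raster is treated as background —
the correct reading of a channel with no expressing cells. If the retained
foreground exceeds 50% of pixels, background statistics instead come from
the lower intensity quartile. (2) The threshold is
`median(bg) + k·MAD(bg)`, k = 6 by default (k = 4 for the counterstain,
where nuclei are dense and bright and recall matters more), mask strictly
`>`.

Every statistic used (percentiles, median, MAD, the separation ratio) is
affine-equivariant, so the mask is invariant under `x → a·x + b`, a > 0 —
property-tested over random rasters and random (a, b). The invariance is
exact for generic continuous intensities; a pixel lying *exactly* at the
threshold (possible for integer-valued toy inputs) can flip under the
strict inequality, which is measure-zero for real detector data. Threshold
statistics are estimated on a stride-2 pixel subsample for rasters above
one megapixel (the mask is always full-resolution); the subsample is
deterministic, so equivariance and reproducibility are unaffected. A
constant raster is degenerate: MAD 0, empty mask, flagged.

## Segmentation

Nucleus detection: dynamic threshold on the counterstain, hole filling, an
area floor (default 30 px ≈ the smallest plausible nucleus), then a
watershed on the (σ = 0.5 px smoothed) distance transform with peaks at
least 3 px apart. The light smoothing suppresses plateau artefacts of the
discrete distance transform without erasing the shallow saddle between
genuinely touching nuclei; tie-breaks are deterministic (peaks ordered by
value then raster order). Cell masks are obtained with exact nearest-seed
expansion (`skimage.segmentation.expand_labels`) by 3 µm — approximating
lymphocyte cytoplasm breadth; macrophage dendritic processes are explicitly
not captured. Colliding expansions halt equidistantly, so cells never
overlap and boundaries between equal neighbours lie on the perpendicular
bisector (tested against a brute-force nearest-seed oracle). The membrane
ring is the 2 px band inside the cell boundary; nucleus, ring and cytoplasm
partition each cell.

## Marker calling and double-positive resolution

A marker's evaluation compartment follows its localisation; the
compartment-positive fraction is compared against a floor of 0.30
(nuclear) or 0.20 (membranous, cytoplasmic). The membranous floor sits
above the ~15% ring coverage of a single spillover arc, so an isolated
contact does not flip a provisional call; cells with multiple positive
neighbours can, and those are the cases the resolution step adjudicates.
An empty compartment scores negative with a warning.

Resolution operates on every unordered pair of provisionally positive
membranous markers of a cell, strongest pair (largest fraction sum) first,
iterated to a fixpoint — decisions only revoke, so at most one sweep per
marker is needed. The ring is cut into 12 angular sectors about the
centroid. A pair is **genuine** when the weaker marker's sector coverage is
≥ 0.5 and the overlap coefficient of the two markers' positive ring pixels
is ≥ 0.5; **spurious spillover** when, instead, every positive sector of
the weaker marker lies within one sector of an interface with a touching
neighbour provisionally positive for that marker (the weaker status is
revoked); otherwise **ambiguous**, with a policy flag (default: revoke the
weaker marker — the conservative choice for phenotype specificity).
Neighbour context uses provisional statuses so the outcome is independent
of cell iteration order. Ties in marker strength break lexicographically.
Nuclear and cytoplasmic markers are never revoked. The sector/overlap/
neighbour construction is this package's own operationalisation of
colocalisation-based adjudication; every constant (sectors, coverage and
overlap floors, per-localisation fractions) is configuration-exposed so
alternative rules can be swapped in and measured against simulator truth.

## Quantification and statistics

Fractions are computed per tile (the sampling unit) relative to each
phenotype's parent population; an empty parent yields an undefined (NaN)
fraction whose record is retained. LP cells, being CD20+, fall outside the
CD20-negative parent used for lymphocyte-panel fractions by construction.
LP-to-phenotype nearest-neighbour distances are centroid-to-centroid in µm
(boundary definitions would depend on the expansion radius; centroids are
stable), LP cells themselves excluded as targets; histogram densities
normalise to unit integral over the observed range.

Group comparisons use the two-sided Mann-Whitney U test: exact enumeration
when both samples have n < 8 and no ties, otherwise the normal
approximation with tie and continuity corrections (scipy). Two identical
constant samples return p = 1 (the approximation's variance is zero).
Undefined fractions are dropped per comparison. Bonferroni adjustment is
`min(1, m·p)` with the family m = all (phenotype × group-pair) tests in the
comparison plan, recorded in every result so any family choice is
auditable; significance is declared at adjusted p < 0.001.

## Validation battery

Truth is the simulator (the synthetic analogue of a manually annotated
validation set, and declared as such in the report header). Detected cells
are matched 1:1 to truth cells greedily under a 3 µm cap. The battery
reports: per-marker provisional call accuracy over matched cells (pooled
per panel across tiles that cycle through all six case-type presets);
genuine-vs-spillover classification accuracy of the resolution step against
an accept-all baseline, on crowded lymphocyte-panel tiles generated with
the CD4+CD8+PD1+ proportion raised to 2% so genuine double-positives are
present at scoreable numbers; and the Pearson correlation of per-tile CD8+
cell fractions between lymphocyte-panel and cytotoxic/NK-panel renders of
the same ground-truth maps under independently drawn technical variation.

Problem sizes: the full run (`scripts/acceptance.py`) uses 20 tiles per
panel, 30 resolution tiles, 60 cross-panel map pairs, 50 pattern-C tiles
and 15 + 160 tiles for the differential test, all at default geometry
(~10 minutes on one CPU). The test suite exercises identical generator and
pipeline defaults at reduced sizes (3/6/12/30 tiles and quarter-size
rasters for the differential test) chosen so that each bound retains a
comfortable statistical margin at the smaller n.

## Known limitations

- The disc-cell model understates segmentation difficulty for irregular or
  process-bearing cells (macrophages); CD68/CD163 co-detection on real
  tissue is harder than the simulator suggests.
- Binary calls approximate "bright" expression; dim populations are not
  modelled (no intensity subclassification by design).
- Greedy matching is not globally optimal for pathological point
  configurations, but equals the optimal assignment at the simulator's
  spacing (tested).
- Tiles are treated as independent sampling units; case-level clustering is
  not modelled (no mixed-effects option).
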