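# Methods

## The model

Each square analysis cell is treated as an independent landscape. Within a
cell of area `A` m² the forest class (pixel value 1) is decomposed into
patches — maximal connected components under 8-connectivity by default —
and three class-level metrics are computed:

* **ED** (edge density, m/ha) = total forest/non-forest edge length / A ×
  10,000. An edge unit is a shared side between a forest and a non-forest
  pixel (4-neighbourhood), each contributing one pixel width of length.
* **PD** (patch density, per 100 ha) = patch count / A × 10,000 × 100.
* **MPA** (mean patch area, ha) = forest area / patch count. Computing it
  as the ratio of the integer pixel total to the patch count keeps the
  identity `MPA × n = forest area` exact in floating point.

Forest coverage FC = forest area / A completes the per-cell row. Cells
without forest carry ED = PD = FC = 0, MPA undefined, and a non-forest flag.

The static index is `FFI = w_ED·ED_nor + w_PD·PD_nor + w_MPA·(1 − MPA_nor)`
with non-negative weights summing to 1 (default equal thirds). Normalization
is clamped min–max with bounds taken from percentiles of the *pooled*
two-epoch distribution over forest-flagged cells: fitting the bounds once on
both epochs jointly is what makes FFI values comparable between years —
per-epoch bounds would make ΔFFI = FFI₂ − FFI₁ meaningless. The default
clip is (0, 100) (plain min–max); (0.5, 99.5) is available when heavy-tailed
metric distributions (MPA especially) would otherwise compress the useful
range. MPA's direction is handled by `1 − MPA_nor` inside the composition,
not by reversing its bounds, so one normalization convention serves all
three metrics.

ΔFFI and ΔFC are computed only on cells forested in both epochs; cells
forested in a single epoch keep their static FFI for that epoch but are
excluded from the dynamic layers.

## Classification conventions

The eight fragmentation-process modes are the sign combinations of
(ΔED, ΔPD, ΔMPA), and the four landscape-dynamic patterns the sign
combinations of (ΔFC, ΔFFI) with the fixed stage reading: cover up &
fragmentation down = deep recovery; both up = early recovery; both down =
early degradation; cover down & fragmentation up = deep degradation.
"Up" means strictly positive; an exact zero classifies as "down". This tie
rule keeps both classifiers total and exhaustive over 8/4 categories; exact
zeros have measure zero on continuous data, and the descriptive
`stable` flag (|ΔFFI| < 0.005 by default) marks near-zero cells without
introducing a ninth or fifth class.

Zonal and country summaries weight by cell count (area = cells ×
cell area); no sub-cell area refinement is attempted. Hotspot reports give
per-metric means, medians and quartiles per epoch and the percent change of
the mean, the convention behind statements like "MPA increased by 73%".

## Driver attribution

The response ΔFFI and the seven covariates are min–max rescaled to [0, 1]
over exactly the rows entering the fit (rescaling before row drops would
leak information from excluded rows). The model is OLS with intercept —
the Gaussian identity-link case of the general linear model — with classical
standard errors; 90%/95% CIs are ±1.645/±1.960 SE and p-values are
two-sided t. No multiple-testing correction is applied. Rank deficiency is
detected before fitting and reported with the names of near-duplicate
columns. The major-driver map groups analysis cells into coarse blocks
(block size an integer multiple of the cell size; 50 km on 5 km cells in the
global setup), refits within each block with at least `n_min = 30` complete
rows, and emits the covariate of largest |coefficient|; smaller or failing
blocks become nodata.

## The synthetic-data generator

The initial map is a modified-random-clusters neutral landscape: seed
pixels at density `p·(1 − a)²/4` (a = autocorrelation knob in [0, 1)), then
batched random accretion of 4-neighbour frontier pixels (acceptance 0.6 per
round) until the forest count equals `round(p·n_pixels)` exactly. One knob
controls clumpiness: a = 0.9 yields few large patches, a = 0.1 many small
ones. Modified random clusters was preferred over midpoint displacement
because it is binary-native and cheap, and the generator sits behind a
narrow interface so another model can be swapped in.

Change operators transform epoch 1 into epoch 2 within optional region
masks. Their geometry fixes the expected signs recorded in the truth table:
dissection (straight 1-pixel transects across the region, count scaling
with intensity and region extent) gives ΔED+, ΔPD+, ΔMPA−, ΔFC−, hence
ΔFFI+; infill (conversion of open pixels with ≥ 2 forest 4-neighbours, so
each conversion closes more edge than it opens and can merge patches) gives
the mirrored signature. Edge erosion, perforation, attrition, seeding and
expansion carry the weaker sign guarantees their geometry supports (mainly
ΔFC and ΔPD directions). Dissection's straight full-extent transects are a
deliberate simplification of per-patch routed cuts: they produce the right
per-cell signatures at a fraction of the complexity. Each operator
application draws from a dedicated stream keyed by (scenario seed, schedule
index), so editing one schedule entry leaves the others' draws untouched.

Driver fields are Gaussian-smoothed white noise per covariate, min–max
rescaled, with the response a planted linear combination plus iid Gaussian
noise. What the generator does *not* emulate: mechanistic forest dynamics
(growth, dispersal, fire spread), real covariate cross-correlations,
spatially autocorrelated regression errors, and the heavy global-scale
heterogeneity of satellite forest products. Passing tests therefore
demonstrate the correctness of the computational chain and the internal
consistency of the classifiers and regressions — not calibration against
real-world forest statistics.

## Numerical and design choices

* **Cell windows**: 0-based, row-major, half-open; origin at the upper-left
  pixel corner. The cell size must be an integer multiple of the pixel size;
  real-data users whose nominal cell size is not a multiple (e.g. 5000 m on
  30 m pixels) should snap the cell size (5010 m) or resample, since exact
  windows avoid per-cell resampling ambiguity. Partial boundary cells are
  excluded by default because their ground area differs from `cell_size²`,
  the denominator of ED and PD.
* **nodata**: pixels are excluded from forest area and edge counts
  (forest/nodata sides are not edges), but `A` stays `cell_size²` so
  densities remain comparable across cells; a cell with more than 50%
  nodata (configurable) is dropped instead.
* **Connectivity** defaults to 8 (queen's case), the convention of the
  standard class-level metric engines; 4 is available.
* **Window borders** are not counted as edge by default, so a fully
  forested landscape reads ED = 0 (unfragmented) rather than carrying a
  perimeter artifact.
* **Patch truncation**: patches are evaluated per window; a patch spanning
  two cells counts in both, truncated at each window, consistent with
  treating every cell as a landscape.
* **Determinism**: patch labels follow row-major first-pixel order; all
  simulation randomness flows from named `numpy` generator streams; pipeline
  manifests carry SHA-256 hashes and reruns reproduce them bit-exactly.
* **Raster format**: Esri AAIGrid with `.prj` sidecars. Geographic
  (degree-unit) CRSs are rejected with a reprojection hint, since all
  metrics are per unit ground area. GeoTIFF, reprojection, resampling and
  mosaicking are out of scope.

## Problem sizes

The validation suite exercises the full pipeline on a 2000×2000-pixel
scenario (10,000 cells of 20×20 pixels), regression calibration on 100
replicated fits at n = 5000 plus 200 null fits at n = 1000, and exact
oracle comparisons on hundreds of ≤ 30×30 windows — sizes chosen so the
whole suite completes in well under a minute on one core while leaving every
code path, including file round-trips, covered.

## Known limitations

Headline global statistics from 30 m satellite products (area shares of
fragmentation levels, country tables) are input-bound and outside what
synthetic validation can reproduce; the package validates the procedure,
not those numbers. The FFI normalization is a documented pooled-percentile
min–max; other plausible schemes (z-scores, per-epoch bounds) would change
absolute FFI values though not the qualitative orderings the tests assert.
Driver fits are associational OLS without spatial-autocorrelation
corrections.
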