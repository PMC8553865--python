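# Methods

## Model and assumptions

The package counts crop cycles per pixel-year by reconstructing the annual
EVI trajectory with a sixth-order polynomial and counting its screened
maxima. The modelling assumptions are:

* Each crop cycle produces one pronounced greenness peak; the number of
  cycles in a year is the number of genuine peaks of the annual EVI curve.
* A degree-6 polynomial is flexible enough for up to three peaks (its
  quintic derivative has at most five real roots, hence at most three
  maxima) while remaining cheap and smooth; intensities above 3 are out of
  range by construction.
* The cropping season does not align with the calendar year, so the fitted
  12-month series starts at the first trough of an 18-month window rather
  than on Jan 1.

## Pipeline and numerical choices

**Time axis.** Composites sit at day-of-year 1, 17, …, 353 — 23 per
calendar year, 16 days apart. The day axis is anchored at Jan 1 of the
first data year; calendar years (including leap years) set the per-year
offsets.

**QC masking and gap filling.** Observations whose reliability flag is not
in the acceptable set (default {0, 1}, the MODIS pixel-reliability "good"
and "marginal" codes; configurable because flag semantics vary by product)
are set missing and filled by linear interpolation in time. Leading and
trailing gaps take the nearest valid value — constant extension — because
linear extrapolation can leave the physical EVI range. Fewer than two valid
observations is an error the raster layer converts to nodata.

**Windowing and alignment.** The 18-month window is 6 + 23 + 6 = 35
composites ("three months" of flanking data = 6 × 16 = 96 days). The
alignment start is the first local minimum of the lightly smoothed window
(3-point moving average, used only for locating the start) within the
first 12 composites, so a full 23-composite series always fits; ties take
the earliest index, and if no local minimum exists there the global
minimum of the search range is used. A local minimum qualifies only if it
lies within 0.02 EVI of the lowest smoothed value in the search range:
a window that opens on the falling or rising limb of the previous season
also satisfies the neighbour tests at its first sample, but sits well above
the true inter-season trough; the 0.02 tolerance (the scale of the default
observation noise) rejects such shoulder points. On flat baselines the
start index is decided by numerically tiny differences, so alignment is
shift-equivariant only while the trough stays inside the search range —
the property tests phase their seasons accordingly.

**Fitting.** Time is normalised to u ∈ [0, 1] before fitting (the raw
degree-6 Vandermonde system over day counts is catastrophically
ill-conditioned); least squares is solved by `numpy.linalg.lstsq`, and the
residual standard error δ = √(RSS/(n − 7)) with n = 23. Derivative roots
come from the companion-matrix eigenvalue method; a root is real if
|Im| ≤ 1e−9·max(1, |Re|), duplicates within 1e−6 are merged, roots at the
interval endpoints are excluded (endpoint maxima are truncation artefacts,
not seasons), and a vanishing second derivative (saddle) is not counted.

**Peak screening.** A maximum counts as a crop cycle iff its fitted value
exceeds 0.35 EVI, it rises more than 0.01 EVI above its valleys (the
shallower side by default; `depth_rule="either"` available), and its cycle
lasts longer than 90 days. The duration is measured as the full cycle
span, left valley to right valley. This is a deliberate design choice: a
12-month fit with three maxima necessarily places peak-to-valley gaps near
50–60 days, so testing each side separately against a 3-month bar would
make triple cropping undetectable by construction, while the cycle span of
a genuine season (~100–170 days as fitted) clears it and the short wiggles
of an overfitted curve do not. The per-side rule remains available as
`duration_rule="min_side"`. Where a maximum has no interior minimum on one
side, the fitted value at the corresponding end of the 12-month interval
serves as the valley.

**Quality band.** Three conditions per pixel-year: (1) at least half the
labeled year's 23 composites carried acceptable flags; (2) at most 11 of
them were gap-filled; (3) the intensity decision is unchanged after
lowering all fitted peak values and peak-valley depths by δ. Condition 3
operationalises "the decision should hold within the fit's error margin"
as one-sided decision stability: lowering is the direction that can lose
peaks, so it probes exactly the marginal cases; durations are left alone
because δ is in EVI units, not days. The QC code is 3 minus the number of
satisfied conditions (0 best … 3 poor).

**Rasters.** GeoTIFF I/O is built on tifffile with explicit
ModelPixelScale/ModelTiepoint/GeoKeyDirectory/GDAL-nodata tags; only
north-up grids are supported (no reprojection). Output maps are uint8 with
nodata 255 — the archive convention for small categorical rasters. Scene
processing streams row blocks from memory-mapped files, and results are
independent of the block size. Modal upscaling resolves ties to the lower
intensity (conservative). Composite dates come from a `dates.json` sidecar
or from `YYYY-MM-DD`/`YYYYDDD` filename patterns.

**Validation statistics.** OA comparison uses the pooled two-proportion
z-test. Region means are unweighted over valid cropland pixels. Trend signs
use the OLS slope over all years (robust to single-year noise); a zero
slope counts as increasing. The change ratio is endpoint-relative,
(last − first)/first. Accuracy on labelled samples is computed over the
class subset the caller declares (cropland samples are typically {1, 2, 3}).

## Synthetic data: what it emulates, and what it does not

A pixel-year is a baseline EVI (default 0.12, bare-soil level) plus one
Gaussian pulse per crop cycle, with additive Gaussian noise (default
sd 0.02) and cloud contamination (default probability 0.10 per
observation: the flag becomes unacceptable and the value is replaced by a
low draw in [−0.1, 0.1], mimicking cloud-darkened EVI). Defaults per class:

| cycles | season centres (DOY) | pulse sd (d) | amplitude draw |
|--------|----------------------|--------------|----------------|
| 1      | 200                  | 30           | U[0.45, 0.80]  |
| 2      | 130, 270             | 30           | U[0.45, 0.80]  |
| 3      | 61, 183, 305         | 20           | U[0.60, 0.80]  |

Single/double centres are generic northern-hemisphere seasons with
spacings well beyond the 90-day duration screen. The triple-crop defaults
encode what real triple cropping (e.g. triple rice) looks like and what
the method can resolve: cycles spread evenly through the year (365/3 ≈
122-day spacing — a degree-6 polynomial can only produce three maxima when
they span the whole fitting interval), pulses narrow enough that the field
returns near baseline between harvests, and high, uniform amplitudes
typical of intensive irrigated systems. The fit attenuates the middle of
three peaks strongly (a 0.57 data peak fits near 0.35), so low-amplitude
triple cropping is genuinely outside the method's detection envelope; the
generator's class-3 defaults deliberately sit inside it.

Scenes draw classes i.i.d. per pixel from a mixture, give cropland pixels
probabilities above the 10% masking threshold and non-cropland pixels
probabilities below it (with baseline-only vegetation).

The generator does **not** emulate: spatial autocorrelation of fields and
clouds, multi-day consecutive cloud outages, inter-annual rotation,
double-logistic green-up/senescence asymmetry, mixed pixels at field
boundaries, or sensor view-angle effects. Passing tests therefore show the
algorithmic chain is correct and robust to independent noise and isolated
gaps — not that the accuracy figures transfer to real MODIS scenes, where
correlated cloud outages and mixed pixels dominate the error budget.

## Problem sizes used in tests

The test and acceptance suites run entirely on synthetic data at desk
scale: label-recovery checks use 100 clean and 1,000 noisy pixels per
class, root-finder/oracle agreement uses 500 random fits against a
10,001-point grid, the maxima bound is brute-forced over 10,000 random
coefficient draws, and raster round-trips use a 64×64 scene — sizes at
which every statistical criterion is well resolved while the whole suite
runs in well under a minute of compute per heavy test.

## Known limitations

* Intensities above 3 cannot be represented (degree-6 bound).
* The duration screen keys on the fitted curve, whose extrema positions
  are strongly shaped by the polynomial's rigidity; cycle spans inherit
  ~±10-day biases from it.
* Alignment on flat (fallow or constant) windows is tie-broken, not
  determined; downstream results are unaffected because such windows carry
  no valid peaks.
* Masked-then-filled stretches longer than a few composites reconstruct a
  straight line; a whole cloudy season is invisible (condition 2 of the QC
  band exists precisely to flag this).
* Only north-up, same-grid rasters are handled; reprojection, mosaicking
  and CRS transforms are out of scope.
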