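# cropcycles

Annual cropping-intensity mapping from 16-day EVI time series.

Cropping intensity — the number of crop cycles harvested from the same
field in one year (0–3) — is a key variable for harvest-area accounting,
yield estimation and food-security analysis. `cropcycles` derives it per
pixel from an enhanced vegetation index (EVI) record of the kind the MODIS
MOD13Q1 product provides (23 sixteen-day composites per year, int16 values
scaled by 10⁻⁴, with a per-observation reliability flag), and ships the
synthetic-data, raster and validation tooling needed to exercise and assess
the method without downloading any satellite archive.

## Method

The enhanced vegetation index is

```
EVI = 2.5 · (ρ_NIR − ρ_Red) / (ρ_NIR + 6·ρ_Red − 7.5·ρ_Blue + 1)
```

For each pixel-year the pipeline:

1. masks observations with unacceptable reliability flags and fills the
   gaps by linear interpolation in time;
2. extracts an 18-month window (6 composites before the year, its 23
   composites, 6 after — 35 samples) and cuts the 12-month series that
   starts at the window's first trough, the start of the cropping season;
3. fits a sixth-order polynomial
   `EVI(t) = a₀ + a₁t + … + a₆t⁶` on normalised time and locates its
   stationary points analytically from EVI′(t) = 0, classified by the sign
   of EVI″(t) — a degree-6 polynomial has at most 3 maxima, matching the
   0–3 intensity range;
4. screens each fitted maximum with three thresholds (peak EVI > 0.35,
   peak-valley depth > 0.01, cycle duration > three months) to remove false
   peaks from non-crop vegetation and overfitting; the number of surviving
   peaks, capped at 3, is the intensity;
5. grades the result with a quality code 0–3 ("best" … "poor") counting
   three failed conditions: flag quality of the year, gap-fill count
   (≤ 11 of 23), and stability of the decision when the fitted curve is
   perturbed by its residual standard error δ = √(RSS/(n−7)).

Raster tooling applies this per pixel over GeoTIFF stacks inside a cropland
mask (cropland probability > 10%), writes uint8 intensity and QC maps
(nodata 255), upscales by modal aggregation and differences maps. The
validation module implements confusion-matrix overall accuracy (OA),
a pooled two-proportion z-test for comparing OAs, per-pixel scatter
regression, difference-map agreement statistics, and country-level
consistency against a statistical cropping intensity
(harvested area ÷ cropland area): Pearson correlation, endpoint change
ratios and a 4-type trend classification.

## Worked example

`examples/01_single_pixel.py` simulates a double-cropping pixel (two
Gaussian greenness pulses per year, 2% noise, 10% cloud gaps) and runs the
full pipeline:

```
record: 69 composites over 3 years, 9 cloud-flagged
aligned 12-month series starts at the season trough; 2 of 23 in-year composites gap-filled
degree-6 fit: residual standard error delta = 0.1526 EVI
  fitted peak at day 112.8, EVI 0.640
  fitted peak at day 279.2, EVI 0.566
cropping intensity = 2 (truth 2), QC = 0 (0=best..3=poor), conditions (True, True, True)
```

Both fitted peaks clear the amplitude/depth/duration screens, so the pixel
is classified double cropping; all three quality conditions hold, so the QC
grade is "best". The other examples cover scene-to-map production
(`02_scene_to_maps.py`), accuracy assessment and map comparison
(`03_map_validation.py`) and country-level statistics
(`04_country_statistics.py`). A thin CLI wraps the same library calls:
`cropcycles simulate | intensity | validate | compare`.

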