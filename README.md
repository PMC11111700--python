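# vigapfill

Reconstruction of **daily, gap-free vegetation-index (NDVI) series** from
long, contaminated satellite records — the AVHRR/VIIRS-era daily NDVI at
0.05°, where cloud contamination and orbital/processing dropouts leave a
large share of pixel-days missing or unreliable.

`vigapfill` implements a two-part framework as a tested library with a thin
command-line interface:

1. **Valid-data identification.** A sliding three-month window (the
   *fundamental processing unit*, FPU) is centered on each target month.
   From the monthly maxima `NDVI_max` of the previous, target and next
   months, a reference set of five numbers is built,

   `V_max = {M_prev, M_tgt, M_next, (M_prev+M_tgt)/2, (M_tgt+M_next)/2}`,

   and a day with value *y* is **valid** when its percent bias against at
   least one reference is within the threshold *T*₁:

   `min_ref |(y − ref)/ref| × 100 ≤ T₁`  (default *T*₁ = 20%).

   A whole month is invalidated when it contains no data, or when the
   percent bias between its maximum and the mean maximum of the same
   calendar month in the adjacent four years (y±1, y±2) exceeds *T*₂
   (default 39%). Both thresholds can be re-derived from any multi-year
   monthly-maximum reference with `calibrate_thresholds`.

2. **Segmented quartic gap-filling.** Each pixel-year is split at the date
   of its maximum valid value. The *growth* side is fitted by a degree-4
   polynomial over the valid data from the previous October–December
   through the peak; the *withering* side over the data from the peak
   through the following January–March. The two fitted curves replace the
   daily series; days under an unfittable segment take the mean
   reconstructed value of the same calendar day in the adjacent four
   years. The output has no missing values.

Evaluation follows the standard five criteria per pixel — Pearson *r*,
*R*² = 1 − SS_res/SS_tot, MAE, RMSE and percent bias
PB = mean((Y_rec − Y_obs)/Y_obs)·100% — plus quality-rule classification
(e.g. high quality ⇔ |PB| < 1% ∧ RMSE < 0.08 ∧ *R*² > 0.5), latitudinal
profiles, monthly maximum-value composites (MVC) and nearest-neighbour
regridding for comparison against monthly products.

A first-class **synthetic scene generator** produces double-logistic
seasonal truth with seeded contamination (dropouts, multiplicative cloud
depression, positive spikes, month-scale transition gaps) and a per-value
ledger, so every stage is testable against exact ground truth.

## Worked example

```python
import numpy as np
import vigapfill as vg

scene = vg.default_scene(nlat=8, nlon=8, years=range(2001, 2004), seed=42)
mask = vg.identify_valid(scene.observed)
recon, report = vg.reconstruct_cube(scene.observed, mask)
m = vg.pixelwise_metrics(recon, scene.truth)
print(scene.observed.n_missing, recon.n_missing,
      round(float(np.nanmedian(m["r2"])), 3))
```

prints `35848 0 0.959`: the contaminated input is missing 35,848
pixel-days, the reconstruction has none, and the median per-pixel *R*²
against the noiseless truth is 0.959 — the fitted curves recover almost
all of the true seasonal signal despite half the days being dropped and a
fifth of the rest cloud-depressed. The `examples/` directory walks through
each capability (simulation, screening, reconstruction, evaluation,
threshold calibration) with commented output.

The same pipeline is available from the shell:

```sh
vigapfill simulate --nlat 8 --nlon 8 --years 2001:2004 --seed 42 --out scene/
vigapfill run --input scene/observed.nc4 --out-dir out/
```

which writes per-year files named `Daily_Gap-filled_NDVI_YYYY.nc4` and a
JSON run report.

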