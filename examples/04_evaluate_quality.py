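"""Evaluate a reconstruction: per-pixel metrics, quality classes, profiles.

Five criteria (r, R^2, MAE, RMSE, percent bias) are computed per pixel;
the "self" quality rule (|PB| < 1%, RMSE < 0.08, R^2 > 0.5) classifies
pixels as high quality; latitudinal profiles and monthly maximum-value
composites support comparisons with coarser monthly products.
"""

import numpy as np

import vigapfill as vg
from vigapfill.cli import _align_mask, _align_reference

scene = vg.default_scene(nlat=8, nlon=8, years=range(2001, 2004), seed=42)
mask = vg.identify_valid(scene.observed)
recon, _ = vg.reconstruct_cube(scene.observed, mask)

# self-validation: compare only on days the screen labeled valid
ref = _align_reference(scene.observed, recon)
m = vg.pixelwise_metrics(recon, ref, mask=_align_mask(mask, recon))
print(f"reconstruction vs original valid observations "
      f"(mean over {m['r2'].size} pixels):")
print(f"  R^2 {np.nanmean(m['r2']):.3f}   RMSE {np.nanmean(m['rmse']):.3f}   "
      f"PB {np.nanmean(m['pb']):+.2f}%")

ok, prop = vg.quality_classification(m, "self")
print(f"high-quality area (|PB|<1%, RMSE<0.08, R^2>0.5): {100 * prop:.1f}%")

prof = vg.latitudinal_profile(m["rmse"], recon.grid)
print("latitudinal RMSE profile (first three grid rows):")
print(prof.head(3).to_string(index=False))

monthly = vg.mvc_monthly_composite(recon)
print(f"monthly maximum-value composite: {monthly.shape} (month, lat, lon), "
      f"gap-free: {bool(np.isfinite(monthly.values).all())}")

coarse = vg.GridSpec(recon.grid.lat_min, recon.grid.lat_max,
                     recon.grid.lon_min, recon.grid.lon_max, cell_size=0.1)
out = vg.regrid_nearest(recon, coarse)
print(f"nearest-neighbour regrid 0.05 -> 0.1 degree: {out.values.shape[1:]} cells")
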