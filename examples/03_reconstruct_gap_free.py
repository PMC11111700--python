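"""Reconstruct a gap-free daily series by segmented quartic fitting.

Each pixel-year is split at its greenness peak; the rising limb is
fitted together with the previous October-December valid data, the
falling limb with the following January-March, each by a degree-4
polynomial. Remaining unfittable days take the mean reconstructed value
of the same calendar day in the adjacent four years.
"""

import numpy as np

import vigapfill as vg

scene = vg.default_scene(nlat=8, nlon=8, years=range(2001, 2004), seed=42)
mask = vg.identify_valid(scene.observed)
recon, report = vg.reconstruct_cube(scene.observed, mask)

print(f"input missing values:  {scene.observed.n_missing}")
print(f"output missing values: {recon.n_missing}  (gap-free by construction)")
print(f"segments fitted: {report['n_segments_fitted']}, "
      f"fallbacks: {report['n_segments_fallback']}, "
      f"adjacent-year filled days: {report['n_gap_filled_values']}")
print(f"mean |jump| where the two fits meet at the peak: "
      f"{report['peak_discontinuity_mean']:.3f} NDVI")

m = vg.pixelwise_metrics(recon, scene.truth)
print(f"median per-pixel R^2 against the noiseless truth: "
      f"{np.nanmedian(m['r2']):.3f} "
      "(how much of the true seasonal signal the reconstruction recovers)")
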