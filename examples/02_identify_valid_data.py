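"""Screen a daily cube into valid / invalid / missing observations.

Stage 1 compares each day against its three-month window's reference set
V_max (monthly maxima and their pairwise means) with a 20% percent-bias
threshold; stage 2 invalidates whole months whose maximum departs from
the same calendar month of the adjacent four years by more than 39%.
"""

import vigapfill as vg

scene = vg.default_scene(nlat=8, nlon=8, years=range(2001, 2004), seed=42)
mask = vg.identify_valid(scene.observed, vg.IdentificationConfig(t1=20, t2=39))

print(f"valid fraction of observed days: {mask.valid_fraction:.3f}")
print(f"months flagged invalid: {int(mask.month_invalid().sum())} "
      f"of {mask.month_reason.size} pixel-months")

score = vg.score_identification(mask, scene)
print(f"contamination detection vs the ledger: "
      f"recall {score['recall']:.3f}, precision {score['precision']:.3f}")
print("(recall = share of cloud-depressed/spiked days caught; precision is "
      "diluted by whole-month invalidation, which also discards clean days)")
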