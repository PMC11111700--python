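"""Derive the T1/T2 screening thresholds from a monthly-maximum record.

T1 is the average percent bias between adjacent months' maxima (how much
NDVI typically moves month to month); T2 is the average of each pixel's
worst adjacent-month percent bias (how much it can move in the fastest
season). On the long real-world monthly reference these come out near
20% and 39%, the defaults used by the screen.
"""

import vigapfill as vg

truth = vg.simulate_truth(vg.GridSpec.toy(8, 8), range(2001, 2011), seed=0)
mm = vg.monthly_maxima(truth)
t1, t2 = vg.calibrate_thresholds(mm)
print(f"ten years of synthetic seasonal truth ({mm.maxima.shape[0]} months, "
      f"{mm.maxima.shape[1] * mm.maxima.shape[2]} pixels):")
print(f"  T1 estimate (mean adjacent-month |PB|):        {t1:6.2f}%")
print(f"  T2 estimate (mean per-pixel max adjacent |PB|): {t2:6.2f}%")
print("T2 > T1 because the month-level screen must tolerate the steepest "
      "seasonal transition a pixel exhibits.")
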