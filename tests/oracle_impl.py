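"""Independent brute-force oracles used by the test suite.

Everything here is written as literal scalar loops, deliberately sharing
no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_identify(times: pd.DatetimeIndex, values: np.ndarray,
                         t1: float = 20.0, t2: float = 39.0) -> np.ndarray:
    """Literal two-stage screen for a (time, lat, lon) array.

    Returns labels 0=missing, 1=valid, 2=invalid.
    """
    nlat, nlon = values.shape[1], values.shape[2]
    labels = np.zeros(values.shape, dtype=np.uint8)
    months = pd.period_range(times[0].to_period("M"),
                             times[-1].to_period("M"), freq="M")
    month_of_day = [months.get_loc(t.to_period("M")) for t in times]

    for i in range(nlat):
        for j in range(nlon):
            # monthly maxima in one pass over the days
            mx: list[float | None] = [None] * len(months)
            for k in range(len(times)):
                v = values[k, i, j]
                if np.isfinite(v):
                    m = month_of_day[k]
                    if mx[m] is None or v > mx[m]:
                        mx[m] = float(v)

            # stage-2 month flags
            month_bad = []
            for m, period in enumerate(months):
                if mx[m] is None:
                    month_bad.append(True)
                    continue
                neigh = []
                for dy in (-2, -1, 1, 2):
                    for m2, p2 in enumerate(months):
                        if p2.year == period.year + dy and p2.month == period.month:
                            if mx[m2] is not None:
                                neigh.append(mx[m2])
                if neigh:
                    ref = sum(neigh) / len(neigh)
                    if ref != 0 and abs((mx[m] - ref) / ref) * 100.0 > t2:
                        month_bad.append(True)
                        continue
                month_bad.append(False)

            # stage-1 day screen + stage-2 override
            for k in range(len(times)):
                v = values[k, i, j]
                if not np.isfinite(v):
                    continue
                m = month_of_day[k]
                prev_mx = mx[m - 1] if m > 0 else None
                next_mx = mx[m + 1] if m < len(months) - 1 else None
                refs = []
                for r in (prev_mx, mx[m], next_mx):
                    if r is not None:
                        refs.append(r)
                if prev_mx is not None and mx[m] is not None:
                    refs.append((prev_mx + mx[m]) / 2.0)
                if mx[m] is not None and next_mx is not None:
                    refs.append((mx[m] + next_mx) / 2.0)
                ok = False
                for r in refs:
                    if r != 0 and abs((v - r) / r) * 100.0 <= t1:
                        ok = True
                        break
                labels[k, i, j] = 1 if ok else 2
                if month_bad[m]:
                    labels[k, i, j] = 2
    return labels


def normal_equations_quartic(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Degree-4 least squares by explicitly solving the normal equations.

    Uses its own affine rescaling of t for conditioning and returns the
    fitted values at the sample points.
    """
    t = np.asarray(t, dtype=float)
    mid = (t.min() + t.max()) / 2.0
    half = (t.max() - t.min()) / 2.0
    x = (t - mid) / half
    X = np.vander(x, 5, increasing=True)
    coeffs = np.linalg.solve(X.T @ X, X.T @ np.asarray(v, dtype=float))
    return X @ coeffs
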