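"""Synthetic AVHRR-like daily VI scenes with known truth.

The generator produces per-pixel double-logistic seasonal trajectories
(smooth, gap-free "truth") and then contaminates them the way long daily
satellite VI records are contaminated:

* month-scale total gaps emulating short no-data periods around satellite
  hand-overs,
* random daily dropouts (orbit/swath/processing losses),
* negatively biased cloud contamination (multiplicative depression of the
  true value),
* occasional positive spikes.

Every altered value is recorded in a ledger, so screening and
reconstruction quality can be scored against exact ground truth.
A degree-4 polynomial truth generator is also provided: the segment
fitter can represent such truth exactly, which makes exact-recovery
checks well posed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .identification import LABEL_INVALID, ValidityMask
from .io_grid import DailyVICube, GridSpec

__all__ = [
    "PhenologyParams",
    "ContaminationParams",
    "SyntheticScene",
    "LEDGER_CLEAN",
    "LEDGER_DROPPED",
    "LEDGER_DEPRESSED",
    "LEDGER_SPIKED",
    "LEDGER_TRANSITION_GAP",
    "simulate_truth",
    "simulate_quartic_truth",
    "contaminate",
    "score_identification",
    "default_scene",
]

LEDGER_CLEAN = np.uint8(0)
LEDGER_DROPPED = np.uint8(1)
LEDGER_DEPRESSED = np.uint8(2)
LEDGER_SPIKED = np.uint8(3)
LEDGER_TRANSITION_GAP = np.uint8(4)

_LEDGER_NAMES = {0: "clean", 1: "dropped", 2: "depressed",
                 3: "spiked", 4: "transition-gap"}


@dataclasses.dataclass(frozen=True)
class PhenologyParams:
    """Double-logistic seasonal curve parameters for one pixel.

    base: winter VI level; amplitude: summer rise above base;
    green_up_day / senescence_day: inflection days-of-year;
    green_up_rate / senescence_rate: logistic steepness (1/days);
    interannual_jitter: fractional standard deviation applied
    multiplicatively to amplitude and to the two inflection dates each
    year (so a 0.03 jitter shifts green-up around day 120 by ~3.6 days,
    1 sigma).
    """

    base: float = 0.15
    amplitude: float = 0.55
    green_up_day: float = 120.0
    senescence_day: float = 280.0
    green_up_rate: float = 0.10
    senescence_rate: float = 0.08
    interannual_jitter: float = 0.03

    def __post_init__(self) -> None:
        if self.base < 0 or self.base + self.amplitude > 1:
            raise ValueError("need 0 <= base and base + amplitude <= 1")
        if self.green_up_day >= self.senescence_day:
            raise ValueError("green-up must precede senescence")


@dataclasses.dataclass(frozen=True)
class ContaminationParams:
    """Contamination process settings.

    Applied in order: transition gaps (whole-cube no-data runs), daily
    dropouts, cloud depressions (value multiplied by a factor drawn from
    depression_range), positive spikes (clamped to 1). Rates are
    fractions of the remaining (not yet removed) days.
    """

    dropout_rate: float = 0.5
    cloud_rate: float = 0.2
    depression_range: tuple[float, float] = (0.3, 0.7)
    spike_rate: float = 0.01
    spike_max: float = 0.3
    transition_gaps: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.dropout_rate, self.cloud_rate, self.spike_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.depression_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("depression factors must lie in (0, 1)")


@dataclasses.dataclass
class SyntheticScene:
    """Truth + contaminated observation + per-value ledger.

    ledger_code is (time, lat, lon) uint8 (see LEDGER_* constants);
    ledger_factor holds the depression factor or spike delta where
    applicable, NaN elsewhere.
    """

    truth: DailyVICube
    observed: DailyVICube
    ledger_code: np.ndarray
    ledger_factor: np.ndarray

    def ledger_frame(self) -> pd.DataFrame:
        """Non-clean ledger entries as a tidy table (CSV-friendly)."""
        t, i, j = np.nonzero(self.ledger_code != LEDGER_CLEAN)
        return pd.DataFrame({
            "date": self.truth.times[t],
            "lat_idx": i,
            "lon_idx": j,
            "kind": [_LEDGER_NAMES[int(c)] for c in self.ledger_code[t, i, j]],
            "factor": self.ledger_factor[t, i, j],
        })


def _double_logistic(doy: np.ndarray, base: float, amplitude: float,
                     gu_day: float, sen_day: float,
                     gu_rate: float, sen_rate: float) -> np.ndarray:
    rise = 1.0 / (1.0 + np.exp(-gu_rate * (doy - gu_day)))
    fall = 1.0 / (1.0 + np.exp(sen_rate * (doy - sen_day)))
    return base + amplitude * rise * fall


def simulate_truth(grid: GridSpec, years: range,
                   params: PhenologyParams | None = None,
                   seed: int = 0) -> DailyVICube:
    """Smooth gap-free truth: a jittered double-logistic curve per pixel-year.

    Pixel-to-pixel variation comes from jittering the base parameters per
    pixel; interannual variation from re-jittering amplitude and
    inflection dates per year. Deterministic for a given seed.
    """
    params = params or PhenologyParams()
    rng = np.random.default_rng(seed)
    times = pd.date_range(pd.Timestamp(years.start, 1, 1),
                          pd.Timestamp(years.stop - 1, 12, 31), freq="D")
    nlat, nlon = grid.lat_count, grid.lon_count
    out = np.empty((len(times), nlat, nlon))

    jit = params.interannual_jitter
    base_px = params.base * (1 + jit * rng.standard_normal((nlat, nlon)))
    amp_px = params.amplitude * (1 + jit * rng.standard_normal((nlat, nlon)))
    gu_px = params.green_up_day + 10.0 * rng.standard_normal((nlat, nlon))
    sen_px = params.senescence_day + 10.0 * rng.standard_normal((nlat, nlon))

    doy = times.dayofyear.to_numpy(dtype=float)
    year_of = times.year.to_numpy()
    for year in years:
        sel = year_of == year
        amp_y = amp_px * (1 + jit * rng.standard_normal((nlat, nlon)))
        gu_y = gu_px * (1 + jit * rng.standard_normal((nlat, nlon)))
        sen_y = sen_px * (1 + jit * rng.standard_normal((nlat, nlon)))
        d = doy[sel][:, None, None]
        curve = _double_logistic(d, base_px[None], amp_y[None], gu_y[None],
                                 sen_y[None], params.green_up_rate,
                                 params.senescence_rate)
        out[sel] = curve
    out = np.clip(out, 0.0, 1.0)
    return DailyVICube(grid, times, out)


def simulate_quartic_truth(grid: GridSpec, years: range,
                           seed: int = 0) -> DailyVICube:
    """Truth polynomial (degree <= 4) in absolute time, one polynomial per pixel.

    Any contiguous window of such truth is itself a quartic in days, so a
    degree-4 segment fit with enough support reproduces it exactly. Each
    pixel's polynomial is a downward-opening quartic peaked near the
    middle of the record (strictly increasing before the peak, strictly
    decreasing after), which guarantees every calendar year's maximum is
    either interior or at a year boundary with a long fittable segment on
    each side. Values are scaled into [0.1, 0.9].
    """
    rng = np.random.default_rng(seed)
    times = pd.date_range(pd.Timestamp(years.start, 1, 1),
                          pd.Timestamp(years.stop - 1, 12, 31), freq="D")
    nlat, nlon = grid.lat_count, grid.lon_count
    npix = nlat * nlon
    x = np.linspace(-1.0, 1.0, len(times))[:, None]  # scaled absolute time
    x0 = rng.uniform(-0.4, 0.4, size=npix)           # peak location
    a2 = rng.uniform(0.2, 1.0, size=npix)
    a4 = rng.uniform(0.05, 0.5, size=npix)
    d = x - x0[None, :]
    vals = -(a2[None, :] * d**2) - a4[None, :] * d**4
    lo = vals.min(axis=0, keepdims=True)
    hi = vals.max(axis=0, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    vals = 0.1 + 0.8 * (vals - lo) / span
    return DailyVICube(grid, times, vals.reshape(len(times), nlat, nlon))


def contaminate(truth: DailyVICube, params: ContaminationParams | None = None
                ) -> SyntheticScene:
    """Apply transition gaps, dropouts, depressions and spikes to truth.

    The ledger records exactly one cause per (pixel, date); observed
    equals truth wherever the ledger says clean. Spiked values are
    clamped to 1.
    """
    params = params or ContaminationParams()
    rng = np.random.default_rng(params.seed)
    obs = truth.values.copy()
    code = np.zeros(obs.shape, dtype=np.uint8)
    factor = np.full(obs.shape, np.nan)
    times = truth.times

    for start, length in params.transition_gaps:
        start = pd.Timestamp(start)
        in_gap = (times >= start) & (times < start + pd.Timedelta(days=int(length)))
        obs[in_gap] = np.nan
        code[in_gap] = LEDGER_TRANSITION_GAP

    untouched = code == LEDGER_CLEAN
    drop = untouched & (rng.random(obs.shape) < params.dropout_rate)
    obs[drop] = np.nan
    code[drop] = LEDGER_DROPPED

    untouched = code == LEDGER_CLEAN
    cloud = untouched & (rng.random(obs.shape) < params.cloud_rate)
    lo, hi = params.depression_range
    f = rng.uniform(lo, hi, size=obs.shape)
    obs[cloud] = obs[cloud] * f[cloud]
    factor[cloud] = f[cloud]
    code[cloud] = LEDGER_DEPRESSED

    untouched = code == LEDGER_CLEAN
    spike = untouched & (rng.random(obs.shape) < params.spike_rate)
    delta = rng.uniform(0.05, params.spike_max, size=obs.shape)
    spiked_vals = np.minimum(obs + delta, 1.0)
    factor[spike] = spiked_vals[spike] - truth.values[spike]  # realized delta
    obs[spike] = spiked_vals[spike]
    code[spike] = LEDGER_SPIKED

    observed = DailyVICube(truth.grid, times, obs, name=truth.name, validate=False)
    return SyntheticScene(truth=truth, observed=observed,
                          ledger_code=code, ledger_factor=factor)


def score_identification(mask: ValidityMask, scene: SyntheticScene
                         ) -> dict[str, float]:
    """Precision/recall of the mask's invalid label against the ledger.

    Ground-truth invalid = depressed or spiked days (contaminated but
    observed); ground-truth valid = clean days. Dropped / transition-gap
    days are missing in the observation and excluded from scoring.
    """
    if mask.labels.shape != scene.ledger_code.shape:
        raise ValueError("mask and scene are not aligned")
    truth_bad = np.isin(scene.ledger_code, (LEDGER_DEPRESSED, LEDGER_SPIKED))
    truth_good = scene.ledger_code == LEDGER_CLEAN
    pred_bad = mask.labels == LABEL_INVALID
    tp = int((truth_bad & pred_bad).sum())
    fp = int((truth_good & pred_bad).sum())
    fn = int((truth_bad & ~pred_bad).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": float(precision), "recall": float(recall),
            "tp": tp, "fp": fp, "fn": fn}


def default_scene(nlat: int = 20, nlon: int = 20,
                  years: range = range(2001, 2004),
                  seed: int = 42) -> SyntheticScene:
    """The standard test scene: 20x20 pixels, three years, 50% dropout,
    20% cloud depression (factors 0.3-0.7), 1% spikes, one 30-day
    mid-record transition gap."""
    grid = GridSpec.toy(nlat, nlon)
    truth = simulate_truth(grid, years, seed=seed)
    mid_year = years.start + (years.stop - 1 - years.start) // 2
    params = ContaminationParams(
        dropout_rate=0.5, cloud_rate=0.2, depression_range=(0.3, 0.7),
        spike_rate=0.01, transition_gaps=((f"{mid_year}-01-10", 30),),
        seed=seed + 1,
    )
    return contaminate(truth, params)
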