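"""Plate-reader kinetics: promoter activity, growth rate, phase calls, Fmax.

A whole-cell biosensor read in a plate reader yields, per well, an OD600
growth curve and a reporter fluorescence curve sampled on a shared time
grid.  The derived quantities are all forward difference quotients on that
grid:

* normalized fluorescence  (Fluo_s - Fluo_b) / (OD_s - OD_b), the reporter
  concentration per unit culture density;
* promoter activity  f(t) = (1/OD_n) * (Fluo_{n+1} - Fluo_n)/(t_{n+1}-t_n),
  the per-density protein synthesis rate, with an un-normalized variant
  dfluo/dt for low-density cultures where dividing by OD amplifies noise;
* growth rate  dOD/dt as the same forward difference of OD600;
* growth-phase labels (lag / exponential / stationary) from the specific
  growth rate mu(t) = d ln(OD)/dt;
* Fmax, the maximum promoter activity restricted to the exponential phase,
  which is the dose-response summary statistic per inducer concentration.

Forward differences are used deliberately (not central differences) so that
a generative model writing Fluo(t+dt) = Fluo(t) + f * OD(t) * dt is inverted
exactly on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PlateTimeSeries

#: OD differences below this are treated as indistinguishable from blank.
OD_FLOOR = 0.005

LAG, EXPONENTIAL, STATIONARY = "lag", "exponential", "stationary"


class KineticsError(ValueError):
    pass


@dataclass
class ActivityTrace:
    """Derived kinetics for one well.

    All rate-like series live on the left endpoints of the difference
    intervals, so ``times_h`` is one point shorter than the raw grid.
    Points masked for low OD are NaN, never fabricated.
    """

    well_id: str
    times_h: np.ndarray
    fluo_over_od: np.ndarray      # AFU per OD unit
    activity: np.ndarray          # AFU * OD^-1 * h^-1
    raw_rate: np.ndarray          # AFU * h^-1
    growth_rate: np.ndarray       # OD * h^-1
    phases: list[str]
    f_max: float
    max_growth_rate: float


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise KineticsError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise KineticsError("time vector must be strictly increasing")
    return times


def normalize_fluorescence(sample_fluo, sample_od, blank_fluo, blank_od,
                           od_floor: float = OD_FLOOR) -> np.ndarray:
    """Blank-corrected fluorescence per unit culture density.

    Pointwise (Fluo_s - Fluo_b) / (OD_s - OD_b).  Time points where the
    blank-corrected OD falls below ``od_floor`` are returned as NaN; if
    every point is masked the culture is indistinguishable from blank and
    an error is raised.
    """
    fs = np.asarray(sample_fluo, dtype=float)
    fb = np.asarray(blank_fluo, dtype=float)
    od = np.asarray(sample_od, dtype=float) - np.asarray(blank_od, dtype=float)
    out = np.full_like(fs, np.nan, dtype=float)
    ok = np.abs(od) >= od_floor
    if not np.any(ok):
        raise KineticsError("culture indistinguishable from blank "
                            f"(|OD_s - OD_b| < {od_floor} everywhere)")
    out[ok] = (fs[ok] - fb[ok]) / od[ok]
    return out


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; endpoints that lack a full window are kept
    as-is, which leaves any locally linear series unchanged."""
    if window is None or window <= 1:
        return series
    if window % 2 == 0:
        raise KineticsError("smoothing window must be odd")
    half = window // 2
    out = series.astype(float).copy()
    for i in range(half, len(series) - half):
        out[i] = np.mean(series[i - half:i + half + 1])
    return out


def promoter_activity(fluo, od, times, normalize: bool = True,
                      smooth_window: int | None = None,
                      od_floor: float = 0.0) -> np.ndarray:
    """Promoter activity by forward differencing of the reporter signal.

    With ``normalize`` on, each difference quotient is divided by the OD at
    the left endpoint; points with OD at or below ``od_floor`` come back as
    NaN.  ``smooth_window`` applies a centered moving average to the
    fluorescence series before differencing (off by default; the pipeline
    uses 3 points on noisy plates).
    """
    times = _check_times(times)
    fluo = _smooth(np.asarray(fluo, dtype=float), smooth_window)
    dt = np.diff(times)
    rate = np.diff(fluo) / dt
    if not normalize:
        return rate
    od_left = np.asarray(od, dtype=float)[:-1]
    out = np.full_like(rate, np.nan)
    ok = np.isfinite(od_left) & (od_left > od_floor)
    out[ok] = rate[ok] / od_left[ok]
    return out


def growth_rate(od, times) -> tuple[np.ndarray, float]:
    """Forward-difference growth rate dOD/dt and its maximum over the run.

    Negative rates are legitimate (death phase, settling); the maximum may
    therefore be interior.
    """
    times = _check_times(times)
    od = np.asarray(od, dtype=float)
    rate = np.diff(od) / np.diff(times)
    finite = rate[np.isfinite(rate)]
    if len(finite) == 0:
        raise KineticsError("no finite OD differences")
    return rate, float(np.max(finite))


def classify_phases(od, times, threshold_frac: float = 0.5) -> list[str]:
    """Label each difference interval lag / exponential / stationary.

    The specific growth rate mu(t) = d ln(OD)/dt is computed on positive,
    finite OD points.  The exponential phase is the contiguous run around
    the global maximum of mu where mu >= threshold_frac * max(mu); lag is
    everything before it, stationary everything after.  If the culture
    never grows (max mu <= 0) the whole series is stationary.
    """
    times = _check_times(times)
    od = np.asarray(od, dtype=float)
    usable = np.isfinite(od) & (od > 0)
    if usable.sum() < 3:
        raise KineticsError("fewer than 3 usable (positive, finite) OD points")

    n = len(times) - 1
    mu = np.full(n, np.nan)
    ln_od = np.where(usable, np.log(np.where(usable, od, 1.0)), np.nan)
    mu_all = np.diff(ln_od) / np.diff(times)
    mu[:] = mu_all

    finite = np.isfinite(mu)
    if not np.any(finite) or np.nanmax(mu) <= 0:
        return [STATIONARY] * n

    mu_max = np.nanmax(mu)
    cutoff = threshold_frac * mu_max
    peak = int(np.nanargmax(mu))
    lo = peak
    while lo - 1 >= 0 and np.isfinite(mu[lo - 1]) and mu[lo - 1] >= cutoff:
        lo -= 1
    hi = peak
    while hi + 1 < n and np.isfinite(mu[hi + 1]) and mu[hi + 1] >= cutoff:
        hi += 1
    return [LAG] * lo + [EXPONENTIAL] * (hi - lo + 1) + [STATIONARY] * (n - hi - 1)


def extract_fmax(trace: ActivityTrace) -> float:
    """Maximum promoter activity over the exponential phase.

    Ties break to the earliest time point.  Raises if the well never shows
    an exponential phase — check the growth curve before trusting the dose
    response of such a well.
    """
    idx = [i for i, p in enumerate(trace.phases)
           if p == EXPONENTIAL and np.isfinite(trace.activity[i])]
    if not idx:
        raise KineticsError(
            f"well {trace.well_id!r}: no exponential-phase activity points; "
            "check that the culture actually grew")
    values = trace.activity[idx]
    return float(values[int(np.argmax(values))])


def blank_series(plate: PlateTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Time-matched mean OD and fluorescence over all blank wells."""
    idx = plate.blank_indices()
    od_b = plate.od600[idx].mean(axis=0)
    if plate.fluorescence is None:
        fluo_b = np.zeros_like(od_b)
    else:
        fluo_b = plate.fluorescence[idx].mean(axis=0)
    return od_b, fluo_b


def characterize_well(plate: PlateTimeSeries, well_id: str,
                      smooth_window: int | None = 3,
                      threshold_frac: float = 0.5,
                      od_floor: float = OD_FLOOR) -> ActivityTrace:
    """Full kinetic work-up of one sample well (blank-corrected)."""
    if plate.fluorescence is None:
        raise KineticsError("plate has no fluorescence channel")
    i = plate.well_index(well_id)
    od_b, fluo_b = blank_series(plate)
    od_c = plate.od600[i] - od_b
    fluo_c = plate.fluorescence[i] - fluo_b

    norm = normalize_fluorescence(plate.fluorescence[i], plate.od600[i],
                                  fluo_b, od_b, od_floor=od_floor)
    activity = promoter_activity(fluo_c, od_c, plate.times_h, normalize=True,
                                 smooth_window=smooth_window,
                                 od_floor=od_floor)
    raw = promoter_activity(fluo_c, od_c, plate.times_h, normalize=False,
                            smooth_window=smooth_window)
    rate, max_rate = growth_rate(od_c, plate.times_h)
    phases = classify_phases(np.where(od_c > 0, od_c, np.nan), plate.times_h,
                             threshold_frac=threshold_frac)
    trace = ActivityTrace(
        well_id=well_id, times_h=plate.times_h[:-1],
        fluo_over_od=norm[:-1], activity=activity, raw_rate=raw,
        growth_rate=rate, phases=phases, f_max=float("nan"),
        max_growth_rate=max_rate)
    trace.f_max = extract_fmax(trace)
    return trace


def characterize_plate(plate: PlateTimeSeries,
                       smooth_window: int | None = 3,
                       threshold_frac: float = 0.5,
                       od_floor: float = OD_FLOOR) -> dict[str, ActivityTrace]:
    """Characterize every sample well; returns {well_id: ActivityTrace}."""
    out = {}
    for entry in plate.plate_map:
        if entry.role != "sample":
            continue
        out[entry.well_id] = characterize_well(
            plate, entry.well_id, smooth_window=smooth_window,
            threshold_frac=threshold_frac, od_floor=od_floor)
    return out


def dose_table(plate: PlateTimeSeries,
               traces: dict[str, ActivityTrace]):
    """Assemble per-well (dose, Fmax) pairs for calibration fitting."""
    from .calibration import DoseResponsePoint

    points = []
    for entry in plate.plate_map:
        if entry.role != "sample" or entry.well_id not in traces:
            continue
        points.append(DoseResponsePoint(
            inducer_nM=entry.inducer_nM if entry.inducer_nM is not None else 0.0,
            signal=traces[entry.well_id].f_max))
    return points
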