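"""Dose-response calibration: Hill fit, log-log linearization, detection limit.

This layer turns a table of (inducer concentration, signal) pairs into two
complementary models of a whole-cell biosensor's response to ionic mercury:

* a four-parameter Hill curve,

  .. math:: S(I) = \\psi_{min} + \\psi_{max} \\frac{I^h}{I^h + K^h},

  describing the full saturating dose-response of the genetic circuit, where
  ``psi_min`` is the baseline synthesis rate without induction, ``psi_max``
  the maximal induced increment, ``K`` the half-maximal inducer
  concentration (nM) and ``h`` the Hill coefficient;

* an ordinary least-squares line through ``ln(signal)`` versus ``ln(I)``
  over a restricted dose window — the operational calibration used for
  inverse prediction of unknown samples and for the ``3.3 * sigma0 / m``
  detection-limit rule.

The two fits are independent views of the same dose table; no constraint
ties their parameters.  The signal may be a fluorescence synthesis rate
(``Fmax``, AFU * OD^-1 * h^-1) from kinetic profiling or a colour score
(``E``) from pellet colorimetry — the mathematics is identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit


class CalibrationError(ValueError):
    """Raised when a calibration cannot be built from the given dose table."""


@dataclass
class DoseResponsePoint:
    """One (dose, signal) observation, possibly excluded from fitting.

    ``excluded`` marks observations removed for cause (e.g. growth toxicity
    at the top dose); they are carried through for bookkeeping but never
    enter any fit objective.
    """

    inducer_nM: float
    signal: float
    replicate_sd: float | None = None
    excluded: bool = False
    exclude_reason: str = ""

    def __post_init__(self) -> None:
        if self.inducer_nM < 0:
            raise ValueError(f"inducer_nM must be >= 0, got {self.inducer_nM}")
        if not self.excluded and not math.isfinite(self.signal):
            raise ValueError("signal must be finite for non-excluded points")


@dataclass
class HillFit:
    """Fitted Hill parameters.

    By construction the predicted signal at ``I = K`` equals
    ``psi_min + psi_max / 2`` (half-maximal identity).
    """

    psi_min: float
    psi_max: float
    K: float
    h: float
    rss: float
    converged: bool
    degenerate: bool = False


@dataclass
class LinearCalibration:
    """Log-log linear calibration ln(signal) = m * ln(I) + y0.

    ``sigma0`` is the residual standard deviation of the regression in log
    units (n-2 denominator by default); ``lod_nM`` the detection limit
    derived from it; ``range_nM`` the dose window the line was fitted on.
    """

    m: float
    y0: float
    sigma0: float
    range_nM: tuple[float, float]
    lod_nM: float
    n_points: int
    r_squared: float


@dataclass
class Calibration:
    """Complete calibration of one biosensor variant: Hill + log-log line."""

    hill: HillFit
    linear: LinearCalibration
    signal_kind: str = "fluorescence_rate"  # or "color_intensity"
    provenance: str = ""

    def to_dict(self) -> dict:
        d = {
            "psi_min": self.hill.psi_min,
            "psi_max": self.hill.psi_max,
            "K": self.hill.K,
            "h": self.hill.h,
            "rss": self.hill.rss,
            "converged": self.hill.converged,
            "degenerate": self.hill.degenerate,
            "m": self.linear.m,
            "y0": self.linear.y0,
            "sigma0": self.linear.sigma0,
            "range_nM": list(self.linear.range_nM),
            "lod_nM": self.linear.lod_nM,
            "n_points": self.linear.n_points,
            "r_squared": self.linear.r_squared,
            "signal_kind": self.signal_kind,
            "provenance": self.provenance,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        hill = HillFit(
            psi_min=d["psi_min"], psi_max=d["psi_max"], K=d["K"], h=d["h"],
            rss=d["rss"], converged=d["converged"],
            degenerate=d.get("degenerate", False),
        )
        linear = LinearCalibration(
            m=d["m"], y0=d["y0"], sigma0=d["sigma0"],
            range_nM=tuple(d["range_nM"]), lod_nM=d["lod_nM"],
            n_points=d["n_points"], r_squared=d.get("r_squared", float("nan")),
        )
        return cls(hill=hill, linear=linear,
                   signal_kind=d.get("signal_kind", "fluorescence_rate"),
                   provenance=d.get("provenance", ""))


def _hill(I, psi_min, psi_max, K, h):
    I = np.asarray(I, dtype=float)
    with np.errstate(invalid="ignore"):
        num = np.power(I, h)
    return psi_min + psi_max * num / (num + K ** h)


def hill_predict(fit, inducer_nM):
    """Evaluate the Hill curve of ``fit`` (anything with psi_min/psi_max/K/h).

    Scalar in, scalar out; arrays are broadcast.  ``I = 0`` returns
    ``psi_min`` exactly for any positive Hill coefficient.
    """
    out = _hill(inducer_nM, fit.psi_min, fit.psi_max, fit.K, fit.h)
    if np.isscalar(inducer_nM):
        return float(out)
    return out


def _active(points: list[DoseResponsePoint]):
    pts = [p for p in points if not p.excluded]
    x = np.array([p.inducer_nM for p in pts], dtype=float)
    y = np.array([p.signal for p in pts], dtype=float)
    return x, y


def fit_hill(points: list[DoseResponsePoint]) -> HillFit:
    """Fit the four-parameter Hill curve by nonlinear least squares.

    Initialisation: ``psi_min`` = min signal, ``psi_max`` = signal span,
    ``K`` = the dose whose signal is closest to the mid-response, ``h`` = 1,
    with a multistart over h in {1, 0.5, 2} and all parameters constrained
    positive.  Excluded points never enter the objective.

    Raises
    ------
    CalibrationError
        If fewer than four usable points remain, the doses span fewer than
        two decades, or no start converges.
    """
    x, y = _active(points)
    if len(x) < 4:
        raise CalibrationError(
            f"Hill fit needs >= 4 non-excluded points, got {len(x)}")
    pos = x[x > 0]
    if len(pos) == 0 or pos.max() / pos.min() < 100.0:
        raise CalibrationError(
            "Hill fit needs doses spanning at least two decades")

    span = float(y.max() - y.min())
    mid = y.min() + 0.5 * span
    k0 = float(x[np.argmin(np.abs(y - mid))])
    if k0 <= 0:
        k0 = float(np.median(pos))
    p_min0 = max(float(y.min()), 0.0)
    p_max0 = max(span, 0.0)

    tiny = 1e-12
    bounds = ([0.0, 0.0, tiny, tiny], [np.inf] * 4)
    best = None
    diagnostics = []
    for h0 in (1.0, 0.5, 2.0):
        try:
            with warnings.catch_warnings():
                # the covariance is unused; flat responses make it singular
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _hill, x, y, p0=[p_min0, p_max0, k0, h0],
                    bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:  # no convergence
            diagnostics.append(f"h0={h0}: {exc}")
            continue
        rss = float(np.sum((_hill(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise CalibrationError(
            "Hill fit did not converge from any start (h0 in 1, 0.5, 2): "
            + "; ".join(diagnostics))

    popt, rss = best
    psi_min, psi_max, K, h = (float(v) for v in popt)
    degenerate = span <= 1e-12 * max(abs(float(y.max())), 1.0) \
        or psi_max < 1e-8 * max(psi_min, 1.0)
    return HillFit(psi_min=psi_min, psi_max=psi_max, K=K, h=h,
                   rss=rss, converged=True, degenerate=degenerate)


def _ols_loglog(x: np.ndarray, y: np.ndarray, sigma_ddof: int):
    """OLS of ln(y) on ln(x); returns (m, y0, sigma0, r_squared, rss)."""
    lx, ly = np.log(x), np.log(y)
    n = len(lx)
    mx, my = lx.mean(), ly.mean()
    sxx = float(np.sum((lx - mx) ** 2))
    sxy = float(np.sum((lx - mx) * (ly - my)))
    if sxx == 0:
        raise CalibrationError("all doses identical; cannot fit a line")
    m = sxy / sxx
    y0 = my - m * mx
    resid = ly - (m * lx + y0)
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((ly - my) ** 2))
    r2 = 1.0 if tss == 0 and rss < 1e-30 else (1.0 - rss / tss if tss > 0 else 0.0)
    dof = max(n - sigma_ddof, 1)
    sigma0 = math.sqrt(rss / dof)
    return m, y0, sigma0, r2, rss


def fit_linear_range(points: list[DoseResponsePoint],
                     range_override: tuple[float, float] | None = None,
                     min_window: int = 4,
                     r2_floor: float = 0.98,
                     sigma_ddof: int = 2) -> LinearCalibration:
    """Fit ln(signal) = m * ln(I) + y0 over the biosensor's linear range.

    Without ``range_override`` the linear range is chosen automatically:
    among all contiguous dose windows containing at least ``min_window``
    points whose OLS fit reaches ``r2_floor``, take the widest (in log-dose
    span); ties go to the higher R^2, then to the lower-dose window.  The
    automatic rule is a determinization — pass ``range_override`` to pin
    the window by hand.

    ``sigma_ddof`` selects the residual-SD denominator: 2 gives the usual
    unbiased n-2 regression estimate, 0 the population form.
    """
    x, y = _active(points)
    usable = (x > 0) & (y > 0) & np.isfinite(y)
    x, y = x[usable], y[usable]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    if range_override is not None:
        lo, hi = range_override
        sel = (x >= lo) & (x <= hi)
        if sel.sum() < 3:
            raise CalibrationError(
                f"need >= 3 points with positive dose inside ({lo}, {hi}), "
                f"got {int(sel.sum())}")
        xs, ys = x[sel], y[sel]
        m, y0, sigma0, r2, _ = _ols_loglog(xs, ys, sigma_ddof)
        return LinearCalibration(
            m=m, y0=y0, sigma0=sigma0,
            range_nM=(float(xs.min()), float(xs.max())),
            lod_nM=compute_lod(m, sigma0), n_points=len(xs), r_squared=r2)

    if len(x) < min_window:
        raise CalibrationError(
            f"need >= {min_window} points with positive dose and signal for "
            f"automatic range selection, got {len(x)}")

    doses = np.unique(x)
    best = None  # (span, r2, -lo, fit tuple, lo, hi, n)
    for i in range(len(doses)):
        for j in range(i + 1, len(doses)):
            lo, hi = doses[i], doses[j]
            sel = (x >= lo) & (x <= hi)
            if sel.sum() < min_window:
                continue
            m, y0, sigma0, r2, _ = _ols_loglog(x[sel], y[sel], sigma_ddof)
            if r2 < r2_floor:
                continue
            key = (math.log(hi / lo), r2, -lo)
            if best is None or key > best[0]:
                best = (key, (m, y0, sigma0, r2), float(lo), float(hi),
                        int(sel.sum()))
    if best is None:
        raise CalibrationError(
            f"no contiguous window of >= {min_window} points reaches "
            f"R^2 >= {r2_floor}; supply range_override to fit a chosen window")
    _, (m, y0, sigma0, r2), lo, hi, n = best
    return LinearCalibration(m=m, y0=y0, sigma0=sigma0, range_nM=(lo, hi),
                             lod_nM=compute_lod(m, sigma0), n_points=n,
                             r_squared=r2)


def compute_lod(m, sigma0: float | None = None) -> float:
    """Limit of detection from the log-log calibration: exp(3.3*sigma0/m).

    Accepts either a :class:`LinearCalibration` or the pair ``(m, sigma0)``.
    The rule is applied literally on the natural-log scale, so the LOD is
    returned in the same concentration units as the calibration doses (nM).
    A zero-residual calibration gives exp(0) = 1 nM by construction.
    """
    if sigma0 is None:
        linear = m
        m, sigma0 = linear.m, linear.sigma0
    if m <= 0:
        raise CalibrationError(
            f"LOD rule requires an increasing calibration (m > 0), got m={m}")
    if sigma0 < 0:
        raise CalibrationError("sigma0 must be >= 0")
    return float(math.exp(3.3 * sigma0 / m))


def build_calibration(points: list[DoseResponsePoint],
                      signal_kind: str = "fluorescence_rate",
                      range_override: tuple[float, float] | None = None,
                      provenance: str = "",
                      sigma_ddof: int = 2) -> Calibration:
    """Fit both the Hill curve and the log-log line on one dose table."""
    hill = fit_hill(points)
    linear = fit_linear_range(points, range_override=range_override,
                              sigma_ddof=sigma_ddof)
    return Calibration(hill=hill, linear=linear, signal_kind=signal_kind,
                       provenance=provenance)
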