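"""Inverse estimation of ionic mercury in unknown samples.

Given a log-log calibration ln(signal) = m * ln(I) + y0, an unknown
sample's signal inverts to the concentration in the assay culture,

    I_culture = exp((ln(signal) - y0) / m),

which is then multiplied by the dilution factor applied during sample
preparation (environmental samples are typically mixed 1:1 with double-
strength medium, so estimates and detection bounds are both doubled).
Estimates whose culture-level concentration falls below the calibration's
limit of detection are censored and reported only as "< bound", with
bound = LOD * dilution_factor.  Estimates above the calibrated range are
reported but flagged as extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Molar mass of mercury, g/mol.
HG_MOLAR_MASS_G_PER_MOL = 200.59


@dataclass
class QuantifiedSample:
    """One quantified unknown: either a point estimate or a censored bound."""

    sample_id: str
    signal: float
    dilution_factor: float
    censored: bool
    estimate_nM: float | None = None
    bound_nM: float | None = None
    estimate_sd_nM: float | None = None
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.censored == (self.estimate_nM is not None):
            raise ValueError("exactly one of estimate_nM / bound_nM must be "
                             "populated")


def _linear_of(cal):
    linear = getattr(cal, "linear", cal)
    if linear is None:
        raise ValueError("calibration has no log-log line")
    return linear


def invert_signal(signal: float, cal) -> float:
    """Invert the log-log calibration to a culture-level concentration (nM)."""
    linear = _linear_of(cal)
    if signal <= 0:
        raise ValueError(f"signal must be > 0 for log inversion, got {signal}")
    return float(math.exp((math.log(signal) - linear.y0) / linear.m))


def estimate_concentration(signal: float, cal,
                           dilution_factor: float = 1.0,
                           sample_id: str = "sample") -> QuantifiedSample:
    """Estimate the Hg2+ concentration behind one measured signal.

    Censoring compares the culture-level estimate against the calibration
    LOD (pre-dilution); the reported bound is then scaled by the dilution
    factor.  The comparison is inclusive: a sample sitting exactly at the
    LOD is reported as an estimate, not a bound.
    """
    linear = _linear_of(cal)
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    i_culture = invert_signal(signal, linear)
    # inclusive boundary: a sample at the LOD (within float round-trip
    # error of the log inversion) is an estimate, not a bound
    if i_culture < linear.lod_nM * (1.0 - 1e-9):
        return QuantifiedSample(
            sample_id=sample_id, signal=signal,
            dilution_factor=dilution_factor, censored=True,
            bound_nM=linear.lod_nM * dilution_factor)
    return QuantifiedSample(
        sample_id=sample_id, signal=signal, dilution_factor=dilution_factor,
        censored=False, estimate_nM=i_culture * dilution_factor,
        extrapolated=bool(i_culture > linear.range_nM[1]))


def estimate_replicates(signals, cal, dilution_factor: float = 1.0,
                        sample_id: str = "sample") -> QuantifiedSample:
    """Invert each replicate signal individually, then summarize.

    The mean culture-level concentration decides censoring; the SD of the
    per-replicate estimates (n-1 denominator), scaled by the dilution
    factor, is carried as the reporting uncertainty.
    """
    signals = list(signals)
    if not signals:
        raise ValueError("no replicate signals")
    linear = _linear_of(cal)
    estimates = np.array([invert_signal(s, linear) for s in signals])
    mean_i = float(estimates.mean())
    sd = float(estimates.std(ddof=1)) if len(estimates) > 1 else None
    if mean_i < linear.lod_nM * (1.0 - 1e-9):
        return QuantifiedSample(
            sample_id=sample_id, signal=float(np.mean(signals)),
            dilution_factor=dilution_factor, censored=True,
            bound_nM=linear.lod_nM * dilution_factor,
            estimate_sd_nM=None if sd is None else sd * dilution_factor)
    return QuantifiedSample(
        sample_id=sample_id, signal=float(np.mean(signals)),
        dilution_factor=dilution_factor, censored=False,
        estimate_nM=mean_i * dilution_factor,
        estimate_sd_nM=None if sd is None else sd * dilution_factor,
        extrapolated=bool(mean_i > linear.range_nM[1]))


def render_result(sample: QuantifiedSample, decimals: int = 1) -> str:
    """Human-readable result cell: "52.3" or "<3.2" for censored samples."""
    if sample.censored:
        return f"<{sample.bound_nM:.{decimals}f}"
    return f"{sample.estimate_nM:.{decimals}f}"


def summarize_run(samples: list[QuantifiedSample]) -> pd.DataFrame:
    """Tabulate quantified samples in reporting layout.

    Columns: sample_id, signal, estimate_nM, censored_flag, bound_nM,
    dilution_factor, estimate_sd_nM, extrapolated, result (rendered cell).
    An empty input yields an empty table with the full header.
    """
    columns = ["sample_id", "signal", "estimate_nM", "censored_flag",
               "bound_nM", "dilution_factor", "estimate_sd_nM",
               "extrapolated", "result"]
    rows = []
    for s in samples:
        rows.append({
            "sample_id": s.sample_id,
            "signal": s.signal,
            "estimate_nM": s.estimate_nM,
            "censored_flag": s.censored,
            "bound_nM": s.bound_nM,
            "dilution_factor": s.dilution_factor,
            "estimate_sd_nM": s.estimate_sd_nM,
            "extrapolated": s.extrapolated,
            "result": render_result(s),
        })
    return pd.DataFrame(rows, columns=columns)


def mass_fraction_to_nM(mg_per_kg: float,
                        molar_mass_g_per_mol: float = HG_MOLAR_MASS_G_PER_MOL,
                        density_kg_per_L: float = 1.0) -> float:
    """Convert a mass fraction (mg analyte per kg water) to nmol/L.

    At unit water density, 0.001 mg/kg Hg — the WHO guideline for natural
    mineral waters — is 1 ug/L, i.e. about 5 nM for mercury.
    """
    g_per_L = mg_per_kg * 1e-3 * density_kg_per_L
    return g_per_L / molar_mass_g_per_mol * 1e9
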