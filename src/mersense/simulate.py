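"""Forward simulation of biosensor assays: plates, dose series, pellets.

The generator produces every input the analysis pipeline consumes, with the
statistical structure the analysis assumes:

* logistic bacterial growth with a lag phase, stepped on the sampling grid
  with an exponential (log-space Euler) update so that a capacity far above
  the inoculum reduces exactly to exponential growth;
* reporter accumulation driven by a Hill dose-response: per time step,
  Fluo(t+dt) = Fluo(t) + f(dose) * OD(t) * dt, where f is the Hill curve
  evaluated at the inducer dose (baseline rate before the induction time).
  Because the analysis recovers f by the same forward difference on the
  same grid, noiseless simulations round-trip exactly;
* growth toxicity above a threshold dose, as a fractional penalty on the
  maximum specific growth rate;
* additive Gaussian noise on OD600, multiplicative noise on fluorescence,
  additive per-channel noise on pellet images;
* flat-colour pellet tiles whose blueness scales with the Hill-predicted
  reporter accumulation, plus a white reference tile.

All randomness flows from a single integer seed; a fixed seed regenerates
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .calibration import DoseResponsePoint, hill_predict
from .io import PlateMapEntry, PlateTimeSeries, write_plate


@dataclass
class GrowthParams:
    lag_h: float = 1.0          # no growth before this time
    mu_max: float = 0.7         # maximum specific growth rate, 1/h
    od_capacity: float = 1.0    # logistic carrying capacity, OD units


@dataclass
class ToxicityParams:
    threshold_nM: float = 2000.0   # doses at/above this slow growth
    growth_penalty: float = 0.3    # fractional reduction of mu_max


@dataclass
class HillParams:
    psi_min: float
    psi_max: float
    K: float
    h: float


#: Fitted dose-response of the fluorescent (RFP) biosensor variant.
MER_RFP_HILL = HillParams(psi_min=150.0, psi_max=6000.0, K=305.0, h=1.6)
#: Fitted dose-response of the colorimetric (blue chromoprotein) variant.
MER_BLUE_HILL = HillParams(psi_min=0.9088, psi_max=161.74, K=23.67, h=0.6986)

#: Dose series used to characterize each variant (nM Hg2+).
MER_RFP_DOSES_NM = (1.0, 5.0, 10.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
MER_BLUE_DOSES_NM = (2.0, 5.0, 10.0, 25.0, 50.0, 125.0, 250.0)

#: Log-log calibration lines (slope m, intercept y0) of the two variants.
MER_RFP_LOGLOG = (0.84, 3.1)
MER_BLUE_LOGLOG = (0.36, 3.2)


@dataclass
class SamplingParams:
    interval_h: float = 0.25
    duration_h: float = 16.0


@dataclass
class NoiseParams:
    od_sd: float = 0.002     # additive, OD units
    fluo_cv: float = 0.05    # multiplicative, fraction of the reading
    rgb_sd: float = 2.0      # additive, per channel, 0-255 scale


@dataclass
class SimulationConfig:
    seed: int = 0
    od0: float = 0.05
    growth: GrowthParams = field(default_factory=GrowthParams)
    toxicity: ToxicityParams = field(default_factory=ToxicityParams)
    hill: HillParams = field(default_factory=lambda: MER_RFP_HILL)
    doses_nM: tuple = MER_RFP_DOSES_NM
    induction_time_h: float = 0.0
    sampling: SamplingParams = field(default_factory=SamplingParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    replicates: int = 3
    n_blanks: int = 3
    medium_od: float = 0.04     # OD600 of sterile medium (blank level)
    medium_fluo: float = 50.0   # medium autofluorescence, AFU

    def __post_init__(self) -> None:
        if self.od0 <= 0:
            raise ValueError("od0 must be positive")
        if any(d < 0 for d in self.doses_nM):
            raise ValueError("doses must be non-negative")
        if self.noise.od_sd < 0 or self.noise.fluo_cv < 0 or \
                self.noise.rgb_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        steps = self.sampling.duration_h / self.sampling.interval_h
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("sampling interval must divide the duration")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.sampling.duration_h / self.sampling.interval_h))
        return np.arange(n + 1) * self.sampling.interval_h


def noiseless(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of ``cfg`` with every noise magnitude set to zero."""
    import copy

    out = copy.deepcopy(cfg)
    out.noise = NoiseParams(od_sd=0.0, fluo_cv=0.0, rgb_sd=0.0)
    return out


def simulate_growth(cfg: SimulationConfig, dose_nM: float,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Culture OD600 trajectory (background-free) under one inducer dose.

    Specific growth rate mu(t) = 0 before the lag ends, then
    mu_max_eff * (1 - OD/capacity), stepped as OD * exp(mu * dt) so that
    capacity >> OD reduces exactly to exponential growth on the grid.
    Doses at or above the toxicity threshold scale mu_max down by the
    configured penalty.  Additive Gaussian noise is applied to the
    trajectory when od_sd > 0.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    times = cfg.time_grid()
    mu_max = cfg.growth.mu_max
    if dose_nM >= cfg.toxicity.threshold_nM:
        mu_max *= (1.0 - cfg.toxicity.growth_penalty)
    od = np.empty_like(times)
    od[0] = cfg.od0
    dt = cfg.sampling.interval_h
    for n in range(len(times) - 1):
        mu = 0.0 if times[n] < cfg.growth.lag_h else \
            mu_max * (1.0 - od[n] / cfg.growth.od_capacity)
        od[n + 1] = od[n] * math.exp(mu * dt)
    if cfg.noise.od_sd > 0:
        od = od + rng.normal(0.0, cfg.noise.od_sd, size=od.shape)
    return od


def simulate_reporter(cfg: SimulationConfig, dose_nM: float,
                      od_series: np.ndarray,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Reporter fluorescence driven by the Hill curve at ``dose_nM``.

    Fluo(0) = 0 and Fluo(t+dt) = Fluo(t) + f * OD(t) * dt, with f the
    induced Hill rate once the induction time is reached and the baseline
    rate psi_min before it.  Multiplicative Gaussian noise of coefficient
    of variation fluo_cv is applied to the recorded readings.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    times = cfg.time_grid()
    if len(od_series) != len(times):
        raise ValueError("od_series does not match the sampling grid")
    f_induced = hill_predict(cfg.hill, dose_nM)
    f_baseline = cfg.hill.psi_min
    dt = cfg.sampling.interval_h
    fluo = np.zeros_like(times)
    for n in range(len(times) - 1):
        f = f_induced if times[n] >= cfg.induction_time_h else f_baseline
        fluo[n + 1] = fluo[n] + f * od_series[n] * dt
    if cfg.noise.fluo_cv > 0:
        fluo = fluo * (1.0 + rng.normal(0.0, cfg.noise.fluo_cv,
                                        size=fluo.shape))
    return fluo


def simulate_plate(cfg: SimulationConfig) -> PlateTimeSeries:
    """Assemble a full plate: blank wells plus replicate wells per dose.

    Recorded OD600 includes the medium background; recorded fluorescence
    includes the medium autofluorescence.  Blank wells carry the same
    noise model, so time-matched blank correction is exact in the
    noiseless limit.
    """
    rng = np.random.default_rng(cfg.seed)
    times = cfg.time_grid()
    entries, od_rows, fluo_rows = [], [], []

    for b in range(cfg.n_blanks):
        entries.append(PlateMapEntry(well_id=f"BLK{b + 1}", role="blank"))
        od = np.full_like(times, cfg.medium_od)
        fluo = np.full_like(times, cfg.medium_fluo)
        if cfg.noise.od_sd > 0:
            od = od + rng.normal(0.0, cfg.noise.od_sd, size=od.shape)
        if cfg.noise.fluo_cv > 0:
            fluo = fluo * (1.0 + rng.normal(0.0, cfg.noise.fluo_cv,
                                            size=fluo.shape))
        od_rows.append(od)
        fluo_rows.append(fluo)

    w = 0
    for dose in cfg.doses_nM:
        for rep in range(cfg.replicates):
            w += 1
            entries.append(PlateMapEntry(
                well_id=f"S{w:02d}", role="sample", inducer_nM=float(dose),
                induction_time_h=cfg.induction_time_h,
                replicate_group=f"dose_{dose:g}"))
            culture = simulate_growth(cfg, dose, rng)
            fluo = simulate_reporter(cfg, dose, culture, rng)
            od_rows.append(culture + cfg.medium_od)
            fluo_rows.append(fluo + cfg.medium_fluo)

    return PlateTimeSeries(times_h=times, od600=np.vstack(od_rows),
                           fluorescence=np.vstack(fluo_rows),
                           plate_map=entries)


def simulate_dose_response(doses_nM, hill: HillParams, replicates: int = 3,
                           noise_cv: float = 0.05,
                           rng: np.random.Generator | None = None,
                           exclude_above_nM: float | None = None,
                           ) -> list[DoseResponsePoint]:
    """Dose-response table drawn directly from the Hill curve.

    Signals are hill(dose) * (1 + noise_cv * eps) per replicate.  Doses at
    or above ``exclude_above_nM`` are generated but marked excluded (the
    growth-toxicity convention for the top dose).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    points = []
    for dose in doses_nM:
        mean = hill_predict(hill, float(dose))
        for _ in range(replicates):
            signal = mean * (1.0 + noise_cv * rng.standard_normal()) \
                if noise_cv > 0 else mean
            excluded = exclude_above_nM is not None and \
                dose >= exclude_above_nM
            points.append(DoseResponsePoint(
                inducer_nM=float(dose), signal=float(signal),
                excluded=excluded,
                exclude_reason="toxicity" if excluded else ""))
    return points


def simulate_loglog_points(doses_nM, slope: float, intercept: float,
                           sigma: float,
                           rng: np.random.Generator | None = None,
                           replicates: int = 1) -> list[DoseResponsePoint]:
    """Points on the line ln(signal) = slope * ln(I) + intercept + N(0, sigma)."""
    if rng is None:
        rng = np.random.default_rng(0)
    points = []
    for dose in doses_nM:
        for _ in range(replicates):
            ln_s = slope * math.log(dose) + intercept
            if sigma > 0:
                ln_s += sigma * rng.standard_normal()
            points.append(DoseResponsePoint(inducer_nM=float(dose),
                                            signal=float(math.exp(ln_s))))
    return points


# -- pellet image rendering --------------------------------------------------

#: Channel deviation (R, G, B) of a fully saturated blue pellet from white.
_FULL_DEVIATION = np.array([200.0, 190.0, 60.0])
_TILE = 96
_RADIUS = 30


def pellet_color(cfg: SimulationConfig, dose_nM: float) -> tuple[int, int, int]:
    """Pellet fill colour for one dose: white minus a blue-weighted deviation
    proportional to the Hill-predicted reporter accumulation."""
    level = hill_predict(cfg.hill, dose_nM)
    saturation = min(max(level / (cfg.hill.psi_min + cfg.hill.psi_max), 0.0),
                     1.0)
    rgb = 255.0 - saturation * _FULL_DEVIATION
    return tuple(int(round(v)) for v in rgb)


def render_pellet(fill_rgb, tile: int = _TILE, radius: int = _RADIUS,
                  rgb_sd: float = 0.0,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one circular pellet tile on a white background (uint8 HxWx3)."""
    img = np.full((tile, tile, 3), 255.0)
    rr, cc = np.ogrid[:tile, :tile]
    center = tile // 2
    mask = (rr - center) ** 2 + (cc - center) ** 2 <= radius ** 2
    img[mask] = np.asarray(fill_rgb, dtype=float)
    if rgb_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, rgb_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def simulate_pellets(cfg: SimulationConfig, out_dir,
                     doses_nM=None) -> pd.DataFrame:
    """Write one pellet tile per dose plus a white reference tile.

    Returns (and writes as ``manifest.tsv``) a manifest mapping each file
    to its dose and to the pellet-center ROI coordinates; the seed is
    recorded so a run can be regenerated byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if doses_nM is None:
        doses_nM = cfg.doses_nM
    rng = np.random.default_rng(cfg.seed)
    center = _TILE // 2
    rows = []
    for i, dose in enumerate(doses_nM):
        fill = pellet_color(cfg, float(dose))
        arr = render_pellet(fill, rgb_sd=cfg.noise.rgb_sd, rng=rng)
        name = f"pellet_{i:02d}_{dose:g}nM.png"
        Image.fromarray(arr).save(out_dir / name)
        rows.append({"file": name, "role": "sample", "dose_nM": float(dose),
                     "roi_row": center, "roi_col": center, "seed": cfg.seed})
    ref = render_pellet((255, 255, 255), rgb_sd=cfg.noise.rgb_sd, rng=rng)
    Image.fromarray(ref).save(out_dir / "reference.png")
    rows.append({"file": "reference.png", "role": "reference",
                 "dose_nM": float("nan"), "roi_row": center,
                 "roi_col": center, "seed": cfg.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def write_run(cfg: SimulationConfig, out_dir,
              pellets: bool = True) -> dict[str, Path]:
    """Simulate a plate (and optionally pellets) and write all artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plate = simulate_plate(cfg)
    run_file = out_dir / "plate.csv"
    map_file = out_dir / "plate_map.csv"
    write_plate(plate, run_file, map_file)
    paths = {"plate": run_file, "plate_map": map_file}
    if pellets:
        simulate_pellets(cfg, out_dir / "pellets")
        paths["pellets"] = out_dir / "pellets"
    return paths
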