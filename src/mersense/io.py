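"""File I/O: plate-reader CSV, plate maps, calibration JSON, results TSV.

Plate runs use a wide CSV dialect: one time column (``time_h`` or
``time_min``; a bare ``time`` column is taken as hours) followed by one
column pair per well, ``<well>_od`` and optionally ``<well>_fluo``.
Colorimetric runs record only OD600, so fluorescence columns may be absent
entirely.  The plate map is a separate CSV assigning each well a role
(sample / blank / reference), inducer dose, induction time, dilution factor
and replicate group.  Well order in memory always follows plate-map order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import Calibration

ROLES = ("sample", "blank", "reference")


class PlateFormatError(ValueError):
    pass


@dataclass
class PlateMapEntry:
    well_id: str
    role: str
    inducer_nM: float | None = None
    induction_time_h: float = 0.0
    dilution_factor: float = 1.0
    replicate_group: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateFormatError(
                f"well {self.well_id!r}: role must be one of {ROLES}, "
                f"got {self.role!r}")
        if self.inducer_nM is not None and self.inducer_nM < 0:
            raise PlateFormatError(
                f"well {self.well_id!r}: inducer_nM must be >= 0")
        if self.induction_time_h < 0:
            raise PlateFormatError(
                f"well {self.well_id!r}: induction_time_h must be >= 0")
        if self.dilution_factor < 1:
            raise PlateFormatError(
                f"well {self.well_id!r}: dilution_factor must be >= 1")


@dataclass
class PlateTimeSeries:
    """Per-well OD600 / fluorescence trajectories plus plate-map annotations.

    ``od600`` and ``fluorescence`` are (wells x times) matrices whose row
    order equals plate-map order; ``fluorescence`` is None for runs without
    a fluorescence channel.
    """

    times_h: np.ndarray
    od600: np.ndarray
    fluorescence: np.ndarray | None
    plate_map: list[PlateMapEntry]

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        n_wells, n_times = len(self.plate_map), len(self.times_h)
        if self.od600.shape != (n_wells, n_times):
            raise PlateFormatError(
                f"od600 shape {self.od600.shape} does not match "
                f"{n_wells} wells x {n_times} times")
        if self.fluorescence is not None and \
                self.fluorescence.shape != (n_wells, n_times):
            raise PlateFormatError("fluorescence shape mismatch")
        if np.any(np.diff(self.times_h) <= 0):
            raise PlateFormatError("time vector must be strictly increasing")
        if not np.all(np.isfinite(self.od600)):
            raise PlateFormatError("OD600 contains non-finite values")
        ids = [e.well_id for e in self.plate_map]
        if len(set(ids)) != len(ids):
            raise PlateFormatError("duplicate well ids in plate map")
        if not any(e.role == "blank" for e in self.plate_map):
            raise PlateFormatError("plate has no blank well")

    def well_index(self, well_id: str) -> int:
        for i, e in enumerate(self.plate_map):
            if e.well_id == well_id:
                return i
        raise KeyError(well_id)

    def blank_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.plate_map) if e.role == "blank"]

    def sample_entries(self) -> list[PlateMapEntry]:
        return [e for e in self.plate_map if e.role == "sample"]


_MAP_COLUMNS = ["well_id", "role", "inducer_nM", "induction_time_h",
                "dilution_factor", "replicate_group"]


def read_plate_map(map_file) -> list[PlateMapEntry]:
    df = pd.read_csv(map_file)
    missing = {"well_id", "role"} - set(df.columns)
    if missing:
        raise PlateFormatError(f"plate map lacks columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        inducer = row.get("inducer_nM")
        inducer = None if inducer is None or pd.isna(inducer) else float(inducer)
        entries.append(PlateMapEntry(
            well_id=str(row["well_id"]),
            role=str(row["role"]),
            inducer_nM=inducer,
            induction_time_h=float(row.get("induction_time_h", 0.0) or 0.0),
            dilution_factor=float(row.get("dilution_factor", 1.0) or 1.0),
            replicate_group=str(row.get("replicate_group", "") or ""),
        ))
    return entries


def read_plate(run_file, map_file) -> PlateTimeSeries:
    """Read a plate run + map pair into a validated :class:`PlateTimeSeries`.

    Minutes are auto-converted to hours when the time column is named
    ``time_min``.  Wells present in the data but absent from the map are
    dropped with a warning; wells named in the map but missing from the
    data are a hard error, as is a map with no blank well.
    """
    entries = read_plate_map(map_file)
    df = pd.read_csv(run_file)
    time_col = df.columns[0]
    if time_col not in ("time_h", "time_min", "time"):
        raise PlateFormatError(
            f"first column must be time_h, time_min or time, got {time_col!r}")
    times = df[time_col].to_numpy(dtype=float)
    if time_col == "time_min":
        times = times / 60.0
    if np.any(np.diff(times) <= 0):
        raise PlateFormatError(f"{run_file}: time column is not "
                               "strictly increasing")

    data_wells = {c[:-3] for c in df.columns if c.endswith("_od")}
    map_wells = {e.well_id for e in entries}
    unmapped = sorted(data_wells - map_wells)
    if unmapped:
        warnings.warn(f"{run_file}: wells {unmapped} absent from plate map; "
                      "dropped", stacklevel=2)
    absent = sorted(map_wells - data_wells)
    if absent:
        raise PlateFormatError(
            f"{run_file}: plate map names wells {absent} not present in data")

    od = np.vstack([df[f"{e.well_id}_od"].to_numpy(dtype=float)
                    for e in entries])
    fluo_cols = [f"{e.well_id}_fluo" for e in entries]
    if any(c in df.columns for c in fluo_cols):
        fluo = np.vstack([
            df[c].to_numpy(dtype=float) if c in df.columns
            else np.full(len(times), np.nan)
            for c in fluo_cols])
    else:
        fluo = None
    return PlateTimeSeries(times_h=times, od600=od, fluorescence=fluo,
                           plate_map=entries)


def write_plate(plate: PlateTimeSeries, run_file, map_file) -> None:
    """Write a plate run + map pair in the dialect :func:`read_plate` reads."""
    data = {"time_h": plate.times_h}
    for i, e in enumerate(plate.plate_map):
        data[f"{e.well_id}_od"] = plate.od600[i]
        if plate.fluorescence is not None:
            data[f"{e.well_id}_fluo"] = plate.fluorescence[i]
    pd.DataFrame(data).to_csv(run_file, index=False)

    rows = []
    for e in plate.plate_map:
        rows.append({
            "well_id": e.well_id, "role": e.role,
            "inducer_nM": "" if e.inducer_nM is None else e.inducer_nM,
            "induction_time_h": e.induction_time_h,
            "dilution_factor": e.dilution_factor,
            "replicate_group": e.replicate_group,
        })
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(map_file, index=False)


def write_calibration(cal: Calibration, path) -> None:
    """Serialize a calibration to JSON (round-trips bit-identically).

    Refuses to write non-finite numeric fields: a NaN in a calibration is
    always an upstream defect, not a value to persist.
    """
    d = cal.to_dict()
    for key, value in d.items():
        if isinstance(value, float) and not math.isfinite(value):
            raise ValueError(f"calibration field {key!r} is not finite "
                             f"({value}); refusing to write")
        if isinstance(value, list):
            if any(not math.isfinite(v) for v in value):
                raise ValueError(f"calibration field {key!r} contains "
                                 "non-finite values; refusing to write")
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_calibration(path) -> Calibration:
    with open(path) as fh:
        return Calibration.from_dict(json.load(fh))


def write_dose_table(points, path) -> None:
    rows = [{"inducer_nM": p.inducer_nM, "signal": p.signal,
             "excluded": p.excluded, "exclude_reason": p.exclude_reason}
            for p in points]
    pd.DataFrame(rows, columns=["inducer_nM", "signal", "excluded",
                                "exclude_reason"]).to_csv(
        path, sep="\t", index=False)


def read_dose_table(path):
    from .calibration import DoseResponsePoint

    df = pd.read_csv(path, sep="\t")
    points = []
    for _, row in df.iterrows():
        points.append(DoseResponsePoint(
            inducer_nM=float(row["inducer_nM"]),
            signal=float(row["signal"]),
            excluded=bool(row.get("excluded", False)),
            exclude_reason=str(row.get("exclude_reason", "") or "")
            if not pd.isna(row.get("exclude_reason", "")) else ""))
    return points


def read_signals(path) -> pd.DataFrame:
    """Read a signals table (TSV: sample_id, signal[, dilution_factor])."""
    df = pd.read_csv(path, sep="\t")
    if "dilution_factor" not in df.columns:
        df["dilution_factor"] = 1.0
    missing = {"sample_id", "signal"} - set(df.columns)
    if missing:
        raise PlateFormatError(f"signals table lacks columns {sorted(missing)}")
    return df


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
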