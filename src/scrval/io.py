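"""CSV / JSON readers and writers for the simulator's artifact tables.

All tables are plain CSV with headers; floats are written with 12+
significant digits so write -> read round-trips are exact to ~1e-9 or
better.  Capture histories use the long format standard in the SCR
community: one row per detection event.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fit import CaptureData, FitResult, SCRParameters
from .landscape import LandscapeGrid, Population, TrappingGrid
from .observation import (
    EffortAllocation,
    EncounterData,
    HarvestData,
    TelemetryData,
)

__all__ = [
    "write_landscape", "read_landscape_frame",
    "write_population", "read_population",
    "write_effort", "read_effort",
    "write_captures", "read_captures",
    "write_telemetry", "read_telemetry",
    "write_fit_json", "read_fit_json",
]

_FLOAT_FMT = "%.15g"


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )


def write_landscape(
    path, landscape: LandscapeGrid, mu: Optional[np.ndarray] = None
) -> None:
    df = pd.DataFrame(
        {
            "cell_id": np.arange(landscape.n_cells),
            "x_km": landscape.centers[:, 0],
            "y_km": landscape.centers[:, 1],
            "habitat": landscape.habitat
            if landscape.habitat is not None
            else np.nan,
            "mu": mu if mu is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_landscape_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["cell_id", "x_km", "y_km", "habitat", "mu"], path)
    return df


def landscape_from_frame(df: pd.DataFrame, cell_km: float = 2.0) -> LandscapeGrid:
    """Rebuild a LandscapeGrid from landscape.csv contents."""
    side = float(df["x_km"].max() + cell_km / 2.0)
    return LandscapeGrid(
        side_km=side,
        cell_km=cell_km,
        centers=df[["x_km", "y_km"]].to_numpy(),
        habitat=df["habitat"].to_numpy(),
    )


def write_population(path, pop: Population) -> None:
    df = pd.DataFrame(
        {
            "id": pop.ids,
            "sex": pop.sex,
            "cell_id": pop.center_cell,
            "x_km": pop.xy[:, 0],
            "y_km": pop.xy[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_population(path) -> Population:
    df = pd.read_csv(path)
    _check_columns(df, ["id", "sex", "cell_id", "x_km", "y_km"], path)
    return Population(
        ids=df["id"].to_numpy(),
        sex=df["sex"].to_numpy(dtype=str),
        center_cell=df["cell_id"].to_numpy(),
        xy=df[["x_km", "y_km"]].to_numpy(),
    )


def write_effort(path, effort: EffortAllocation) -> None:
    J, T = effort.effort.shape
    cell, occ = np.meshgrid(np.arange(J), np.arange(1, T + 1), indexing="ij")
    df = pd.DataFrame(
        {"cell_id": cell.ravel(), "occasion": occ.ravel(),
         "km": effort.effort.ravel()}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_effort(path, mode: str = "uncorrelated") -> EffortAllocation:
    df = pd.read_csv(path)
    _check_columns(df, ["cell_id", "occasion", "km"], path)
    J = int(df["cell_id"].max()) + 1
    T = int(df["occasion"].max())
    eff = np.zeros((J, T))
    eff[df["cell_id"].to_numpy(), df["occasion"].to_numpy() - 1] = df[
        "km"
    ].to_numpy()
    return EffortAllocation(
        effort=eff, total_per_occasion=float(eff[:, 0].sum()), mode=mode
    )


def write_captures(
    path, enc: EncounterData, harvest: Optional[HarvestData] = None
) -> None:
    """Long format: one row per detection or harvest event."""
    ii, jj, tt = np.nonzero(enc.detections)
    rows = {
        "individual_id": enc.ids[ii],
        "sex": enc.sex[ii],
        "cell_id": jj,
        "occasion": tt + 1,
        "type": np.repeat("search", ii.shape[0]),
    }
    df = pd.DataFrame(rows)
    if harvest is not None and harvest.n_records:
        hdf = pd.DataFrame(
            {
                "individual_id": enc.ids[harvest.individual],
                "sex": enc.sex[harvest.individual],
                "cell_id": harvest.cell,
                "occasion": harvest.occasion + 1,
                "type": "harvest",
            }
        )
        df = pd.concat([df, hdf], ignore_index=True)
    df = df.sort_values(
        ["individual_id", "occasion", "cell_id", "type"]
    ).reset_index(drop=True)
    df.to_csv(path, index=False)


def read_captures(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"individual_id": int, "cell_id": int, "occasion": int}
    )
    _check_columns(
        df, ["individual_id", "sex", "cell_id", "occasion", "type"], path
    )
    return df


def capture_data_from_frames(
    captures: pd.DataFrame,
    effort: EffortAllocation,
    use_harvest: bool = True,
    n_occasions: Optional[int] = None,
) -> CaptureData:
    """Assemble likelihood-ready CaptureData from the long capture table."""
    T = n_occasions or effort.n_occasions
    J = effort.effort.shape[0]
    if not use_harvest:
        captures = captures[captures["type"] == "search"]
    ids = np.unique(captures["individual_id"].to_numpy())
    n = ids.shape[0]
    hist = np.zeros((n, J, T), dtype=np.uint8)
    avail = np.ones((n, T), dtype=bool)
    harvested = np.zeros(n, dtype=bool)
    sex = np.empty(n, dtype="<U1")
    row_of = {v: r for r, v in enumerate(ids)}
    for rec in captures.itertuples(index=False):
        r = row_of[rec.individual_id]
        hist[r, rec.cell_id, rec.occasion - 1] = 1
        sex[r] = rec.sex
        if rec.type == "harvest":
            harvested[r] = True
            avail[r, rec.occasion :] = False
    return CaptureData(
        histories=hist, sex=sex, ids=ids, avail=avail,
        harvested=harvested, effort=effort.effort,
    )


def write_telemetry(path, telemetry: TelemetryData) -> None:
    rr, kk = np.nonzero(telemetry.counts)
    df = pd.DataFrame(
        {
            "individual_id": telemetry.ids[rr],
            "sex": telemetry.sex[rr],
            "cell_id": kk,
            "n_fixes": telemetry.counts[rr, kk],
        }
    )
    df.to_csv(path, index=False)


def read_telemetry(path, n_landscape_cells: int, n_fixes: int = 30) -> TelemetryData:
    df = pd.read_csv(path)
    _check_columns(df, ["individual_id", "sex", "cell_id", "n_fixes"], path)
    ids = np.unique(df["individual_id"].to_numpy())
    counts = np.zeros((ids.shape[0], n_landscape_cells), dtype=int)
    sex = np.empty(ids.shape[0], dtype="<U1")
    row_of = {v: r for r, v in enumerate(ids)}
    for rec in df.itertuples(index=False):
        r = row_of[rec.individual_id]
        counts[r, rec.cell_id] = rec.n_fixes
        sex[r] = rec.sex
    return TelemetryData(ids=ids, sex=sex, counts=counts, n_fixes=n_fixes)


_FIT_SCHEMA_VERSION = 1


def write_fit_json(path, fit: FitResult) -> None:
    payload = {
        "schema_version": _FIT_SCHEMA_VERSION,
        "estimates": {
            f: getattr(fit.estimates, f) for f in fit.estimates._FIELDS
        },
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "expected_abundance": fit.expected_abundance,
        "density_per_100km2": fit.density_per_100km2,
        "std_errors": fit.std_errors,
        "message": fit.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != _FIT_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported fit schema "
            f"{payload.get('schema_version')!r}"
        )
    return FitResult(
        estimates=SCRParameters(**payload["estimates"]),
        log_likelihood=payload["log_likelihood"],
        converged=payload["converged"],
        n_evaluations=payload["n_evaluations"],
        expected_abundance=payload["expected_abundance"],
        density_per_100km2=payload["density_per_100km2"],
        std_errors=payload["std_errors"],
        message=payload["message"],
    )
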