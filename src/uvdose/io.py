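"""File I/O, the bundled plate registry, and the end-to-end pipeline.

Interchange formats are deliberately plain: CSV for tabular data, JSON
for the plate registry and run reports.

Dose columns always carry the instrument *set* dose in mJ/cm^2; adjusted
axes (sigma, rho, D') are emitted as additional columns and never
overwrite the set dose, so a reader can always recover the raw
instrument setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .dose_response import DoseResponseDataset, FourPLParams, ec50, fit_4pl, trim_descending_tail
from .effective import effective_dose
from .errors import InsufficientDataError, ValidationError
from .geometry import WellGeometry, derive_geometry
from .indices import calibrate_log_log, calibrate_semi_log
from .optics import DilutionSeries, MediumOptics

__all__ = [
    "load_plate_registry",
    "write_plate_registry",
    "registry_to_frame",
    "load_fitted_d_half",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "read_dilution_csv",
    "RunReport",
    "run_pipeline",
]

_REGISTRY_FIELDS = {"diameter_cm", "wall_height_cm", "medium_volume_ml"}


def _registry_entry(name: str, entry: dict) -> WellGeometry:
    if not isinstance(entry, dict):
        raise ValidationError(f"registry entry {name!r} must be an object")
    missing = _REGISTRY_FIELDS - entry.keys()
    if missing:
        raise ValidationError(f"registry entry {name!r} is missing fields: {sorted(missing)}")
    return derive_geometry(
        name,
        diameter=float(entry["diameter_cm"]),
        wall_height=float(entry["wall_height_cm"]),
        medium_volume=float(entry["medium_volume_ml"]),
        seeding_cells=entry.get("seeding_cells"),
    )


def load_plate_registry(path: str | Path | None = None) -> dict[str, WellGeometry]:
    """Load named vessel profiles from JSON; bundled defaults when absent.

    The bundled registry carries the four standard vessels (96-, 24-,
    12-well plates and the 3.5 cm dish) with their growth-area diameters,
    wall heights and working medium volumes.
    """
    if path is None:
        raw = json.loads(
            resources.files("uvdose").joinpath("data/plates.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    return {
        name: _registry_entry(name, entry)
        for name, entry in raw.items()
        if not name.startswith("_")
    }


def write_plate_registry(registry: dict[str, WellGeometry], path: str | Path) -> None:
    """Write a registry back to JSON (input fields only; derived are recomputed)."""
    out = {
        name: {
            "diameter_cm": g.diameter,
            "wall_height_cm": g.wall_height,
            "medium_volume_ml": g.medium_volume,
            **({"seeding_cells": g.seeding_cells} if g.seeding_cells is not None else {}),
        }
        for name, g in registry.items()
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def registry_to_frame(registry: dict[str, WellGeometry]) -> pd.DataFrame:
    """Derived quantities for every vessel as a tidy frame (CSV-exportable)."""
    return pd.DataFrame([g.to_dict() for g in registry.values()])


def load_fitted_d_half() -> dict[str, FourPLParams]:
    """Bundled worked-example 4PL fits of IL-6 release per vessel."""
    raw = json.loads(
        resources.files("uvdose").joinpath("data/il6_fit_params.json").read_text()
    )
    return {
        name: FourPLParams(**entry) for name, entry in raw.items() if not name.startswith("_")
    }


def read_dose_response_csv(path: str | Path) -> dict[str, DoseResponseDataset]:
    """Read a replicate dose-response table.

    Expected columns: vessel, dose_mJ_cm2, response (a replicate column
    is accepted and ignored — replicates are rows).
    """
    df = pd.read_csv(path)
    required = {"vessel", "dose_mJ_cm2", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"dose-response CSV is missing columns: {sorted(missing)}")
    out = {}
    for vessel, grp in df.groupby("vessel", sort=False):
        grp = grp.sort_values("dose_mJ_cm2")
        out[str(vessel)] = DoseResponseDataset(
            vessel=str(vessel),
            doses=tuple(grp["dose_mJ_cm2"].astype(float)),
            responses=tuple(grp["response"].astype(float)),
        )
    return out


def write_dose_response_csv(datasets: dict[str, DoseResponseDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets.values():
        d = np.asarray(ds.doses)
        rep_counter: dict[float, int] = {}
        for dose, resp in zip(d, ds.responses):
            rep_counter[dose] = rep_counter.get(dose, 0) + 1
            rows.append(
                {
                    "vessel": ds.vessel,
                    "dose_mJ_cm2": dose,
                    "response": resp,
                    "replicate": rep_counter[dose],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dilution_csv(path: str | Path, path_length: float = 1.0) -> DilutionSeries:
    """Two-column CSV (relative_concentration, absorbance) -> DilutionSeries."""
    df = pd.read_csv(path)
    required = {"relative_concentration", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"dilution CSV is missing columns: {sorted(missing)}")
    return DilutionSeries(
        concentrations=tuple(df["relative_concentration"].astype(float)),
        absorbances=tuple(df["absorbance"].astype(float)),
        path_length=path_length,
    )


@dataclass
class RunReport:
    """Self-contained record of one pipeline run.

    Every numeric output is keyed by vessel and stage so it can be traced
    back to a named operation and input.
    """

    command: str
    parameters: dict[str, Any]
    fits: dict[str, dict[str, float]] = field(default_factory=dict)
    d_half: dict[str, float] = field(default_factory=dict)
    calibrations: dict[str, dict[str, float]] = field(default_factory=dict)
    effective_doses: dict[str, dict[str, float]] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_pipeline(
    datasets: dict[str, DoseResponseDataset] | None,
    registry: dict[str, WellGeometry],
    d_half_overrides: dict[str, float] | None = None,
    trim_mode: str = "descending",
    absorptivity: float | None = None,
    set_dose_for_dprime: float = 1.0,
) -> RunReport:
    """Trim -> 4PL fit -> D_1/2 table -> sigma/rho calibrations -> optional D'.

    ``d_half_overrides`` lets the fitting stage be skipped for vessels
    whose half-effect doses are already known (e.g. the bundled
    worked-example fits).  If ``absorptivity`` is given, the
    effective-dose model runs for every registered vessel.
    Deterministic given inputs.
    """
    report = RunReport(
        command="run_pipeline",
        parameters={
            "trim_mode": trim_mode,
            "absorptivity": absorptivity,
            "n_vessels": len(registry),
        },
    )
    d_half: dict[str, float] = dict(d_half_overrides or {})

    if datasets:
        for name, ds in datasets.items():
            if name in d_half:
                continue
            if name not in registry:
                raise ValidationError(f"dataset vessel {name!r} is not in the plate registry")
            try:
                trimmed = trim_descending_tail(ds, mode=trim_mode)
                params = fit_4pl(trimmed.doses, trimmed.responses)
            except Exception as exc:
                raise type(exc)(f"[fit stage, vessel {name!r}] {exc}") from exc
            report.fits[name] = {
                "lower_plateau": params.lower_plateau,
                "slope_factor": params.slope_factor,
                "midpoint": params.midpoint,
                "upper_plateau": params.upper_plateau,
                "r_squared": params.r_squared,
            }
            d_half[name] = ec50(params)

    unknown = set(d_half) - set(registry)
    if unknown:
        raise ValidationError(f"D_1/2 given for unregistered vessels: {sorted(unknown)}")
    report.d_half = dict(d_half)

    if len(d_half) < 3:
        raise InsufficientDataError(
            f"calibration needs >= 3 vessels with a D_1/2, got {len(d_half)}"
        )
    names = list(d_half)
    s_vals = [registry[n].surface_area for n in names]
    r_vals = [registry[n].aspect_ratio for n in names]
    d_vals = [d_half[n] for n in names]
    loglog = calibrate_log_log(s_vals, d_vals)
    semilog = calibrate_semi_log(r_vals, d_vals)
    report.calibrations["log-log"] = {
        "slope": loglog.slope,
        "intercept": loglog.intercept,
        "r_squared": loglog.r_squared,
        "sigma_exponent": loglog.sigma_exponent,
    }
    report.calibrations["semi-log"] = {
        "slope": semilog.slope,
        "intercept": semilog.intercept,
        "r_squared": semilog.r_squared,
        "rho_base": semilog.rho_base,
    }

    if absorptivity is not None:
        optics = MediumOptics(absorptivity=absorptivity)
        for name, geom in registry.items():
            try:
                res = effective_dose(set_dose_for_dprime, geom, optics)
            except Exception as exc:
                raise type(exc)(f"[D' stage, vessel {name!r}] {exc}") from exc
            report.effective_doses[name] = {
                "set_dose": res.set_dose,
                "effective_dose": res.effective_dose,
                "transmitted_fraction": res.transmitted_fraction,
            }
    return report
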