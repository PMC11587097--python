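"""Synthetic data generators mirroring the pipeline's input shapes.

Three generators, all pure functions of their arguments and a mandatory
seed:

* 4PL-shaped dose-response tables with replicate noise and an optional
  multiplicative high-dose decline (UV-inflammation data drop again at
  cytotoxic doses; the decline here exists to exercise tail trimming,
  not to model cell death);
* per-vessel D_1/2 panels following a known power-law, exponential or
  effective-dose rule, for calibration round trips;
* linear-through-origin dilution/absorbance series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseDataset, FourPLParams, four_pl
from .effective import effective_dose
from .errors import ValidationError
from .geometry import WellGeometry
from .optics import DilutionSeries, MediumOptics

__all__ = [
    "SyntheticSpec",
    "generate_4pl_dataset",
    "generate_vessel_panel",
    "generate_dilution_series",
]

#: instrument set doses used in the underlying exposure experiments (mJ/cm^2)
DEFAULT_DOSE_GRID = (0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 200.0, 500.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic dose-response dataset.

    Defaults emulate the replicate assays behind the worked examples:
    the instrument's dose grid, 3 independent replicates, additive
    Gaussian noise with SD equal to 5% of the upper plateau, and a 30%
    multiplicative decline above ``tail_threshold`` mimicking the
    high-dose drop in cytokine release.
    """

    truth: FourPLParams
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    replicates: int = 3
    noise_sd: float | None = None  # None -> 5% of the upper plateau
    proportional_noise: bool = False
    tail_drop_fraction: float = 0.0
    tail_threshold: float | None = None  # None -> strictly above the 2nd-highest dose
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_grid, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValidationError("dose grid must be strictly ascending")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.tail_drop_fraction < 1.0):
            raise ValidationError("tail_drop_fraction must lie in [0, 1)")


def generate_4pl_dataset(spec: SyntheticSpec, vessel: str = "synthetic") -> DoseResponseDataset:
    """Draw a replicate dose-response table from a known 4PL truth.

    Mean responses follow the truth curve; doses strictly above the tail
    threshold have their mean multiplied by (1 - tail_drop_fraction)
    before noise is added.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    doses = np.repeat(np.asarray(spec.dose_grid, dtype=float), spec.replicates)
    mean = four_pl(
        doses,
        spec.truth.lower_plateau,
        spec.truth.slope_factor,
        spec.truth.midpoint,
        spec.truth.upper_plateau,
    )
    if spec.tail_drop_fraction > 0:
        threshold = (
            spec.tail_threshold
            if spec.tail_threshold is not None
            else sorted(set(spec.dose_grid))[-2]
        )
        mean = np.where(doses > threshold, mean * (1.0 - spec.tail_drop_fraction), mean)
    sd = (
        spec.noise_sd
        if spec.noise_sd is not None
        else 0.05 * abs(spec.truth.upper_plateau)
    )
    if spec.proportional_noise:
        noise = rng.normal(0.0, 1.0, doses.size) * sd * np.abs(mean)
    else:
        noise = rng.normal(0.0, sd, doses.size)
    return DoseResponseDataset(
        vessel=vessel,
        doses=tuple(doses),
        responses=tuple(mean + noise),
        response_kind="synthetic",
    )


def generate_vessel_panel(
    vessels: dict[str, WellGeometry],
    rule: str = "power-law",
    exponent: float = 0.687,
    base: float = 5.0,
    absorptivity: float | None = None,
    d_half_reference: float = 72.0,
    noise_sd_log: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-vessel D_1/2 table following a known cross-vessel rule.

    rule "power-law":      D_1/2 = d_half_reference * S**(-exponent)
                           (d_half_reference is the value at S = 1 cm^2);
    rule "exponential":    D_1/2 = d_half_reference * base**r
                           (value at r = 0);
    rule "effective-dose": D_1/2 = d_half_reference / (D'/D fraction),
                           i.e. vessels transmitting less need more dose.

    Lognormal noise multiplies each value by 10**N(0, noise_sd_log).
    Returns a tidy frame with columns vessel, S_cm2, r, D_half.
    """
    if len(vessels) < 3:
        raise ValidationError("need >= 3 vessels for a calibration panel")
    rng = np.random.default_rng(seed)
    rows = []
    for name, geom in vessels.items():
        if rule == "power-law":
            d_half = d_half_reference * geom.surface_area ** (-exponent)
        elif rule == "exponential":
            d_half = d_half_reference * base**geom.aspect_ratio
        elif rule == "effective-dose":
            if absorptivity is None:
                raise ValidationError("effective-dose rule requires an absorptivity")
            frac = effective_dose(
                1.0, geom, MediumOptics(absorptivity=absorptivity)
            ).transmitted_fraction
            d_half = d_half_reference / frac
        else:
            raise ValidationError(f"unknown panel rule {rule!r}")
        d_half *= 10.0 ** rng.normal(0.0, noise_sd_log)
        rows.append(
            {"vessel": name, "S_cm2": geom.surface_area, "r": geom.aspect_ratio, "D_half": d_half}
        )
    return pd.DataFrame(rows)


def generate_dilution_series(
    eps_true: float,
    n_halvings: int = 3,
    noise_sd: float = 0.002,
    path_length: float = 1.0,
    seed: int = 0,
) -> DilutionSeries:
    """Serial-halving dilution series with Gaussian absorbance noise.

    Concentrations (1, 1/2, ..., 1/2**n_halvings) relative to the
    undiluted medium; absorbances eps_true * c * l + noise.
    """
    if n_halvings < 1:
        raise ValidationError("n_halvings must be >= 1")
    rng = np.random.default_rng(seed)
    conc = 0.5 ** np.arange(n_halvings + 1)
    a = eps_true * conc * path_length + rng.normal(0.0, noise_sd, conc.size)
    return DilutionSeries(
        concentrations=tuple(conc),
        absorbances=tuple(a),
        path_length=path_length,
    )
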