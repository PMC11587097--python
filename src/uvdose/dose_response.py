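"""Four-parameter logistic (4PL) dose-response fitting.

The target model is

    y = d + (a - d) / (1 + (x/c)**b)

with ``a`` the response at zero dose (lower plateau for an increasing
curve), ``d`` the asymptotic response, ``b`` the slope factor and ``c``
the midpoint: the dose producing a response halfway between the plateaus.
On a UV-dose axis the fitted ``c`` is the half-effect dose D_1/2 (an EC50
on the dose axis).

UV-inflammation data typically *decline* again at the highest doses
(cytotoxicity overtakes cytokine release), so the descending high-dose
tail is trimmed before fitting; :func:`trim_descending_tail` implements
both the "drop the top dose group" rule and a general trailing-run rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, NumericalError, ValidationError

__all__ = [
    "DoseResponseDataset",
    "FourPLParams",
    "four_pl",
    "trim_descending_tail",
    "fit_4pl",
    "ec50",
]

MIN_DOSES_FOR_4PL = 4


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicate-level dose-response observations for one vessel.

    ``doses`` (mJ/cm^2) may repeat; repeats are replicates of one dose
    group.  ``responses`` are in whatever units the assay reports (e.g.
    pg/mL IL-6 or relative viability).
    """

    vessel: str
    doses: tuple[float, ...]
    responses: tuple[float, ...]
    response_kind: str = "response"

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.shape != r.shape:
            raise ValidationError("doses and responses must have equal length")
        if d.size == 0:
            raise InsufficientDataError("empty dataset")
        if np.any(d < 0):
            raise ValidationError("doses must be >= 0")
        if not np.all(np.isfinite(r)):
            raise ValidationError("responses must be finite")

    @property
    def dose_groups(self) -> np.ndarray:
        """Unique doses, ascending."""
        return np.unique(np.asarray(self.doses, dtype=float))

    def group_means(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique ascending doses, mean response per dose group)."""
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        groups = np.unique(d)
        means = np.array([r[d == g].mean() for g in groups])
        return groups, means


@dataclass(frozen=True)
class FourPLParams:
    """Fitted 4PL parameters.

    Field names avoid the single letters a/b/c/d so the response-scale
    parameters cannot be confused with the geometric radius ``a``.
    """

    lower_plateau: float
    slope_factor: float
    midpoint: float
    upper_plateau: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.midpoint > 0):
            raise ValidationError(f"midpoint D_1/2 must be > 0, got {self.midpoint}")

    def predict(self, doses):
        return four_pl(
            doses, self.lower_plateau, self.slope_factor, self.midpoint, self.upper_plateau
        )


def four_pl(x, lower, slope, midpoint, upper):
    """Evaluate the 4PL curve; defined at x = 0 by its limit.

    For slope > 0 the x = 0 limit is ``lower``; for slope < 0 the roles of
    the plateaus swap (the curve then decreases from ``upper``... i.e. the
    zero-dose value is ``upper``).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    zero = x == 0
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.power(x[~zero] / midpoint, slope)
    out[~zero] = upper + (lower - upper) / (1.0 + ratio)
    out[zero] = lower if slope > 0 else upper
    return float(out[0]) if scalar else out


def trim_descending_tail(dataset: DoseResponseDataset, mode: str = "descending") -> DoseResponseDataset:
    """Remove the high-dose decline before sigmoid fitting.

    mode "highest": drop exactly the top dose group.
    mode "descending": drop the maximal trailing run of dose groups whose
    mean response falls below the running maximum of the preceding group
    means; the retained set is always a prefix of the dose grid ending at
    (or after) the argmax group.

    Raises :class:`InsufficientDataError` if fewer than 4 dose groups
    would remain.
    """
    groups, means = dataset.group_means()
    if groups.size < 2:
        raise InsufficientDataError("need at least 2 dose groups to trim")
    if mode == "highest":
        keep = groups.size - 1
    elif mode == "descending":
        keep = groups.size
        while keep > 1 and means[keep - 1] < means[: keep - 1].max():
            keep -= 1
    else:
        raise ValidationError(f"unknown trim mode {mode!r}")
    if keep < MIN_DOSES_FOR_4PL:
        raise InsufficientDataError(
            f"trimming leaves {keep} dose groups; >= {MIN_DOSES_FOR_4PL} required for a 4PL fit"
        )
    retained = set(groups[:keep])
    d = np.asarray(dataset.doses, dtype=float)
    mask = np.array([v in retained for v in d])
    return replace(
        dataset,
        doses=tuple(np.asarray(dataset.doses, dtype=float)[mask]),
        responses=tuple(np.asarray(dataset.responses, dtype=float)[mask]),
    )


def _initial_guess(doses: np.ndarray, means: np.ndarray) -> tuple[float, float, float, float]:
    positive = doses[doses > 0]
    c0 = float(np.exp(np.mean(np.log(positive)))) if positive.size else 1.0
    return float(means.min()), 1.0, c0, float(means.max())


def fit_4pl(
    doses,
    responses,
    init: tuple[float, float, float, float] | None = None,
    bounds: tuple | None = None,
    fit_means: bool = True,
    max_nfev: int = 10_000,
) -> FourPLParams:
    """Nonlinear least-squares 4PL fit; returns parameters and R^2.

    By default the fit is performed on per-dose means (the mean +/- SD
    presentation of replicate assays); pass ``fit_means=False`` to fit all
    replicates.  ``init`` is (lower, slope, midpoint, upper); the default
    is data-driven and deterministic: plateaus from the extreme means, the
    midpoint from the geometric mean of the positive doses, slope 1.  The
    midpoint is constrained positive; the slope is unconstrained in sign.
    """
    dataset = DoseResponseDataset("_", tuple(np.ravel(doses)), tuple(np.ravel(responses)))
    if dataset.dose_groups.size < MIN_DOSES_FOR_4PL:
        raise InsufficientDataError(
            f">= {MIN_DOSES_FOR_4PL} distinct doses required, got {dataset.dose_groups.size}"
        )
    if fit_means:
        x, y = dataset.group_means()
    else:
        x = np.asarray(dataset.doses, dtype=float)
        y = np.asarray(dataset.responses, dtype=float)
    if np.ptp(y) == 0:
        raise NumericalError("degenerate (constant) response; 4PL parameters unidentifiable")

    p0 = init if init is not None else _initial_guess(x, y)
    lo = (-np.inf, -np.inf, 1e-12, -np.inf)
    hi = (np.inf, np.inf, np.inf, np.inf)
    if bounds is not None:
        lo, hi = bounds

    def model(xx, lower, slope, midpoint, upper):
        return four_pl(xx, lower, slope, midpoint, upper)

    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0, bounds=(lo, hi), max_nfev=max_nfev, ftol=1e-10, xtol=1e-10
        )
    except (RuntimeError, ValueError) as exc:
        raise NumericalError(
            f"4PL fit did not converge: {exc}",
            diagnostics={"init": p0, "n_doses": int(x.size)},
        ) from exc

    resid = y - model(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return FourPLParams(
        lower_plateau=float(popt[0]),
        slope_factor=float(popt[1]),
        midpoint=float(popt[2]),
        upper_plateau=float(popt[3]),
        r_squared=r2,
    )


def ec50(params: FourPLParams) -> float:
    """The half-effect dose D_1/2: the fitted midpoint, in mJ/cm^2."""
    return params.midpoint
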