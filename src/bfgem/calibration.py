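"""Fitting the ATP maintenance coefficients (GAM, NGAM) to growth data.

Growth-associated maintenance (GAM, mmol ATP per gDW of biomass formed)
and non-growth-associated maintenance (NGAM, mmol ATP/gDW/h) are the
two free energetic parameters of a genome-scale model.  They are fitted
by minimizing the *maximum* relative error between model-predicted and
observed growth rates over a panel of literature conditions, using
Nelder-Mead simplex search from an initial guess of (100, 6) — a
minimax criterion, so the worst-fitting condition is the one driving
the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .biomass import set_maintenance
from .fba import MediumSpec, apply_medium, optimize
from .model import MetabolicModel

__all__ = [
    "GrowthObservation",
    "CalibrationResult",
    "predict_mu",
    "calibrate",
    "error_report",
]

# large penalty steering the simplex away from negative coefficients
_NEGATIVE_PENALTY = 1e3


@dataclass
class GrowthObservation:
    label: str
    medium: MediumSpec
    observed_mu: float  # 1/h

    def __post_init__(self) -> None:
        if self.observed_mu <= 0:
            raise ValueError(f"observation {self.label!r}: observed_mu must be > 0")


@dataclass
class CalibrationResult:
    gam: float
    ngam: float
    predicted_mu: dict[str, float]
    observed_mu: dict[str, float]
    max_relative_error: float
    mean_percent_error: float
    trace: list[tuple[float, float, float]] = field(default_factory=list)
    converged: bool = True


def predict_mu(
    model: MetabolicModel, gam: float, ngam: float, medium: MediumSpec
) -> float:
    """FBA growth rate with the given maintenance coefficients installed.

    Infeasible problems (e.g. NGAM above the medium's ATP capacity)
    return 0 with a warning rather than raising, so a calibration can
    treat them as maximal error.
    """
    probe = set_maintenance(model, gam, ngam)
    probe = apply_medium(probe, medium)
    sol = optimize(probe)
    if not sol.ok:
        warnings.warn(
            f"growth prediction {sol.status} at GAM={gam:.4g}, NGAM={ngam:.4g}; "
            "treating as zero growth",
            stacklevel=2,
        )
        return 0.0
    return max(0.0, sol.objective_value)


def _max_relative_error(predicted: dict[str, float], observed: dict[str, float]) -> float:
    return max(abs(predicted[k] - observed[k]) / observed[k] for k in observed)


def calibrate(
    model: MetabolicModel,
    observations: list[GrowthObservation],
    initial: tuple[float, float] = (100.0, 6.0),
    xatol: float = 1e-4,
    fatol: float = 1e-6,
    restarts: list[tuple[float, float]] | None = None,
) -> CalibrationResult:
    """Fit (GAM, NGAM) by minimax relative error over growth observations.

    Nelder-Mead with standard coefficients; negative parameter values
    are repelled by a penalty rather than hard bounds (the simplex is
    unconstrained).  Optional ``restarts`` re-run the search from a grid
    of initial guesses and keep the best basin, which also serves as a
    uniqueness check.
    """
    if len(observations) < 2:
        raise ValueError("calibration needs at least two observations "
                         "(GAM and NGAM are confounded with fewer)")
    observed = {o.label: o.observed_mu for o in observations}
    media = {o.label: o.medium for o in observations}
    trace: list[tuple[float, float, float]] = []

    def objective(x: np.ndarray) -> float:
        gam, ngam = float(x[0]), float(x[1])
        if gam < 0 or ngam < 0:
            return _NEGATIVE_PENALTY + abs(min(gam, 0)) + abs(min(ngam, 0))
        predicted = {
            lab: predict_mu(model, gam, ngam, media[lab]) for lab in observed
        }
        err = _max_relative_error(predicted, observed)
        trace.append((gam, ngam, err))
        return err

    starts = [tuple(initial)] + list(restarts or [])
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    gam, ngam = float(best.x[0]), float(best.x[1])
    gam, ngam = max(gam, 0.0), max(ngam, 0.0)
    predicted = {lab: predict_mu(model, gam, ngam, media[lab]) for lab in observed}
    if all(v == 0.0 for v in predicted.values()):
        raise RuntimeError(
            "calibration landscape is all-infeasible: no condition supports growth"
        )
    errors = {lab: abs(predicted[lab] - observed[lab]) / observed[lab] for lab in observed}
    return CalibrationResult(
        gam=gam,
        ngam=ngam,
        predicted_mu=predicted,
        observed_mu=dict(observed),
        max_relative_error=max(errors.values()),
        mean_percent_error=100.0 * float(np.mean(list(errors.values()))),
        trace=trace,
        converged=bool(best.success),
    )


def error_report(result: CalibrationResult) -> pd.DataFrame:
    """Per-condition predicted vs observed growth with error summaries."""
    rows = []
    for lab, obs in result.observed_mu.items():
        pred = result.predicted_mu[lab]
        rows.append(
            {
                "condition": lab,
                "observed_mu": obs,
                "predicted_mu": pred,
                "relative_error": abs(pred - obs) / obs,
            }
        )
    df = pd.DataFrame(rows).set_index("condition")
    df.attrs["max_relative_error"] = result.max_relative_error
    df.attrs["mean_percent_error"] = result.mean_percent_error
    df.attrs["gam"] = result.gam
    df.attrs["ngam"] = result.ngam
    return df
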