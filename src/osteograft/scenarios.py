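"""The three published modeling scenarios, end to end.

Each scenario builds a design from the study table, selects the number of
latent components by leave-one-out RMSE, fits the PLSR model, and reports
the back-transformed equation together with cross-validated predictions,
predicted-vs-measured correlations (both held-out and fitted mode) and
residuals:

- ``all_grafts``     — all seven materials; predictors CaCO3 wt%, Ti wt%,
  macroporosity;
- ``exclude_natix``  — calcium-phosphate materials only (titanium graft
  dropped); predictors CaCO3 wt%, H2O wt%, macroporosity;
- ``exclude_ostim``  — the aqueous paste dropped; same predictor set as
  ``all_grafts``.

The module reports raw numbers; any tolerance policy for comparing against
published coefficients belongs to the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import pls
from .dataset import StudyTable, design_matrix
from .pls import CVCurve, FittedEquation, PLSModel

__all__ = [
    "ScenarioError",
    "ScenarioSpec",
    "ScenarioReport",
    "SCENARIOS",
    "run_scenario",
    "run_all",
    "predict_new",
    "comparison_table",
]


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """A named modeling scenario: exclusions, predictor set, component cap."""

    name: str
    excluded: tuple[str, ...]
    predictors: tuple[str, ...]
    a_max: int | None = None  # default min(p, n−2), set at run time


SCENARIOS: dict[str, ScenarioSpec] = {
    "all_grafts": ScenarioSpec(
        name="all_grafts",
        excluded=(),
        predictors=("caco3_wt", "ti_wt", "macroporosity"),
    ),
    "exclude_natix": ScenarioSpec(
        name="exclude_natix",
        excluded=("Natix",),
        predictors=("caco3_wt", "h2o_wt", "macroporosity"),
    ),
    "exclude_ostim": ScenarioSpec(
        name="exclude_ostim",
        excluded=("Ostim",),
        predictors=("caco3_wt", "ti_wt", "macroporosity"),
    ),
}


@dataclass(frozen=True)
class ScenarioReport:
    """Audit-ready record of one fitted scenario."""

    spec: ScenarioSpec
    rows: tuple[str, ...]
    equation: FittedEquation
    cv: CVCurve
    selected_a: int
    measured: np.ndarray
    fitted: np.ndarray
    loo_predictions: np.ndarray
    residuals: np.ndarray          # measured − fitted, exactly
    r_loo: float
    r_fitted: float
    predictor_ranges: dict[str, tuple[float, float]]
    scale: bool = True
    model: PLSModel = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "scenario": self.spec.name,
            "excluded": list(self.spec.excluded),
            "predictors": list(self.spec.predictors),
            "rows": list(self.rows),
            "selected_a": self.selected_a,
            "equation": self.equation.to_dict(),
            "equation_text": self.equation.to_text(),
            "cv": self.cv.to_dict(),
            "measured": self.measured.tolist(),
            "fitted": self.fitted.tolist(),
            "loo_predictions": self.loo_predictions.tolist(),
            "residuals": self.residuals.tolist(),
            "r_loo": self.r_loo,
            "r_fitted": self.r_fitted,
            "predictor_ranges": {k: list(v) for k, v in self.predictor_ranges.items()},
            "scale": self.scale,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def run_scenario(table: StudyTable, spec: ScenarioSpec, *, scale: bool = True) -> ScenarioReport:
    """Fit one scenario: LOO component selection, fit, back-transform, audit."""
    design = design_matrix(table, spec.predictors, exclude=spec.excluded)
    n, p = design.X.shape
    a_max = min(p, n - 2)
    if spec.a_max is not None:
        a_max = min(a_max, spec.a_max)
    cv = pls.loo_rmse(design.X, design.y, a_max, scale=scale, labels=design.labels)
    a = cv.selected_a
    model = pls.fit_pls(
        design.X, design.y, a, scale=scale, labels=design.labels, allow_constant=True
    )
    eqn = pls.to_equation(model)
    fitted = np.asarray(eqn.predict(design.X), dtype=float)
    loo_pred = cv.predictions[a]
    return ScenarioReport(
        spec=spec,
        rows=design.rows,
        equation=eqn,
        cv=cv,
        selected_a=a,
        measured=design.y,
        fitted=fitted,
        loo_predictions=loo_pred,
        residuals=design.y - fitted,
        r_loo=pls.pred_obs_correlation(loo_pred, design.y),
        r_fitted=pls.pred_obs_correlation(fitted, design.y),
        predictor_ranges={
            lab: (float(design.X[:, j].min()), float(design.X[:, j].max()))
            for j, lab in enumerate(design.labels)
        },
        scale=scale,
        model=model,
    )


def run_all(table: StudyTable, *, scale: bool = True) -> dict[str, ScenarioReport]:
    """Run the three published scenarios; see :func:`comparison_table`."""
    return {name: run_scenario(table, spec, scale=scale) for name, spec in SCENARIOS.items()}


def comparison_table(reports: dict[str, ScenarioReport]) -> "pd.DataFrame":
    """Side-by-side coefficient summary of several scenario reports."""
    import pandas as pd

    rows = []
    for name, rep in reports.items():
        row: dict[str, object] = {
            "scenario": name,
            "n": len(rep.rows),
            "selected_a": rep.selected_a,
            "intercept": rep.equation.intercept,
            "r_loo": rep.r_loo,
            "r_fitted": rep.r_fitted,
            "loo_rmse": rep.cv.rmse_by_components[rep.selected_a],
        }
        for k, v in rep.equation.coefficients.items():
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")


def predict_new(report: ScenarioReport, values: dict[str, float]) -> tuple[float, list[str]]:
    """Predict BMC for a new material from a scenario's fitted equation.

    ``values`` maps each scenario predictor to its value (wt% or percent).
    Returns the prediction and a list of warnings; inputs outside the
    training min/max box are flagged (the equation extrapolates linearly
    there). Negative composition or porosity values are errors.
    """
    missing = [k for k in report.spec.predictors if k not in values]
    if missing:
        raise ScenarioError(f"missing predictor value(s) {missing}")
    flags: list[str] = []
    for k in report.spec.predictors:
        v = float(values[k])
        if v < 0:
            raise ScenarioError(f"{k} = {v} is negative")
        lo, hi = report.predictor_ranges[k]
        if not (lo <= v <= hi):
            flags.append(f"{k} = {v:g} outside the training range [{lo:g}, {hi:g}]")
    pred = report.equation.predict({k: float(values[k]) for k in report.spec.predictors})
    return float(pred), flags
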