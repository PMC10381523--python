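"""Univariate-response partial least squares regression (NIPALS).

The engine behind the empirical structure–outcome models: PLSR projects a
small, collinear predictor block onto latent components that maximize
covariance with the response, which keeps the fit stable at n of the order
of the number of predictors — the regime of a seven-material study.

For a single response the NIPALS inner iteration collapses to a closed form
per component: w_a ∝ X'y on the deflated residuals, t_a = X w_a, followed
by rank-one deflation. At A = rank(X) the coefficients coincide with the
ordinary least-squares solution; with fewer components they are shrunk
toward the leading covariance directions.

Model assessment uses leave-one-out cross-validation: each material is held
out once, the model is refit on the rest, and the pooled RMSE of held-out
predictions is minimized over the number of components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PLSError",
    "ZeroVarianceError",
    "PLSModel",
    "FittedEquation",
    "CVCurve",
    "EliminationStep",
    "EliminationResult",
    "fit_pls",
    "to_equation",
    "predict",
    "loo_predictions",
    "loo_rmse",
    "vip_scores",
    "backward_eliminate",
    "pred_obs_correlation",
]

_EPS = 1e-12


class PLSError(ValueError):
    """Base class for regression-engine failures."""


class ZeroVarianceError(PLSError):
    """A predictor column is constant and cannot be autoscaled."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"predictor column {column!r} has zero variance")


@dataclass(frozen=True)
class PLSModel:
    """Centered/autoscaled NIPALS decomposition of one X, y block.

    ``coef_scaled`` maps standardized predictors to the standardized
    response; :func:`to_equation` back-transforms to original units.
    Scores in ``T`` are mutually orthogonal by construction.
    """

    n_components: int
    x_means: np.ndarray
    x_scales: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray      # p × A, unit columns
    x_loadings: np.ndarray   # p × A
    y_loadings: np.ndarray   # A
    scores: np.ndarray       # n × A (training scores)
    coef_scaled: np.ndarray  # p
    labels: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "labels": list(self.labels),
            "x_means": self.x_means.tolist(),
            "x_scales": self.x_scales.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef_scaled": self.coef_scaled.tolist(),
        }


@dataclass(frozen=True)
class FittedEquation:
    """Back-transformed affine model in original units (response: % BMC)."""

    intercept: float
    coefficients: dict[str, float]

    def predict(self, values) -> np.ndarray | float:
        """Evaluate the equation.

        ``values`` may be a mapping label → value (returns a scalar), a 1-D
        array ordered like ``coefficients``, or a 2-D array with one row per
        observation.
        """
        labels = tuple(self.coefficients)
        beta = np.array([self.coefficients[k] for k in labels])
        if isinstance(values, Mapping):
            missing = [k for k in labels if k not in values]
            if missing:
                raise PLSError(f"missing predictor value(s) {missing}")
            x = np.array([float(values[k]) for k in labels])
            return float(self.intercept + x @ beta)
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 1:
            if arr.shape[0] != len(labels):
                raise PLSError(f"expected {len(labels)} values, got {arr.shape[0]}")
            return float(self.intercept + arr @ beta)
        if arr.shape[1] != len(labels):
            raise PLSError(f"expected {len(labels)} columns, got {arr.shape[1]}")
        return self.intercept + arr @ beta

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients)}

    def to_text(self, response: str = "BMC (%)") -> str:
        """Human-readable equation, e.g. ``BMC (%) = 58.14 + 3.60 * caco3_wt``."""
        parts = [f"{response} = {self.intercept:.2f}"]
        for k, v in self.coefficients.items():
            sign = "+" if v >= 0 else "-"
            parts.append(f"{sign} {abs(v):.2f} * {k}")
        return " ".join(parts)


@dataclass(frozen=True)
class CVCurve:
    """Leave-one-out RMSE as a function of the number of components."""

    rmse_by_components: dict[int, float]
    selected_a: int
    predictions: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    invalid: frozenset[int] = frozenset()

    def to_dict(self) -> dict:
        return {
            "rmse_by_components": {str(k): v for k, v in self.rmse_by_components.items()},
            "selected_a": self.selected_a,
            "invalid": sorted(self.invalid),
        }


def _prepare(X: np.ndarray, y: np.ndarray, labels: Sequence[str] | None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise PLSError("X must be a 2-D array")
    n, p = X.shape
    if y.shape[0] != n:
        raise PLSError(f"X has {n} rows but y has {y.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise PLSError("non-finite values in X or y")
    if labels is None:
        labels = tuple(f"x{j}" for j in range(p))
    else:
        labels = tuple(labels)
        if len(labels) != p:
            raise PLSError(f"{len(labels)} labels for {p} columns")
    return X, y, labels


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    scale: bool = True,
    labels: Sequence[str] | None = None,
    allow_constant: bool = False,
) -> PLSModel:
    """Fit a univariate-response PLSR model by closed-form NIPALS.

    Parameters
    ----------
    n_components:
        Requested number of latent components A ≤ min(p, n−1). Extraction
        stops early if the residual block is exhausted (rank deficiency);
        the fitted model records the number actually extracted.
    scale:
        Autoscale predictors and response to unit variance (n−1 SD) after
        centering. With ``scale=False`` only centering is applied.
    allow_constant:
        Treat constant columns as inert (scale 1, zero weight) instead of
        raising :class:`ZeroVarianceError`. Used by cross-validation folds
        in which a predictor degenerates (e.g. the single titanium material
        held out).
    """
    X, y, labels = _prepare(X, y, labels)
    n, p = X.shape
    if n < 3:
        raise PLSError(f"need at least 3 rows, got {n}")
    A = int(n_components)
    if not (1 <= A <= min(p, n - 1)):
        raise PLSError(f"n_components={A} outside [1, min(p, n-1)={min(p, n-1)}]")

    x_means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd <= _EPS * np.maximum(1.0, np.abs(x_means))
    if np.any(constant) and not allow_constant:
        raise ZeroVarianceError(labels[int(np.flatnonzero(constant)[0])])
    if scale:
        x_scales = np.where(constant, 1.0, sd)
    else:
        x_scales = np.ones(p)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd <= _EPS:
        y_scale = 1.0
    else:
        y_scale = y_sd if scale else 1.0

    Xr = (X - x_means) / x_scales
    yr = (y - y_mean) / y_scale
    norm0 = max(1.0, float(np.linalg.norm(Xr)))

    W, P, q, T = [], [], [], []
    for _ in range(A):
        w = Xr.T @ yr
        wn = float(np.linalg.norm(w))
        if wn <= 1e-10 * norm0:
            break  # residual covariance exhausted
        w /= wn
        t = Xr @ w
        tt = float(t @ t)
        if tt <= (1e-10 * norm0) ** 2:
            break
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p_a)
        yr = yr - q_a * t
        W.append(w)
        P.append(p_a)
        q.append(q_a)
        T.append(t)
    if not W:
        raise PLSError("no component could be extracted (response uncorrelated or constant)")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(q)
    Tm = np.column_stack(T)
    coef_scaled = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return PLSModel(
        n_components=Wm.shape[1],
        x_means=x_means,
        x_scales=x_scales,
        y_mean=y_mean,
        y_scale=y_scale,
        weights=Wm,
        x_loadings=Pm,
        y_loadings=qv,
        scores=Tm,
        coef_scaled=coef_scaled,
        labels=labels,
    )


def to_equation(model: PLSModel) -> FittedEquation:
    """Back-transform a fitted model to an original-scale affine equation."""
    coefs = model.coef_scaled * model.y_scale / model.x_scales
    intercept = model.y_mean - float(coefs @ model.x_means)
    return FittedEquation(
        intercept=float(intercept),
        coefficients={k: float(c) for k, c in zip(model.labels, coefs)},
    )


def predict(model_or_equation, X_new) -> np.ndarray | float:
    """Predict responses from a :class:`PLSModel` or :class:`FittedEquation`."""
    if isinstance(model_or_equation, PLSModel):
        eqn = to_equation(model_or_equation)
    elif isinstance(model_or_equation, FittedEquation):
        eqn = model_or_equation
    else:
        raise PLSError(f"cannot predict from {type(model_or_equation).__name__}")
    return eqn.predict(X_new)


def loo_predictions(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    scale: bool = True,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Held-out prediction for each row under leave-one-out refitting.

    Columns that are constant within a training fold are inert there
    (coefficient 0); a fold whose design is entirely constant yields NaN.
    """
    X, y, labels = _prepare(X, y, labels)
    n = X.shape[0]
    if n < 4:
        raise PLSError(f"leave-one-out needs at least 4 rows, got {n}")
    preds = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        sd = Xi.std(axis=0, ddof=1)
        if np.all(sd <= _EPS * np.maximum(1.0, np.abs(Xi.mean(axis=0)))):
            continue  # fold design entirely constant: no model
        a = min(n_components, Xi.shape[0] - 1)
        m = fit_pls(Xi, yi, a, scale=scale, labels=labels, allow_constant=True)
        preds[i] = to_equation(m).predict(X[i])
    return preds


def loo_rmse(
    X: np.ndarray,
    y: np.ndarray,
    a_max: int,
    *,
    scale: bool = True,
    labels: Sequence[str] | None = None,
) -> CVCurve:
    """Leave-one-out RMSE curve over A = 1..a_max with argmin selection.

    RMSE pools all n held-out squared errors before the square root. Ties
    resolve to the smallest A. An A whose folds produced no valid model is
    flagged invalid and excluded from selection.
    """
    X, y, labels = _prepare(X, y, labels)
    n, p = X.shape
    a_max = int(a_max)
    if not (1 <= a_max <= min(p, n - 2)):
        raise PLSError(f"a_max={a_max} outside [1, min(p, n-2)={min(p, n - 2)}]")
    rmse: dict[int, float] = {}
    preds: dict[int, np.ndarray] = {}
    invalid = set()
    for a in range(1, a_max + 1):
        pr = loo_predictions(X, y, a, scale=scale, labels=labels)
        if np.any(~np.isfinite(pr)):
            invalid.add(a)
            rmse[a] = float("nan")
            preds[a] = pr
            continue
        rmse[a] = float(np.sqrt(np.mean((y - pr) ** 2)))
        preds[a] = pr
    valid = [a for a in rmse if a not in invalid]
    if not valid:
        raise PLSError("every component count was invalid under leave-one-out")
    selected = min(valid, key=lambda a: (rmse[a], a))
    return CVCurve(
        rmse_by_components=rmse,
        selected_a=selected,
        predictions=preds,
        invalid=frozenset(invalid),
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection; the squared scores average to 1.

    VIP_j = sqrt( p · Σ_a SS_a w_{ja}² / Σ_a SS_a ) with SS_a = q_a² t_a't_a
    the response variance captured by component a.
    """
    ss = model.y_loadings**2 * np.einsum("ia,ia->a", model.scores, model.scores)
    p = model.weights.shape[0]
    num = (model.weights**2) @ ss
    return np.sqrt(p * num / ss.sum())


@dataclass(frozen=True)
class EliminationStep:
    """One audit entry of the backward predictor elimination."""

    labels: tuple[str, ...]
    selected_a: int
    rmse: float
    criterion: dict[str, float]
    dropped: str | None


@dataclass(frozen=True)
class EliminationResult:
    retained: tuple[str, ...]
    model: PLSModel
    cv: CVCurve
    trace: tuple[EliminationStep, ...]


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    *,
    labels: Sequence[str] | None = None,
    criterion: str = "vip",
    scale: bool = True,
    a_max: int | None = None,
) -> EliminationResult:
    """Iteratively drop the least-important predictor until LOO RMSE worsens.

    At each step the component count is re-selected by leave-one-out RMSE;
    the lowest-ranked predictor (smallest VIP or absolute standardized
    coefficient) is removed, and the step is accepted only while the best
    LOO RMSE does not increase. The full trace is returned for audit.
    """
    if criterion not in ("vip", "abs_coef"):
        raise PLSError(f"unknown elimination criterion {criterion!r}")
    X, y, labels = _prepare(X, y, labels)
    n, p = X.shape
    if p < 2:
        cv = loo_rmse(X, y, min(p, n - 2), scale=scale, labels=labels)
        model = fit_pls(X, y, cv.selected_a, scale=scale, labels=labels, allow_constant=True)
        step = EliminationStep(labels, cv.selected_a, cv.rmse_by_components[cv.selected_a], {}, None)
        return EliminationResult(labels, model, cv, (step,))

    def evaluate(cols: list[int]):
        sub = X[:, cols]
        amax = min(len(cols), n - 2) if a_max is None else min(a_max, len(cols), n - 2)
        cv = loo_rmse(sub, y, amax, scale=scale, labels=[labels[c] for c in cols])
        model = fit_pls(
            sub, y, cv.selected_a, scale=scale,
            labels=[labels[c] for c in cols], allow_constant=True,
        )
        return cv, model

    cols = list(range(p))
    cv, model = evaluate(cols)
    trace: list[EliminationStep] = []
    while len(cols) > 1:
        if criterion == "vip":
            ranks = vip_scores(model)
        else:
            ranks = np.abs(model.coef_scaled)
        crit = {labels[c]: float(r) for c, r in zip(cols, ranks)}
        drop_idx = int(np.argmin(ranks))
        candidate = cols[:drop_idx] + cols[drop_idx + 1:]
        cv_new, model_new = evaluate(candidate)
        best_old = cv.rmse_by_components[cv.selected_a]
        best_new = cv_new.rmse_by_components[cv_new.selected_a]
        if best_new > best_old:
            trace.append(EliminationStep(
                tuple(labels[c] for c in cols), cv.selected_a, best_old, crit, None))
            break
        trace.append(EliminationStep(
            tuple(labels[c] for c in cols), cv.selected_a, best_old, crit,
            labels[cols[drop_idx]]))
        cols, cv, model = candidate, cv_new, model_new
    else:
        best = cv.rmse_by_components[cv.selected_a]
        trace.append(EliminationStep(tuple(labels[c] for c in cols), cv.selected_a, best, {}, None))
    return EliminationResult(
        retained=tuple(labels[c] for c in cols),
        model=model,
        cv=cv,
        trace=tuple(trace),
    )


def pred_obs_correlation(predicted, measured) -> float:
    """Pearson product-moment correlation between predictions and measurements."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    measured = np.asarray(measured, dtype=float).ravel()
    if predicted.shape != measured.shape or predicted.size < 3:
        raise PLSError("predicted and measured must have equal length ≥ 3")
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(measured))):
        raise PLSError("non-finite values in correlation input")
    if predicted.std() <= _EPS or measured.std() <= _EPS:
        raise PLSError("zero variance in correlation input")
    return float(np.corrcoef(predicted, measured)[0, 1])
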