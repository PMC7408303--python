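"""Prediction-accuracy statistics: coefficient of determination and MAE.

Conventions follow the source protocol exactly: ``y_obs`` denotes the
values *predicted from the placebo-calibrated transfer*, ``y_prd`` the
values read from the drug product's own response surface, and the R²
denominator centers on ``y_obs``.  A ``form="conventional"`` switch centers
on ``y_prd`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import UndefinedStatisticError
from .formulation import ExcipientComposition
from .surface import ResponseSurface, sample_compositions

__all__ = ["EvaluationSample", "PredictionReport", "r_squared", "mae", "evaluate_prediction"]


@dataclass(frozen=True)
class EvaluationSample:
    """Paired predictions over a set of sampled compositions."""

    compositions: tuple[ExcipientComposition, ...]
    y_obs: tuple[float, ...]  # placebo-calibrated predictions
    y_prd: tuple[float, ...]  # drug product's own surface values

    def __post_init__(self):
        if not (len(self.compositions) == len(self.y_obs) == len(self.y_prd)):
            raise ValueError("compositions, y_obs and y_prd must have equal length")
        if len(self.y_obs) < 2:
            raise ValueError("evaluation sample needs at least 2 points")


@dataclass(frozen=True)
class PredictionReport:
    """Accuracy summary for one calibrated prediction run."""

    r_squared: float
    mae: float
    residuals: tuple[float, ...]
    n: int
    seed: int | None = None

    def __post_init__(self):
        if self.mae < 0:
            raise ValueError("mae must be >= 0")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "mae": self.mae,
            "n": self.n,
            "seed": self.seed,
            "residuals": list(self.residuals),
        }


def r_squared(y_obs, y_prd, form: str = "paper") -> float:
    """``1 - SS_res / SS_tot`` with the stated centering convention.

    ``form="paper"`` (default) centers the denominator on the mean of
    ``y_obs`` (the calibrated predictions); ``form="conventional"`` centers
    on the mean of ``y_prd``.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_prd = np.asarray(y_prd, dtype=float)
    if y_obs.shape != y_prd.shape:
        raise ValueError("y_obs and y_prd must have the same shape")
    ss_res = float(np.sum((y_obs - y_prd) ** 2))
    if form == "paper":
        ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    elif form == "conventional":
        ss_tot = float(np.sum((y_prd - y_prd.mean()) ** 2))
    else:
        raise ValueError(f"unknown form {form!r}")
    if ss_tot == 0.0:
        raise UndefinedStatisticError(
            "centering vector has zero variance; R^2 is undefined"
        )
    return 1.0 - ss_res / ss_tot


def mae(y_obs, y_prd) -> float:
    """Mean absolute error between the paired vectors."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_prd = np.asarray(y_prd, dtype=float)
    if y_obs.shape != y_prd.shape:
        raise ValueError("y_obs and y_prd must have the same shape")
    if y_obs.size < 1:
        raise ValueError("mae needs at least 1 point")
    return float(np.mean(np.abs(y_obs - y_prd)))


def evaluate_prediction(
    predictor: Callable[[ExcipientComposition], float],
    api_surface: ResponseSurface,
    n: int = 500,
    seed: int = 0,
    form: str = "paper",
) -> PredictionReport:
    """Sample the domain and score the calibrated predictor.

    Draws ``n`` uniform compositions over the drug product surface's
    domain, computes the placebo-calibrated prediction and the surface's
    own value at each, and summarizes with R² and MAE.  Deterministic for a
    fixed seed.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    pts = sample_compositions(n, seed, api_surface.constraints)
    xy = np.array([p.xy for p in pts])
    if hasattr(predictor, "predict_xy"):
        y_obs = np.asarray(predictor.predict_xy(xy), dtype=float)
    else:
        y_obs = np.array([predictor(p) for p in pts], dtype=float)
    y_prd = api_surface.evaluate_xy(xy)
    resid = y_obs - y_prd
    return PredictionReport(
        r_squared=r_squared(y_obs, y_prd, form=form),
        mae=mae(y_obs, y_prd),
        residuals=tuple(float(r) for r in resid),
        n=n,
        seed=seed,
    )
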