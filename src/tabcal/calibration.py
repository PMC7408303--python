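"""Placebo-to-drug-product transfer models and composed predictors.

A calibration model maps a placebo surface value to the corresponding
drug-product value via a linear (``a*v + b``) or quadratic
(``a*v**2 + b*v + c``) transfer fitted on a handful of anchor recipes.
The tensile-strength protocol uses a single whole-domain linear model with
two anchors; the disintegration-time protocol uses a quadratic model on the
left half of the domain (three anchors) and a linear model on the right
half (two anchors).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import SingularFitError
from .formulation import ExcipientComposition, PropertyObservation
from .surface import (
    DEFAULT_PARTITION,
    NearestAnchorPartition,
    ResponseSurface,
    sample_compositions,
)

__all__ = [
    "Anchor",
    "CalibrationModel",
    "fit_linear",
    "fit_quadratic",
    "build_ts_predictor",
    "build_dt_predictor",
    "CalibratedPredictor",
    "RegionwisePredictor",
    "scatter_slope",
]

logger = logging.getLogger(__name__)

_DISTINCT_TOL = 1e-12


@dataclass(frozen=True)
class Anchor:
    """One anchor pair: placebo surface value vs observed drug-product mean."""

    recipe_id: str
    placebo_value: float
    api_value: float


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted transfer of placebo values to drug-product values.

    ``coeffs`` is ``(a, b)`` for linear models and ``(a, b, c)`` for
    quadratic ones, highest degree first.
    """

    kind: str  # "linear" | "quadratic"
    coeffs: tuple[float, ...]
    prop: str = "TS"
    region: str = "whole"  # "whole" | "left" | "right"
    anchor_ids: tuple[str, ...] = ()

    def __post_init__(self):
        expected = {"linear": 2, "quadratic": 3}.get(self.kind)
        if expected is None:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(self.coeffs) != expected:
            raise ValueError(
                f"{self.kind} model needs {expected} coefficients, "
                f"got {len(self.coeffs)}"
            )

    def predict(self, v):
        """Apply the transfer to a placebo value (scalar or array)."""
        return np.polyval(self.coeffs, v)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coeffs": list(self.coeffs),
            "prop": self.prop,
            "region": self.region,
            "anchor_ids": list(self.anchor_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            d["kind"],
            tuple(d["coeffs"]),
            d.get("prop", "TS"),
            d.get("region", "whole"),
            tuple(d.get("anchor_ids", ())),
        )


def _check_distinct(x: np.ndarray, needed: int, what: str) -> None:
    distinct = len({round(float(v), 12) for v in x})
    if distinct < needed:
        raise SingularFitError(
            f"{what} requires {needed} distinct placebo values, "
            f"got {distinct} among {x.tolist()}"
        )


def fit_linear(anchors: Sequence[Anchor], prop: str = "TS", region: str = "whole") -> CalibrationModel:
    """Fit ``api = a * placebo + b``.

    Exact interpolation with two anchors; ordinary least squares with more.
    """
    if len(anchors) < 2:
        raise SingularFitError("linear fit requires at least 2 anchors")
    x = np.array([a.placebo_value for a in anchors], dtype=float)
    y = np.array([a.api_value for a in anchors], dtype=float)
    _check_distinct(x, 2, "linear fit")
    if len(anchors) == 2:
        a = (y[1] - y[0]) / (x[1] - x[0])
        b = y[0] - a * x[0]
        coeffs = (float(a), float(b))
    else:
        A = np.column_stack([x, np.ones_like(x)])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        coeffs = (float(sol[0]), float(sol[1]))
    return CalibrationModel(
        "linear", coeffs, prop, region, tuple(a.recipe_id for a in anchors)
    )


def fit_quadratic(anchors: Sequence[Anchor], prop: str = "DT", region: str = "whole") -> CalibrationModel:
    """Fit ``api = a * placebo**2 + b * placebo + c``.

    Exact interpolation (Vandermonde solve) with three anchors; least
    squares with more.  Three collinear anchors degrade gracefully to
    ``a = 0`` and the linear solution.
    """
    if len(anchors) < 3:
        raise SingularFitError("quadratic fit requires at least 3 anchors")
    x = np.array([a.placebo_value for a in anchors], dtype=float)
    y = np.array([a.api_value for a in anchors], dtype=float)
    _check_distinct(x, 3, "quadratic fit")
    V = np.column_stack([x**2, x, np.ones_like(x)])
    if len(anchors) == 3:
        sol = np.linalg.solve(V, y)
    else:
        sol, *_ = np.linalg.lstsq(V, y, rcond=None)
    return CalibrationModel(
        "quadratic",
        tuple(float(c) for c in sol),
        prop,
        region,
        tuple(a.recipe_id for a in anchors),
    )


def _anchors_from_obs(
    placebo_surface: ResponseSurface, obs: Sequence[PropertyObservation]
) -> list[Anchor]:
    anchors = []
    for o in obs:
        if o.composition is None:
            raise ValueError(f"anchor observation {o.recipe_id} has no composition")
        anchors.append(Anchor(o.recipe_id, placebo_surface.evaluate(o.composition), o.mean))
    return anchors


@dataclass(frozen=True)
class CalibratedPredictor:
    """Whole-domain predictor: transfer applied to the placebo surface."""

    placebo_surface: ResponseSurface
    model: CalibrationModel

    def __call__(self, x: ExcipientComposition) -> float:
        v = float(self.model.predict(self.placebo_surface.evaluate(x)))
        if v < 0:
            logger.warning("negative predicted %s at %s: %g", self.model.prop, x.as_tuple(), v)
        return v

    def predict_xy(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(self.placebo_surface.evaluate_xy(xy)))


@dataclass(frozen=True)
class RegionwisePredictor:
    """Region-wise predictor: quadratic on the left cell, linear on the right."""

    placebo_surface: ResponseSurface
    left_model: CalibrationModel
    right_model: CalibrationModel
    partitioner: NearestAnchorPartition = DEFAULT_PARTITION

    def __call__(self, x: ExcipientComposition) -> float:
        model = (
            self.left_model
            if self.partitioner.label(x) == "left"
            else self.right_model
        )
        v = float(model.predict(self.placebo_surface.evaluate(x)))
        if v < 0:
            logger.warning("negative predicted %s at %s: %g", model.prop, x.as_tuple(), v)
        return v

    def predict_xy(self, xy: np.ndarray) -> np.ndarray:
        vals = self.placebo_surface.evaluate_xy(xy)
        labels = np.array(
            [
                self.partitioner.label(ExcipientComposition.from_xy(x, y))
                for x, y in np.asarray(xy, dtype=float)
            ]
        )
        out = np.empty_like(vals)
        left = labels == "left"
        out[left] = self.left_model.predict(vals[left])
        out[~left] = self.right_model.predict(vals[~left])
        return out


def build_ts_predictor(
    placebo_surface: ResponseSurface,
    anchor_obs: Sequence[PropertyObservation],
) -> CalibratedPredictor:
    """Tensile-strength predictor from two anchor recipes.

    ``anchor_obs`` are the drug-product observations at the two anchor
    recipes (conventionally the high-MCC and high-CS corners); their
    placebo counterparts are read off the placebo surface.
    """
    anchors = _anchors_from_obs(placebo_surface, anchor_obs)
    model = fit_linear(anchors, prop=placebo_surface.prop)
    return CalibratedPredictor(placebo_surface, model)


def build_dt_predictor(
    placebo_surface: ResponseSurface,
    left_anchor_obs: Sequence[PropertyObservation],
    right_anchor_obs: Sequence[PropertyObservation],
    partitioner: NearestAnchorPartition = DEFAULT_PARTITION,
) -> RegionwisePredictor:
    """Disintegration-time predictor: quadratic left / linear right.

    The left model is fitted on three anchors, the right on two; an anchor
    recipe may legitimately appear in both sets.
    """
    left = fit_quadratic(
        _anchors_from_obs(placebo_surface, left_anchor_obs),
        prop=placebo_surface.prop,
        region="left",
    )
    right = fit_linear(
        _anchors_from_obs(placebo_surface, right_anchor_obs),
        prop=placebo_surface.prop,
        region="right",
    )
    return RegionwisePredictor(placebo_surface, left, right, partitioner)


def scatter_slope(
    placebo_surface: ResponseSurface,
    api_surface: ResponseSurface,
    n: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """OLS slope/intercept of drug-product vs placebo surface values.

    Both surfaces are read at ``n`` uniformly sampled in-domain
    compositions; the regression of drug-product on placebo values is
    returned as ``(slope, intercept)``.
    """
    pts = sample_compositions(n, seed, placebo_surface.constraints)
    xy = np.array([p.xy for p in pts])
    x = placebo_surface.evaluate_xy(xy)
    y = api_surface.evaluate_xy(xy)
    if np.ptp(x) < _DISTINCT_TOL or np.var(x) == 0:
        raise SingularFitError("placebo surface values have zero variance")
    A = np.column_stack([x, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(sol[0]), float(sol[1])
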