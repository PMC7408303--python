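"""Response surfaces over the constrained mixture polygon.

A surface is an exact scattered-data interpolant of per-recipe replicate
means, built on the two free coordinates ``(lac, cs)`` — the third
component is fixed by the mixture constraint.  The default kernel is the
thin-plate spline, which interpolates exactly and reproduces affine fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator

from .errors import DomainError, InfeasibleConstraintsError, RankDeficiencyError
from .formulation import (
    PAPER_CONSTRAINTS,
    ExcipientComposition,
    MixtureConstraints,
    PropertyObservation,
    polygon_vertices,
)

__all__ = [
    "ResponseSurface",
    "fit_surface",
    "sample_compositions",
    "partition",
    "NearestAnchorPartition",
    "DEFAULT_PARTITION",
    "export_grid",
]

_DOMAIN_TOL = 1e-9


class ResponseSurface:
    """Exact interpolating surface ``composition -> property value``.

    Parameters
    ----------
    prop : str
        Property kind, ``"TS"`` or ``"DT"``.
    nodes : (n, 2) array
        Training ``(lac, cs)`` coordinates.
    values : (n,) array
        Training means (replicates already averaged).
    constraints : MixtureConstraints
        Evaluation domain; points outside raise :class:`DomainError`.
    kernel : str
        Any kernel accepted by :class:`scipy.interpolate.RBFInterpolator`.
    """

    def __init__(
        self,
        prop: str,
        nodes: np.ndarray,
        values: np.ndarray,
        constraints: MixtureConstraints = PAPER_CONSTRAINTS,
        kernel: str = "thin_plate_spline",
    ):
        nodes = np.asarray(nodes, dtype=float)
        values = np.asarray(values, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise ValueError("nodes must be an (n, 2) array of (lac, cs)")
        if len(nodes) != len(values):
            raise ValueError("nodes and values must have equal length")
        if len(nodes) < 3:
            raise RankDeficiencyError(
                f"need at least 3 training compositions, got {len(nodes)}"
            )
        centered = nodes - nodes.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise RankDeficiencyError("training compositions are collinear")
        self.prop = prop
        self.nodes = nodes
        self.values = values
        self.constraints = constraints
        self.kernel = kernel
        self._rbf = RBFInterpolator(nodes, values, kernel=kernel, smoothing=0.0)

    # -- evaluation ---------------------------------------------------------

    def _check_domain(self, xy: np.ndarray) -> None:
        lac, cs = xy[:, 0], xy[:, 1]
        mcc = 100.0 - lac - cs
        (l_lo, l_hi) = self.constraints.lac
        (c_lo, c_hi) = self.constraints.cs
        (m_lo, m_hi) = self.constraints.mcc
        ok = (
            (lac >= l_lo - _DOMAIN_TOL)
            & (lac <= l_hi + _DOMAIN_TOL)
            & (cs >= c_lo - _DOMAIN_TOL)
            & (cs <= c_hi + _DOMAIN_TOL)
            & (mcc >= m_lo - _DOMAIN_TOL)
            & (mcc <= m_hi + _DOMAIN_TOL)
        )
        if not np.all(ok):
            bad = xy[~ok][0]
            raise DomainError(
                f"composition (lac={bad[0]}, cs={bad[1]}) is outside the "
                "designed constraint region; extrapolation is not supported"
            )

    def evaluate(self, x: ExcipientComposition) -> float:
        """Surface value at one composition (must be inside the domain)."""
        return float(self.evaluate_xy(np.array([x.xy]))[0])

    def evaluate_xy(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized evaluation at an (n, 2) array of (lac, cs) points."""
        xy = np.asarray(xy, dtype=float)
        self._check_domain(xy)
        return self._rbf(xy)

    def __call__(self, x: ExcipientComposition) -> float:
        return self.evaluate(x)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "prop": self.prop,
            "kernel": self.kernel,
            "nodes": self.nodes.tolist(),
            "values": self.values.tolist(),
            "constraints": self.constraints.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseSurface":
        return cls(
            d["prop"],
            np.array(d["nodes"]),
            np.array(d["values"]),
            MixtureConstraints.from_dict(d["constraints"]),
            d["kernel"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ResponseSurface":
        return cls.from_dict(json.loads(s))


def fit_surface(
    observations: Sequence[PropertyObservation],
    constraints: MixtureConstraints = PAPER_CONSTRAINTS,
    kernel: str = "thin_plate_spline",
) -> ResponseSurface:
    """Fit an interpolating surface to replicate observations.

    Replicate values are pooled per distinct composition (duplicate runs of
    the same composition, e.g. the repeated centroid, collapse into one
    training node) and the pooled mean becomes the training target.
    """
    if not observations:
        raise ValueError("no observations given")
    props = {o.prop for o in observations}
    if len(props) != 1:
        raise ValueError(f"observations mix property kinds: {sorted(props)}")
    pooled: dict[tuple[float, float], list[float]] = {}
    for o in observations:
        if o.composition is None:
            raise ValueError(f"observation for {o.recipe_id} has no composition")
        key = (round(o.composition.lac, 9), round(o.composition.cs, 9))
        pooled.setdefault(key, []).extend(o.replicates)
    nodes = np.array(sorted(pooled), dtype=float)
    values = np.array([float(np.mean(pooled[tuple(k)])) for k in nodes])
    return ResponseSurface(props.pop(), nodes, values, constraints, kernel)


def sample_compositions(
    n: int,
    seed: int,
    constraints: MixtureConstraints = PAPER_CONSTRAINTS,
) -> list[ExcipientComposition]:
    """Uniform random compositions over the constraint polygon.

    Rejection sampling from the polygon's bounding box in ``(lac, cs)``,
    driven by ``numpy.random.default_rng(seed)`` — bit-reproducible for a
    fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    verts = np.array(polygon_vertices(constraints))
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    if np.any(hi - lo <= 0):
        raise InfeasibleConstraintsError("constraint polygon has zero area")
    rng = np.random.default_rng(seed)
    out: list[ExcipientComposition] = []
    while len(out) < n:
        batch = rng.uniform(lo, hi, size=(max(2 * (n - len(out)), 64), 2))
        for x, y in batch:
            if _inside(x, y, constraints):
                out.append(ExcipientComposition.from_xy(x, y))
                if len(out) == n:
                    break
    return out


def _inside(lac: float, cs: float, constraints: MixtureConstraints) -> bool:
    mcc = 100.0 - lac - cs
    return (
        constraints.lac[0] <= lac <= constraints.lac[1]
        and constraints.cs[0] <= cs <= constraints.cs[1]
        and constraints.mcc[0] <= mcc <= constraints.mcc[1]
    )


@dataclass(frozen=True)
class NearestAnchorPartition:
    """Two-cell partition of the domain by nearest anchor in (lac, cs).

    A composition is labeled ``"left"`` when it is at least as close to the
    left anchor as to the right one (ties go left); the boundary is the
    perpendicular bisector of the two anchors.
    """

    left_anchor: tuple[float, float] = (0.0, 60.0)  # high-CS corner (Rp.8)
    right_anchor: tuple[float, float] = (10.0, 0.0)  # high-MCC corner (Rp.5)

    def label(
        self,
        x: ExcipientComposition,
        constraints: MixtureConstraints | None = None,
    ) -> str:
        if constraints is not None and not constraints.contains(x):
            raise DomainError(f"composition {x.as_tuple()} is outside the domain")
        lx, ly = self.left_anchor
        rx, ry = self.right_anchor
        d_left = (x.lac - lx) ** 2 + (x.cs - ly) ** 2
        d_right = (x.lac - rx) ** 2 + (x.cs - ry) ** 2
        return "left" if d_left <= d_right else "right"


DEFAULT_PARTITION = NearestAnchorPartition()


def partition(
    x: ExcipientComposition,
    constraints: MixtureConstraints | None = PAPER_CONSTRAINTS,
) -> str:
    """Label a composition 'left' or 'right' with the default anchors."""
    return DEFAULT_PARTITION.label(x, constraints)


def export_grid(surface: ResponseSurface, step: float = 2.5):
    """Tabulate the surface on a triangular lattice for ternary plotting.

    Returns a :class:`pandas.DataFrame` with columns
    ``lac, cs, mcc, value`` covering in-domain lattice points.
    """
    import pandas as pd

    verts = np.array(polygon_vertices(surface.constraints))
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    pts = []
    for lac in np.arange(lo[0], hi[0] + step / 2, step):
        for cs in np.arange(lo[1], hi[1] + step / 2, step):
            if _inside(lac, cs, surface.constraints):
                pts.append((lac, cs))
    xy = np.array(pts)
    vals = surface.evaluate_xy(xy)
    return pd.DataFrame(
        {
            "lac": xy[:, 0],
            "cs": xy[:, 1],
            "mcc": 100.0 - xy[:, 0] - xy[:, 1],
            "value": vals,
        }
    )
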