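"""Composition arithmetic, extreme-vertices designs, and crush-test mechanics.

Compositions are expressed as percentages of the *excipient base* — the
tablet mass remaining after the drug substance and the lubricant are
removed.  This is the single most common source of user error: a recipe at
10% drug load with 0.60% lubricant has an excipient base of 178.80 mg out
of a 200 mg tablet, and a "90% MCC" composition therefore contains
160.92 mg MCC, not 180 mg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    InfeasibleConstraintsError,
    InfeasibleRecipeError,
    InvalidGeometryError,
)

__all__ = [
    "ExcipientComposition",
    "MixtureConstraints",
    "TabletRecipe",
    "CrushTest",
    "PropertyObservation",
    "PAPER_CONSTRAINTS",
    "API_LUBRICANT_PCT",
    "PLACEBO_LUBRICANT_PCT",
    "DEFAULT_TABLET_MASS_MG",
    "make_recipe",
    "tensile_strength",
    "component_masses",
    "derive_placebo",
    "extreme_vertices_design",
    "polygon_vertices",
    "reference_design",
]

#: Lubricant level (% of tablet mass) for drug-loaded tablets.
API_LUBRICANT_PCT = 0.60

#: Lubricant level for placebo tablets.  Obtained by removing the 20 mg of
#: drug from a 10% drug-load tablet and rescaling the remaining 180 mg to
#: 200 mg: 1.20 mg * 200/180 = 1.333... mg, i.e. 2/3 % of tablet mass
#: (printed as 0.67% after rounding).
PLACEBO_LUBRICANT_PCT = API_LUBRICANT_PCT * 200.0 / 180.0

DEFAULT_TABLET_MASS_MG = 200.0

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ExcipientComposition:
    """A point in the three-excipient mixture simplex.

    Parameters
    ----------
    lac, cs, mcc : float
        Lactose, cornstarch and microcrystalline-cellulose content, each as
        a percentage of the excipient base.  Must be non-negative and sum
        to 100 within ``1e-9``.
    """

    lac: float
    cs: float
    mcc: float

    def __post_init__(self):
        for name in ("lac", "cs", "mcc"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        total = self.lac + self.cs + self.mcc
        if abs(total - 100.0) > _SUM_TOL:
            raise ValueError(
                f"composition percentages must sum to 100, got {total!r}"
            )

    @classmethod
    def from_xy(cls, lac: float, cs: float) -> "ExcipientComposition":
        """Build from the two free coordinates; mcc is the remainder."""
        return cls(lac, cs, 100.0 - lac - cs)

    @property
    def xy(self) -> tuple[float, float]:
        """The free planar coordinates ``(lac, cs)``."""
        return (self.lac, self.cs)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lac, self.cs, self.mcc)


@dataclass(frozen=True)
class MixtureConstraints:
    """Per-component bounds defining a convex polygon in the simplex.

    Each bound is a ``(low, high)`` pair in percent.  The region is
    ``{(lac, cs, mcc) : bounds hold, lac+cs+mcc = 100}``.
    """

    lac: tuple[float, float] = (0.0, 100.0)
    cs: tuple[float, float] = (0.0, 100.0)
    mcc: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self):
        lo_sum, hi_sum = 0.0, 0.0
        for name in ("lac", "cs", "mcc"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InfeasibleConstraintsError(
                    f"{name}: lower bound {lo} exceeds upper bound {hi}"
                )
            lo_sum += lo
            hi_sum += hi
        if lo_sum > 100.0 + _SUM_TOL or hi_sum < 100.0 - _SUM_TOL:
            raise InfeasibleConstraintsError(
                "bounds exclude every point of the simplex "
                f"(sum of lows {lo_sum}, sum of highs {hi_sum})"
            )

    def contains(self, comp: ExcipientComposition, tol: float = 1e-9) -> bool:
        for name in ("lac", "cs", "mcc"):
            lo, hi = getattr(self, name)
            v = getattr(comp, name)
            if v < lo - tol or v > hi + tol:
                return False
        return True

    def to_dict(self) -> dict:
        return {"lac": list(self.lac), "cs": list(self.cs), "mcc": list(self.mcc)}

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureConstraints":
        return cls(tuple(d["lac"]), tuple(d["cs"]), tuple(d["mcc"]))


#: The constraint region of the reference ten-run design:
#: lac, cs in [0, 60]; mcc in [40, 90].
PAPER_CONSTRAINTS = MixtureConstraints(lac=(0.0, 60.0), cs=(0.0, 60.0), mcc=(40.0, 90.0))


@dataclass(frozen=True)
class TabletRecipe:
    """A full tablet recipe: drug load, lubricant level and composition."""

    recipe_id: str
    composition: ExcipientComposition
    api_id: str = "none"
    drug_load: float = 0.0
    lubricant: float = PLACEBO_LUBRICANT_PCT
    tablet_mass: float = DEFAULT_TABLET_MASS_MG

    def __post_init__(self):
        if not 0.0 <= self.drug_load <= 60.0:
            raise ValueError(f"drug_load must be in [0, 60] %, got {self.drug_load}")
        if self.lubricant < 0:
            raise ValueError(f"lubricant must be >= 0 %, got {self.lubricant}")
        if self.tablet_mass <= 0:
            raise ValueError(f"tablet_mass must be > 0 mg, got {self.tablet_mass}")
        if self.api_id == "none" and self.drug_load != 0.0:
            raise ValueError("placebo recipe must have drug_load = 0")

    @property
    def is_placebo(self) -> bool:
        return self.api_id == "none"


def make_recipe(
    recipe_id: str,
    composition: ExcipientComposition,
    api_id: str = "none",
    drug_load: float = 0.0,
    tablet_mass: float = DEFAULT_TABLET_MASS_MG,
) -> TabletRecipe:
    """Create a recipe with the conventional lubricant level.

    Drug-loaded tablets carry 0.60% lubricant; placebo tablets carry the
    rescaled 2/3 % (printed 0.67%).
    """
    lub = PLACEBO_LUBRICANT_PCT if api_id == "none" else API_LUBRICANT_PCT
    return TabletRecipe(recipe_id, composition, api_id, drug_load, lub, tablet_mass)


@dataclass(frozen=True)
class CrushTest:
    """Diametral crush test readings: force (N), diameter and thickness (mm)."""

    F: float
    d: float
    t: float

    def __post_init__(self):
        if self.F < 0:
            raise ValueError(f"crushing force must be >= 0, got {self.F}")
        if self.d <= 0 or self.t <= 0:
            raise InvalidGeometryError(
                f"diameter and thickness must be > 0, got d={self.d}, t={self.t}"
            )


@dataclass(frozen=True)
class PropertyObservation:
    """Replicate measurements of one property for one recipe."""

    recipe_id: str
    prop: str  # "TS" or "DT"
    replicates: tuple[float, ...]
    composition: ExcipientComposition | None = None

    def __post_init__(self):
        if self.prop not in ("TS", "DT"):
            raise ValueError(f"property must be 'TS' or 'DT', got {self.prop!r}")
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate value is required")
        if any(v < 0 for v in self.replicates):
            raise ValueError("replicate values must be >= 0")
        object.__setattr__(self, "replicates", tuple(float(v) for v in self.replicates))

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))


def tensile_strength(ct: CrushTest) -> float:
    """Tensile strength 2F / (pi * d * t) in MPa (N/mm^2)."""
    return 2.0 * ct.F / (math.pi * ct.d * ct.t)


def component_masses(recipe: TabletRecipe) -> dict[str, float]:
    """Masses (mg) of drug, each excipient and lubricant in one tablet.

    The excipient base is the tablet mass net of drug and lubricant; it is
    split between LAC/CS/MCC by the composition percentages.  The returned
    masses sum to the tablet mass exactly (up to rounding noise < 1e-6 mg).
    """
    m = recipe.tablet_mass
    api_mass = recipe.drug_load / 100.0 * m
    lub_mass = recipe.lubricant / 100.0 * m
    base = m - api_mass - lub_mass
    if base <= 0:
        raise InfeasibleRecipeError(
            f"drug load {recipe.drug_load}% + lubricant {recipe.lubricant}% "
            f"leave no excipient base in a {m} mg tablet"
        )
    c = recipe.composition
    return {
        "api": api_mass,
        "lac": c.lac / 100.0 * base,
        "cs": c.cs / 100.0 * base,
        "mcc": c.mcc / 100.0 * base,
        "lubricant": lub_mass,
    }


def derive_placebo(recipe: TabletRecipe) -> TabletRecipe:
    """The placebo counterpart of a recipe: no drug, rescaled lubricant.

    The composition percentages and tablet mass are unchanged; the
    lubricant level becomes the placebo 2/3 %.  Idempotent.
    """
    return replace(
        recipe,
        api_id="none",
        drug_load=0.0,
        lubricant=PLACEBO_LUBRICANT_PCT,
    )


# ---------------------------------------------------------------------------
# Extreme-vertices design generation


def _constraint_lines(constraints: MixtureConstraints):
    """Active-bound lines a*x + b*y = c in the (lac, cs) plane."""
    (l_lo, l_hi), (c_lo, c_hi) = constraints.lac, constraints.cs
    m_lo, m_hi = constraints.mcc
    # mcc = 100 - lac - cs, so mcc bounds become lac + cs bounds.
    return [
        (1.0, 0.0, l_lo),
        (1.0, 0.0, l_hi),
        (0.0, 1.0, c_lo),
        (0.0, 1.0, c_hi),
        (1.0, 1.0, 100.0 - m_hi),
        (1.0, 1.0, 100.0 - m_lo),
    ]


def _feasible(x: float, y: float, constraints: MixtureConstraints, tol: float = 1e-7) -> bool:
    (l_lo, l_hi), (c_lo, c_hi) = constraints.lac, constraints.cs
    m_lo, m_hi = constraints.mcc
    m = 100.0 - x - y
    return (
        l_lo - tol <= x <= l_hi + tol
        and c_lo - tol <= y <= c_hi + tol
        and m_lo - tol <= m <= m_hi + tol
    )


def polygon_vertices(constraints: MixtureConstraints) -> list[tuple[float, float]]:
    """Vertices of the constraint polygon in (lac, cs), counter-clockwise.

    Found by intersecting every pair of active-bound lines and keeping the
    feasible, distinct intersection points.  The list starts at the
    lexicographically smallest vertex so output order is deterministic.
    """
    pts: list[tuple[float, float]] = []
    for (a1, b1, c1), (a2, b2, c2) in combinations(_constraint_lines(constraints), 2):
        det = a1 * b2 - a2 * b1
        if abs(det) < 1e-12:
            continue
        x = (c1 * b2 - c2 * b1) / det
        y = (a1 * c2 - a2 * c1) / det
        if _feasible(x, y, constraints):
            if not any(abs(x - px) < 1e-7 and abs(y - py) < 1e-7 for px, py in pts):
                pts.append((round(x, 9) + 0.0, round(y, 9) + 0.0))  # +0.0 kills -0.0
    if len(pts) < 3:
        raise InfeasibleConstraintsError(
            "constraint region is empty or degenerate "
            f"({len(pts)} feasible vertex/vertices)"
        )
    cx = sum(p[0] for p in pts) / len(pts)
    cy = sum(p[1] for p in pts) / len(pts)
    pts.sort(key=lambda p: math.atan2(p[1] - cy, p[0] - cx))
    start = min(range(len(pts)), key=lambda i: pts[i])
    return pts[start:] + pts[:start]


def extreme_vertices_design(
    constraints: MixtureConstraints = PAPER_CONSTRAINTS,
    duplicate_centroid: bool = False,
) -> list[ExcipientComposition]:
    """Extreme-vertices mixture design for a constrained ternary region.

    Returns the polygon vertices, the midpoint of every polygon edge, and
    the overall centroid (mean of the vertices), in that order.  With
    ``duplicate_centroid`` the centroid appears twice, giving the ten-run
    layout used for the reference design.
    """
    verts = polygon_vertices(constraints)
    n = len(verts)
    points: list[ExcipientComposition] = [
        ExcipientComposition.from_xy(x, y) for x, y in verts
    ]
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        points.append(ExcipientComposition.from_xy((x1 + x2) / 2.0, (y1 + y2) / 2.0))
    cx = sum(v[0] for v in verts) / n
    cy = sum(v[1] for v in verts) / n
    centroid = ExcipientComposition.from_xy(cx, cy)
    points.append(centroid)
    if duplicate_centroid:
        points.append(centroid)
    return points


#: Recipe labels of the reference ten-run design, keyed by (lac, cs, mcc).
_REFERENCE_LABELS = {
    (0.0, 10.0, 90.0): "Rp.1",
    (17.5, 17.5, 65.0): "Rp.2",
    (0.0, 35.0, 65.0): "Rp.3",
    (60.0, 0.0, 40.0): "Rp.4",
    (10.0, 0.0, 90.0): "Rp.5",
    (35.0, 0.0, 65.0): "Rp.6",
    (30.0, 30.0, 40.0): "Rp.7",
    (0.0, 60.0, 40.0): "Rp.8",
    (5.0, 5.0, 90.0): "Rp.9",
}


def reference_design(duplicate_centroid: bool = True) -> list[tuple[str, ExcipientComposition]]:
    """The labeled ten-run reference design (Rp.1 ... Rp.9, Rp.2 twice).

    Generated from :data:`PAPER_CONSTRAINTS` by :func:`extreme_vertices_design`
    and relabeled to the published run order.
    """
    pts = extreme_vertices_design(PAPER_CONSTRAINTS, duplicate_centroid=False)
    by_label: dict[str, ExcipientComposition] = {}
    for p in pts:
        key = tuple(round(v, 6) for v in p.as_tuple())
        label = _REFERENCE_LABELS.get(key)
        if label is None:  # pragma: no cover - guards against generator drift
            raise RuntimeError(f"generated point {key} has no reference label")
        by_label[label] = p
    order = ["Rp.1", "Rp.2", "Rp.3", "Rp.4", "Rp.5", "Rp.6", "Rp.7", "Rp.8", "Rp.9"]
    out: list[tuple[str, ExcipientComposition]] = []
    for label in order:
        out.append((label, by_label[label]))
        if label == "Rp.2" and duplicate_centroid:
            out.append((label, by_label[label]))
    return out
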