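"""Synthetic placebo / drug-product datasets with known ground truth.

The generator mirrors the qualitative structure of the measured data:
the default strength field rises with the binder (MCC) content, and the
default disintegration field has two ridges — one at the high-MCC corner
and one at the high-disintegrant corner.  The placebo-to-product transfer
is a known affine map (optionally region-wise quadratic/linear), so the
full design -> surfaces -> calibration -> evaluation pipeline can be
checked for exact parameter recovery at zero noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .formulation import ExcipientComposition, PropertyObservation
from .surface import DEFAULT_PARTITION, NearestAnchorPartition

__all__ = [
    "AffineField",
    "BumpField",
    "LinearTransfer",
    "QuadraticTransfer",
    "RegionwiseTransfer",
    "SyntheticScenario",
    "generate_placebo_observations",
    "generate_api_observations",
    "default_ts_scenario",
    "default_dt_scenario",
]


@dataclass(frozen=True)
class AffineField:
    """``c0 + c_lac*lac + c_cs*cs`` — affine in the free coordinates."""

    c0: float
    c_lac: float = 0.0
    c_cs: float = 0.0

    def __call__(self, x: ExcipientComposition) -> float:
        return self.c0 + self.c_lac * x.lac + self.c_cs * x.cs


@dataclass(frozen=True)
class BumpField:
    """Baseline plus Gaussian bumps at chosen (lac, cs) centers."""

    base: float
    bumps: tuple[tuple[float, float, float, float], ...]
    # each bump: (center_lac, center_cs, amplitude, width)

    def __call__(self, x: ExcipientComposition) -> float:
        v = self.base
        for cx, cy, amp, width in self.bumps:
            d2 = (x.lac - cx) ** 2 + (x.cs - cy) ** 2
            v += amp * math.exp(-d2 / (2.0 * width**2))
        return v


@dataclass(frozen=True)
class LinearTransfer:
    a: float
    b: float

    def __call__(self, v: float, x: ExcipientComposition | None = None) -> float:
        return self.a * v + self.b


@dataclass(frozen=True)
class QuadraticTransfer:
    a: float
    b: float
    c: float

    def __call__(self, v: float, x: ExcipientComposition | None = None) -> float:
        return self.a * v * v + self.b * v + self.c


@dataclass(frozen=True)
class RegionwiseTransfer:
    """Quadratic transfer on the left cell, linear on the right."""

    left: QuadraticTransfer
    right: LinearTransfer
    partitioner: NearestAnchorPartition = DEFAULT_PARTITION

    def __call__(self, v: float, x: ExcipientComposition) -> float:
        if self.partitioner.label(x) == "left":
            return self.left(v)
        return self.right(v)


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth scenario for pipeline testing.

    ``transfer`` may be a transfer object or a callable
    ``drug_load -> transfer`` (e.g. a slope that declines with load);
    ``noise_sd`` is the s.d. of additive Gaussian measurement noise, with a
    log-normal option for strictly positive responses.
    """

    field: Callable[[ExcipientComposition], float]
    transfer: object
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0
    prop: str = "TS"
    noise_model: str = "gaussian"  # "gaussian" | "lognormal"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def transfer_for_load(self, drug_load: float):
        if callable(self.transfer) and not isinstance(
            self.transfer, (LinearTransfer, QuadraticTransfer, RegionwiseTransfer)
        ):
            return self.transfer(drug_load)
        return self.transfer


def _noisy(rng: np.random.Generator, value: float, scenario: SyntheticScenario) -> tuple[float, ...]:
    k = scenario.replicates
    if scenario.noise_sd == 0.0:
        return tuple([value] * k)
    if scenario.noise_model == "gaussian":
        return tuple(float(v) for v in value + scenario.noise_sd * rng.standard_normal(k))
    # log-normal: multiplicative noise with approximate s.d. noise_sd at `value`
    sigma = scenario.noise_sd / max(value, 1e-12)
    return tuple(
        float(value * math.exp(sigma * z - 0.5 * sigma**2))
        for z in rng.standard_normal(k)
    )


def generate_placebo_observations(
    scenario: SyntheticScenario,
    design: Sequence[tuple[str, ExcipientComposition]],
) -> list[PropertyObservation]:
    """Replicate placebo observations: field value plus seeded noise."""
    rng = np.random.default_rng((scenario.seed, 0))
    out = []
    for recipe_id, comp in design:
        v = scenario.field(comp)
        out.append(
            PropertyObservation(recipe_id, scenario.prop, _noisy(rng, v, scenario), comp)
        )
    return out


def generate_api_observations(
    scenario: SyntheticScenario,
    design: Sequence[tuple[str, ExcipientComposition]],
    drug_load: float = 20.0,
) -> list[PropertyObservation]:
    """Replicate drug-product observations: transferred field plus noise."""
    transfer = scenario.transfer_for_load(drug_load)
    rng = np.random.default_rng((scenario.seed, 1, int(round(drug_load * 100))))
    out = []
    for recipe_id, comp in design:
        v = transfer(scenario.field(comp), comp)
        out.append(
            PropertyObservation(recipe_id, scenario.prop, _noisy(rng, v, scenario), comp)
        )
    return out


def default_ts_scenario(
    a: float = 0.8, b: float = -0.1, noise_sd: float = 0.0, seed: int = 0
) -> SyntheticScenario:
    """Strength scenario: field rising with binder content, affine transfer.

    The field ``3.1 - 0.02*lac - 0.02*cs`` equals ``1.1 + 0.02*mcc``, i.e.
    strength increases with MCC from 1.9 at 40% to 2.9 at 90%.
    """
    return SyntheticScenario(
        field=AffineField(3.1, -0.02, -0.02),
        transfer=LinearTransfer(a, b),
        noise_sd=noise_sd,
        seed=seed,
        prop="TS",
    )


def default_dt_scenario(
    transfer: object | None = None, noise_sd: float = 0.0, seed: int = 0
) -> SyntheticScenario:
    """Disintegration scenario: ridges at the two slow-disintegrating corners."""
    fld = BumpField(
        base=30.0,
        bumps=((10.0, 0.0, 60.0, 18.0), (0.0, 60.0, 90.0, 22.0)),
    )
    if transfer is None:
        transfer = LinearTransfer(0.9, 5.0)
    return SyntheticScenario(
        field=fld, transfer=transfer, noise_sd=noise_sd, seed=seed, prop="DT"
    )
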