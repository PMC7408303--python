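"""CSV/JSON interchange, run configuration, and the end-to-end pipeline.

CSV dialect: comma-separated, UTF-8, header row, ``.`` decimal.
Percentages are stored as numbers on the 0–100 scale, and compositions are
percentages of the *excipient base* (drug- and lubricant-exclusive).

Design CSV columns:
    recipe_id, api_id, drug_load_pct, lubricant_pct, lac_pct, cs_pct, mcc_pct
Observation CSV columns:
    recipe_id, property, replicate, value
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from .errors import ValidationError
from .evaluation import PredictionReport, evaluate_prediction
from .formulation import (
    PAPER_CONSTRAINTS,
    ExcipientComposition,
    MixtureConstraints,
    PropertyObservation,
    TabletRecipe,
)
from .surface import ResponseSurface, fit_surface

__all__ = [
    "read_design",
    "write_design",
    "read_observations",
    "write_observations",
    "write_report",
    "predictor_to_dict",
    "predictor_from_dict",
    "ApiCase",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_DESIGN_COLS = [
    "recipe_id",
    "api_id",
    "drug_load_pct",
    "lubricant_pct",
    "lac_pct",
    "cs_pct",
    "mcc_pct",
]
_OBS_COLS = ["recipe_id", "property", "replicate", "value"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _to_float(df: pd.DataFrame, col: str, path) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    if s.isna().any():
        row = int(s.index[s.isna()][0])
        raise ValidationError(f"{path}: non-numeric value", row=row, column=col)
    return s.astype(float)


def read_design(path) -> list[TabletRecipe]:
    """Read a design/recipe table; validates composition sums row by row."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, _DESIGN_COLS, path)
    for col in _DESIGN_COLS[2:]:
        df[col] = _to_float(df, col, path)
    recipes = []
    for idx, row in df.iterrows():
        total = row.lac_pct + row.cs_pct + row.mcc_pct
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(
                f"{path}: lac+cs+mcc = {total}, expected 100",
                row=int(idx),
                column="lac_pct",
            )
        try:
            comp = ExcipientComposition(row.lac_pct, row.cs_pct, 100.0 - row.lac_pct - row.cs_pct)
            recipes.append(
                TabletRecipe(
                    recipe_id=str(row.recipe_id),
                    composition=comp,
                    api_id=str(row.api_id),
                    drug_load=row.drug_load_pct,
                    lubricant=row.lubricant_pct,
                )
            )
        except ValueError as e:
            raise ValidationError(f"{path}: {e}", row=int(idx)) from e
    return recipes


def write_design(recipes: Sequence[TabletRecipe], path, config_hash: str | None = None) -> None:
    rows = [
        {
            "recipe_id": r.recipe_id,
            "api_id": r.api_id,
            "drug_load_pct": r.drug_load,
            "lubricant_pct": r.lubricant,
            "lac_pct": r.composition.lac,
            "cs_pct": r.composition.cs,
            "mcc_pct": r.composition.mcc,
        }
        for r in recipes
    ]
    _write_csv(pd.DataFrame(rows, columns=_DESIGN_COLS), path, config_hash)


def read_observations(
    path,
    compositions: dict[str, ExcipientComposition] | None = None,
) -> list[PropertyObservation]:
    """Read replicate observations, optionally attaching compositions.

    When ``compositions`` is given, every recipe id must resolve; unknown
    ids raise a :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, _OBS_COLS, path)
    df["value"] = _to_float(df, "value", path)
    df["replicate"] = _to_float(df, "replicate", path)
    out = []
    for (rid, prop), grp in df.groupby(["recipe_id", "property"], sort=False):
        rid = str(rid)
        comp = None
        if compositions is not None:
            if rid not in compositions:
                row = int(grp.index[0])
                raise ValidationError(
                    f"{path}: unknown recipe id {rid!r}", row=row, column="recipe_id"
                )
            comp = compositions[rid]
        reps = tuple(grp.sort_values("replicate")["value"].tolist())
        try:
            out.append(PropertyObservation(rid, str(prop), reps, comp))
        except ValueError as e:
            raise ValidationError(f"{path}: {e}", row=int(grp.index[0])) from e
    return out


def write_observations(
    observations: Sequence[PropertyObservation], path, config_hash: str | None = None
) -> None:
    rows = [
        {"recipe_id": o.recipe_id, "property": o.prop, "replicate": i + 1, "value": v}
        for o in observations
        for i, v in enumerate(o.replicates)
    ]
    _write_csv(pd.DataFrame(rows, columns=_OBS_COLS), path, config_hash)


def _write_csv(df: pd.DataFrame, path, config_hash: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def write_report(report: PredictionReport, path, config_hash: str | None = None, **extra) -> None:
    """Serialize a prediction report as JSON (residuals included)."""
    d = report.to_dict()
    d.update(extra)
    if config_hash:
        d["config_hash"] = config_hash
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(d, indent=2, sort_keys=True), encoding="utf-8")


# -- predictor serialization -------------------------------------------------


def predictor_to_dict(predictor) -> dict:
    if isinstance(predictor, cal.CalibratedPredictor):
        return {
            "type": "whole",
            "placebo_surface": predictor.placebo_surface.to_dict(),
            "model": predictor.model.to_dict(),
        }
    if isinstance(predictor, cal.RegionwisePredictor):
        return {
            "type": "regionwise",
            "placebo_surface": predictor.placebo_surface.to_dict(),
            "left_model": predictor.left_model.to_dict(),
            "right_model": predictor.right_model.to_dict(),
        }
    raise TypeError(f"cannot serialize predictor of type {type(predictor)!r}")


def predictor_from_dict(d: dict):
    surf = ResponseSurface.from_dict(d["placebo_surface"])
    if d["type"] == "whole":
        return cal.CalibratedPredictor(surf, cal.CalibrationModel.from_dict(d["model"]))
    if d["type"] == "regionwise":
        return cal.RegionwisePredictor(
            surf,
            cal.CalibrationModel.from_dict(d["left_model"]),
            cal.CalibrationModel.from_dict(d["right_model"]),
        )
    raise ValueError(f"unknown predictor type {d['type']!r}")


# -- run configuration and pipeline ------------------------------------------


@dataclass(frozen=True)
class ApiCase:
    """One drug product x drug load case with its observation table."""

    api_id: str
    drug_load: float
    obs_csv: str


@dataclass(frozen=True)
class RunConfig:
    design_csv: str
    placebo_obs_csv: str
    api_cases: tuple[ApiCase, ...]
    constraints: MixtureConstraints = PAPER_CONSTRAINTS
    ts_anchors: tuple[str, ...] = ("Rp.5", "Rp.8")
    dt_left_anchors: tuple[str, ...] = ("Rp.3", "Rp.4", "Rp.8")
    dt_right_anchors: tuple[str, ...] = ("Rp.4", "Rp.5")
    n_samples: int = 500
    seed: int = 0
    output_dir: str = "tabcal_out"

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")

    def to_dict(self) -> dict:
        return {
            "design_csv": self.design_csv,
            "placebo_obs_csv": self.placebo_obs_csv,
            "api_cases": [
                {"api_id": c.api_id, "drug_load": c.drug_load, "obs_csv": c.obs_csv}
                for c in self.api_cases
            ],
            "constraints": self.constraints.to_dict(),
            "ts_anchors": list(self.ts_anchors),
            "dt_left_anchors": list(self.dt_left_anchors),
            "dt_right_anchors": list(self.dt_right_anchors),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            design_csv=d["design_csv"],
            placebo_obs_csv=d["placebo_obs_csv"],
            api_cases=tuple(
                ApiCase(c["api_id"], float(c["drug_load"]), c["obs_csv"])
                for c in d["api_cases"]
            ),
            constraints=(
                MixtureConstraints.from_dict(d["constraints"])
                if "constraints" in d
                else PAPER_CONSTRAINTS
            ),
            ts_anchors=tuple(d.get("ts_anchors", ("Rp.5", "Rp.8"))),
            dt_left_anchors=tuple(d.get("dt_left_anchors", ("Rp.3", "Rp.4", "Rp.8"))),
            dt_right_anchors=tuple(d.get("dt_right_anchors", ("Rp.4", "Rp.5"))),
            n_samples=int(d.get("n_samples", 500)),
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir", "tabcal_out"),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def _case_seed(seed: int, index: int) -> int:
    # independent, reproducible per-case sampling stream
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0])


def _select_anchors(observations, anchor_ids, prop, label):
    by_id = {o.recipe_id: o for o in observations if o.prop == prop}
    missing = [a for a in anchor_ids if a not in by_id]
    if missing:
        raise ValidationError(
            f"{label}: anchor observations missing for recipe ids {missing}; "
            f"available ids: {sorted(by_id)}"
        )
    return [by_id[a] for a in anchor_ids]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full placebo-calibrated prediction pipeline.

    For every drug-product case and every property present in both the
    placebo and case observation tables: fit both surfaces, calibrate the
    transfer from the configured anchors, score it on ``n_samples`` fresh
    seeded compositions, and write all artifacts (JSON, config-hashed) to
    the output directory.
    """
    cfg_hash = config.hash()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    recipes = read_design(config.design_csv)
    comps = {r.recipe_id: r.composition for r in recipes}
    placebo_obs = read_observations(config.placebo_obs_csv, comps)
    logger.info("pipeline config hash %s, %d cases", cfg_hash, len(config.api_cases))

    placebo_surfaces: dict[str, ResponseSurface] = {}
    for prop in sorted({o.prop for o in placebo_obs}):
        placebo_surfaces[prop] = fit_surface(
            [o for o in placebo_obs if o.prop == prop], config.constraints
        )
        (outdir / f"placebo_surface_{prop}.json").write_text(
            json.dumps({**placebo_surfaces[prop].to_dict(), "config_hash": cfg_hash}),
            encoding="utf-8",
        )

    results: dict[str, dict] = {}
    for i, case in enumerate(config.api_cases):
        case_key = f"{case.api_id}_{case.drug_load:g}"
        case_obs = read_observations(case.obs_csv, comps)
        case_seed = _case_seed(config.seed, i)
        case_result: dict[str, dict] = {}
        for prop in sorted({o.prop for o in case_obs}):
            if prop not in placebo_surfaces:
                logger.warning("no placebo %s surface; skipping %s", prop, case_key)
                continue
            psurf = placebo_surfaces[prop]
            obs_p = [o for o in case_obs if o.prop == prop]
            api_surf = fit_surface(obs_p, config.constraints)
            if prop == "TS":
                anchors = _select_anchors(obs_p, config.ts_anchors, prop, case_key)
                predictor = cal.build_ts_predictor(psurf, anchors)
            else:
                left = _select_anchors(obs_p, config.dt_left_anchors, prop, case_key)
                right = _select_anchors(obs_p, config.dt_right_anchors, prop, case_key)
                predictor = cal.build_dt_predictor(psurf, left, right)
            report = evaluate_prediction(
                predictor, api_surf, n=config.n_samples, seed=case_seed
            )
            slope, intercept = cal.scatter_slope(
                psurf, api_surf, n=config.n_samples, seed=case_seed
            )
            stem = f"{case_key}_{prop}"
            (outdir / f"surface_{stem}.json").write_text(
                json.dumps({**api_surf.to_dict(), "config_hash": cfg_hash}),
                encoding="utf-8",
            )
            (outdir / f"predictor_{stem}.json").write_text(
                json.dumps({**predictor_to_dict(predictor), "config_hash": cfg_hash}),
                encoding="utf-8",
            )
            write_report(
                report,
                outdir / f"report_{stem}.json",
                config_hash=cfg_hash,
                api_id=case.api_id,
                drug_load=case.drug_load,
                property=prop,
                scatter_slope=slope,
                scatter_intercept=intercept,
            )
            case_result[prop] = {
                "report": report,
                "predictor": predictor,
                "api_surface": api_surf,
                "scatter_slope": slope,
                "scatter_intercept": intercept,
                "seed": case_seed,
            }
        results[case_key] = case_result
    summary = {
        "config_hash": cfg_hash,
        "cases": {
            k: {
                p: {
                    "r_squared": v[p]["report"].r_squared,
                    "mae": v[p]["report"].mae,
                    "scatter_slope": v[p]["scatter_slope"],
                    "seed": v[p]["seed"],
                }
                for p in v
            }
            for k, v in results.items()
        },
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    return results
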