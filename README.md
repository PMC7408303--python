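# tabcal

Placebo-calibrated prediction of tablet properties — tensile strength (TS,
MPa) and disintegration time (DT, s) — over a constrained three-excipient
mixture region (lactose / cornstarch / microcrystalline cellulose).

The workflow:

1. **Design** — generate an extreme-vertices mixture design (polygon
   vertices, edge midpoints, overall centroid; the default constraints
   `lac, cs ∈ [0, 60]`, `mcc ∈ [40, 90]` give the ten-run reference design
   with a duplicated centroid).
2. **Surfaces** — fit exact thin-plate-spline response surfaces to
   replicate means of TS or DT over the design (`scipy` RBF, no smoothing;
   no extrapolation outside the constraint polygon).
3. **Calibration transfer** — map the placebo surface to a drug-loaded
   product with a small-anchor regression: a two-anchor linear transfer for
   TS, and a region-wise transfer for DT (quadratic on the "left" half of
   the domain near the high-disintegrant corner, fitted on three anchors;
   linear on the "right" half near the high-MCC corner, fitted on two).
4. **Evaluation** — score the transferred prediction against the product's
   own surface on 500 uniformly sampled in-domain compositions using the
   determination coefficient (centered on the calibrated predictions) and
   the mean absolute error.
5. **Synthetic data** — generate placebo/product datasets with a known
   transfer and noise level, so the whole pipeline is testable end to end
   (zero-noise runs recover the generating coefficients exactly).

> **Units gotcha:** compositions are percentages of the *excipient base*
> (tablet mass net of drug substance and lubricant), not of the whole
> tablet. A 200 mg tablet at 10% drug load with 0.60% lubricant has a
> 178.80 mg base, so "90% MCC" means 160.92 mg MCC.

## CLI

```bash
tabcal design --output design.csv                 # ten-run reference design
tabcal simulate --property TS --noise-sd 0.02 --seed 7 --output-dir sim
tabcal fit-surface --design sim/design.csv --observations sim/placebo_TS.csv \
    --property TS --output psurf.json
tabcal calibrate-ts --placebo-surface psurf.json --design sim/design.csv \
    --observations sim/api_TS.csv --output pred.json
tabcal fit-surface --design sim/design.csv --observations sim/api_TS.csv \
    --property TS --output asurf.json
tabcal evaluate --predictor pred.json --api-surface asurf.json \
    --seed 5 --output report.json
tabcal run --config config.json                   # full multi-case pipeline
```

`tabcal run` consumes a JSON config (paths to a design CSV, a placebo
observation CSV, and one observation CSV per product × drug-load case,
plus anchors, `n_samples`, `seed`, `output_dir`); all artifacts are JSON
and embed the config hash, and reruns with an identical config are
byte-identical. `calibrate-dt` fits the region-wise DT transfer with
`--left-anchors Rp.3,Rp.4,Rp.8 --right-anchors Rp.4,Rp.5` defaults.

CSV dialects (comma, UTF-8, header, `.` decimal):

- design: `recipe_id, api_id, drug_load_pct, lubricant_pct, lac_pct, cs_pct, mcc_pct`
- observations: `recipe_id, property, replicate, value`

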