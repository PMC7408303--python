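"""Loader for the measured TS/DT tables of the original study.

The published supplementary tables (per-recipe replicate measurements of
tensile strength and disintegration time for the placebo and for each of
the four drug substances at 20-60% drug load) were not available as text
in this build, so no transcription ships with the repository.  The
measured-data acceptance checks therefore fail at load time with the
message below rather than being skipped or faked.

If the tables become available, place them at:

    tests/data/appendix_a_ts.csv
    tests/data/appendix_a_dt.csv

with columns: api_id, drug_load, recipe_id, replicate, value
(``api_id = none`` and ``drug_load = 0`` for the placebo rows; value in
MPa for TS, seconds for DT; recipe ids Rp.1 ... Rp.9) and the checks will
run against them unchanged.
"""

from pathlib import Path

import pandas as pd

DATA_DIR = Path(__file__).parent / "data"

MISSING_MSG = (
    "measured TS/DT tables are not available: the supplementary appendix "
    "with per-recipe measurements was not extractable as text, so the "
    "measured-data acceptance criterion cannot be evaluated. See "
    "tests/appendix_data.py for the expected CSV layout."
)


def load_measurements(prop: str) -> pd.DataFrame:
    """Load the measured table for ``prop`` ("TS" or "DT").

    Returns a tidy frame with columns api_id, drug_load, recipe_id,
    replicate, value.  Raises ``FileNotFoundError`` with an explanatory
    message when the transcription is absent.
    """
    path = DATA_DIR / f"appendix_a_{prop.lower()}.csv"
    if not path.exists():
        raise FileNotFoundError(f"{path}: {MISSING_MSG}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"api_id", "drug_load", "recipe_id", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
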