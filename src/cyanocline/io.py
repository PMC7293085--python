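"""CSV readers/writers, configuration, and run manifests.

CSV is the interchange format throughout: the plant-record table, the
GHCN-Daily-like weather table, the per-population environment table, and
the primer-pattern table.  ``NA`` is the only missing-value token; dates
are ISO-8601.  Row-level validation failures are collected with row
numbers, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "PLANT_COLUMNS",
    "WEATHER_COLUMNS",
    "SchemaError",
    "read_plant_table",
    "write_plant_table",
    "read_weather_table",
    "read_environment_table",
    "read_pattern_panel",
    "file_digest",
    "RunManifest",
]

PLANT_COLUMNS = [
    "city",
    "population_id",
    "latitude",
    "longitude",
    "distance_km",
    "feigl_anger",
    "plus_linamarin",
    "plus_linamarase",
]
WEATHER_COLUMNS = [
    "station_id",
    "date",
    "tmin_c",
    "tmax_c",
    "snowfall_cm",
    "snowdepth_cm",
]
_TRISTATE = {"pos", "neg", "NA"}


class SchemaError(ValueError):
    """Raised for malformed input tables, naming the offending rows."""


def read_plant_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plant-record CSV.

    Assay columns must contain only ``pos``/``neg``/``NA``; unknown columns
    beyond the schema are tolerated (truth columns from the simulator,
    appended cyanotype) but the schema columns must all be present.
    """
    df = pd.read_csv(path, dtype={"city": str, "population_id": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in PLANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    errors = []
    for col in ("feigl_anger", "plus_linamarin", "plus_linamarase"):
        vals = df[col].fillna("NA").astype(str)
        bad = ~vals.isin(_TRISTATE)
        for i in df.index[bad][:20]:
            errors.append(f"row {i + 2}: {col} = {df.loc[i, col]!r}")
        df[col] = vals
    for col in ("latitude", "longitude", "distance_km"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str) != "NA")
        for i in df.index[bad][:20]:
            errors.append(f"row {i + 2}: unparseable {col} = {df.loc[i, col]!r}")
        df[col] = coerced
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return df


def write_plant_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a plant-record CSV (cyanotype column, if present, is kept)."""
    cols = [c for c in PLANT_COLUMNS if c in df.columns]
    extra = [c for c in ("cyanotype",) if c in df.columns]
    df[cols + extra].to_csv(path, index=False, na_rep="NA")


def read_weather_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    try:
        pd.to_datetime(df["date"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable date: {exc}") from exc
    neg_depth = df["snowdepth_cm"].dropna() < 0
    if neg_depth.any():
        raise SchemaError(f"{path}: negative snow depth")
    return df


def read_environment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"city": str, "population_id": str})
    for col in ("city", "population_id", "mwt_c", "mst_c", "ai", "apet_mm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    return df


def read_pattern_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plant_id": str, "city": str})
    for col in ("plant_id", "city", "habitat", "locus", "pp1", "pp2", "pp3"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    return df


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class RunManifest:
    """Reproducibility manifest: config hash, seed, and file digests.

    Re-running with identical config and seed reproduces byte-identical
    outputs, so the recorded digests certify a run.
    """

    def __init__(self, config: dict, seed: int):
        self.config = config
        self.seed = int(seed)
        self.stages: dict[str, dict] = {}

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def record(self, stage: str, outputs: dict[str, str | Path] | None = None,
               audit: dict | None = None) -> None:
        entry: dict = {"audit": audit or {}}
        entry["outputs"] = {
            name: file_digest(p) for name, p in (outputs or {}).items()
        }
        self.stages[stage] = entry

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))
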