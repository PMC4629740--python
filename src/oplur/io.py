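"""CSV/JSON readers and writers with schema validation.

All tables are UTF-8 comma-separated files with a header row and '.'
decimals; period ids are opaque strings; coordinates are planar meters.
Readers validate schemas eagerly and name the offending rows or columns
in their error messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .lur_model import PredictorMeta, PredictorTable
from .metrics import METRICS, SITE_TYPES

SITE_COLUMNS = ("site_id", "site_type", "x", "y")
MEASUREMENT_COLUMNS = ("site_id", "period_id", "metric", "value")
REFERENCE_COLUMNS = ("period_id", "metric", "value")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "site_type": str})
    _require_columns(df, SITE_COLUMNS, path)
    if df.empty:
        raise ValueError(f"{path}: site roster is empty")
    dup = df["site_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate site ids {df['site_id'][dup].tolist()}")
    bad = ~df["site_type"].isin(SITE_TYPES)
    if bad.any():
        rows = df.loc[bad, ["site_id", "site_type"]].to_dict("records")
        raise ValueError(f"{path}: unknown site types in rows {rows}")
    df[["x", "y"]] = df[["x", "y"]].astype(float)
    return df[list(SITE_COLUMNS)]


def read_measurements(path, sites: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "period_id": str, "metric": str})
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    if df.empty:
        raise ValueError(f"{path}: measurements table is empty")
    bad = ~df["metric"].isin(METRICS)
    if bad.any():
        raise ValueError(
            f"{path}: unknown metrics {sorted(df['metric'][bad].unique())}"
        )
    dup = df.duplicated(subset=["site_id", "period_id", "metric"])
    if dup.any():
        rows = df.loc[dup, ["site_id", "period_id", "metric"]].to_dict("records")
        raise ValueError(f"{path}: duplicate (site, period, metric) records {rows}")
    if sites is not None:
        unknown = set(df["site_id"]) - set(sites["site_id"])
        if unknown:
            raise ValueError(f"{path}: measurements at unknown sites {sorted(unknown)}")
    if "below_lod" not in df.columns:
        df["below_lod"] = False
    df["value"] = df["value"].astype(float)
    return df


def read_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"period_id": str, "metric": str})
    _require_columns(df, REFERENCE_COLUMNS, path)
    if df.empty:
        raise ValueError(f"{path}: reference series is empty")
    df["value"] = df["value"].astype(float)
    return df


def read_predictors(path, meta_path=None, sites: pd.DataFrame | None = None) -> PredictorTable:
    df = pd.read_csv(path, dtype={"site_id": str})
    if "site_id" not in df.columns:
        raise ValueError(f"{path}: missing required column site_id")
    if df["site_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate site ids")
    df = df.set_index("site_id")
    if df.empty or not len(df.columns):
        raise ValueError(f"{path}: predictor table has no predictors")
    if sites is not None:
        unknown = set(df.index) - set(sites["site_id"])
        if unknown:
            raise ValueError(f"{path}: predictors for unknown sites {sorted(unknown)}")
    df = df.astype(float)
    if meta_path is not None:
        with open(meta_path) as fh:
            raw = json.load(fh)
        meta = {m["name"]: PredictorMeta(**m) for m in raw}
    else:
        # default: everything positive-direction unless named seminatural/forest
        meta = {
            c: PredictorMeta(
                name=c,
                direction="-" if ("seminatural" in c or "forest" in c) else "+",
            )
            for c in df.columns
        }
    missing = [c for c in df.columns if c not in meta]
    if missing:
        raise ValueError(f"{meta_path}: metadata missing for predictors {missing}")
    return PredictorTable(df, {c: meta[c] for c in df.columns})


def write_annual_averages(annual: pd.DataFrame, path) -> None:
    annual.to_csv(path, index=False)


def read_annual_averages(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "metric": str})
    _require_columns(df, ("site_id", "metric", "value"), path)
    df["value"] = df["value"].astype(float)
    return df


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
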