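"""Plain-CSV readers and writers for every table the pipeline exchanges.

Interchange dialect: comma-separated text with documented column names;
missing values are written as empty fields and round-trip as NaN.  Malformed
rows raise errors that name the offending line number (header = line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import ClimateEnsemble, FarEstimate, ModelRealizations

__all__ = [
    "write_ensemble", "read_ensemble",
    "write_far_table", "read_far_table",
    "write_far_estimate", "read_far_estimate",
    "write_panel", "read_panel",
    "write_seine", "read_seine",
    "write_recruitment", "read_recruitment",
]

SCENARIOS = ("observed", "preindustrial", "projection")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _numeric(df: pd.DataFrame, col: str, path, required: bool = True) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}:{line}: non-numeric value in column {col!r}")
    if required and out.isna().any():
        line = int(out.isna().idxmax()) + 2
        raise ValueError(f"{path}:{line}: missing value in column {col!r}")
    return out


# -- climate ensemble --------------------------------------------------------

def write_ensemble(ensemble: ClimateEnsemble, path) -> None:
    rows = [
        {"year": int(y), "value": v, "model_id": "", "scenario": "observed"}
        for y, v in ensemble.observed.items()
    ]
    for m in ensemble.models:
        for i, v in enumerate(m.preindustrial.to_numpy()):
            rows.append(
                {"year": i + 1, "value": v, "model_id": m.model_id,
                 "scenario": "preindustrial"}
            )
        for y, v in m.projection.items():
            rows.append(
                {"year": int(y), "value": v, "model_id": m.model_id,
                 "scenario": "projection"}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ensemble(path) -> ClimateEnsemble:
    df = pd.read_csv(path, dtype={"model_id": str})
    _require_columns(df, ["year", "value", "model_id", "scenario"], path)
    bad = ~df["scenario"].isin(SCENARIOS)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}:{line}: unknown scenario {df['scenario'][bad.idxmax()]!r}")
    df["year"] = _numeric(df, "year", path).astype(int)
    df["value"] = _numeric(df, "value", path)
    obs = df[df["scenario"] == "observed"].sort_values("year")
    observed = pd.Series(
        obs["value"].to_numpy(), index=obs["year"].to_numpy(), name="observed"
    )
    models = []
    for mid, g in df[df["scenario"] != "observed"].groupby("model_id", sort=True):
        pre = g[g["scenario"] == "preindustrial"].sort_values("year")
        proj = g[g["scenario"] == "projection"].sort_values("year")
        models.append(
            ModelRealizations(
                model_id=str(mid),
                preindustrial=pd.Series(pre["value"].to_numpy(), name="preindustrial"),
                projection=pd.Series(
                    proj["value"].to_numpy(), index=proj["year"].to_numpy(),
                    name="projection",
                ),
            )
        )
    return ClimateEnsemble(observed=observed, models=models)


# -- FAR tables and estimates ------------------------------------------------

def write_far_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_far_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"model_id": str})
    _require_columns(df, ["year", "model_id", "far"], path)
    df["year"] = _numeric(df, "year", path).astype(int)
    df["far"] = _numeric(df, "far", path)
    return df


def write_far_estimate(est: FarEstimate, path) -> None:
    est.table.to_csv(path, index=False)


def read_far_estimate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "mean", "se"], path)
    df["year"] = _numeric(df, "year", path).astype(int)
    for col in df.columns.drop("year"):
        df[col] = _numeric(df, col, path)
    return df


# -- survey panel (long format) ----------------------------------------------

def write_panel(panel: pd.DataFrame, path) -> None:
    """Wide panel (year index, series columns) -> long CSV with empty fields
    for missing surveys."""
    long = panel.rename_axis("year").reset_index().melt(
        id_vars="year", var_name="series_id", value_name="value"
    )
    long.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"series_id": str})
    _require_columns(df, ["year", "series_id", "value"], path)
    df["year"] = _numeric(df, "year", path).astype(int)
    df["value"] = _numeric(df, "value", path, required=False)
    wide = df.pivot(index="year", columns="series_id", values="value").sort_index()
    wide.columns.name = None
    return wide


# -- seine sets ----------------------------------------------------------------

SEINE_COLUMNS = ["year", "day_of_year", "bay", "site", "temperature", "ssb", "count"]


def write_seine(data: pd.DataFrame, path) -> None:
    data[SEINE_COLUMNS].to_csv(path, index=False)


def read_seine(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bay": str, "site": str})
    _require_columns(df, SEINE_COLUMNS, path)
    for col in ("year", "day_of_year", "count"):
        vals = _numeric(df, col, path)
        frac = ~np.isclose(vals.to_numpy(), np.round(vals.to_numpy()))
        if frac.any():
            line = int(vals.index[frac][0]) + 2
            raise ValueError(f"{path}:{line}: column {col!r} must be integer")
        df[col] = vals.astype(int)
    if (df["count"] < 0).any():
        line = int((df["count"] < 0).idxmax()) + 2
        raise ValueError(f"{path}:{line}: negative count")
    for col in ("temperature", "ssb"):
        df[col] = _numeric(df, col, path)
    return df


# -- recruitment series --------------------------------------------------------

def write_recruitment(series: pd.Series, path, source: str = "assessment") -> None:
    pd.DataFrame(
        {"year": series.index.to_numpy(), "log_anomaly": series.to_numpy(),
         "source": source}
    ).to_csv(path, index=False)


def read_recruitment(path) -> pd.Series:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "log_anomaly"], path)
    df["year"] = _numeric(df, "year", path).astype(int)
    df["log_anomaly"] = _numeric(df, "log_anomaly", path)
    return pd.Series(
        df["log_anomaly"].to_numpy(), index=df["year"].to_numpy(),
        name="log_anomaly",
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
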