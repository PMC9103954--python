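"""Delimited-text readers/writers, point-to-area aggregation and config.

All interchange is CSV (UTF-8, header row, '.' decimal, ISO-8601 dates,
planar-metre coordinates); configuration is a nested-key YAML file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_panel",
    "write_panel",
    "read_table",
    "write_table",
    "aggregate_points_to_areas",
    "load_config",
]

_DATE_COLS = ("date",)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in _DATE_COLS:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in _DATE_COLS:
        if c in out.columns:
            out[c] = pd.DatetimeIndex(out[c]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")
    return path


read_panel = read_table
write_panel = write_table


def aggregate_points_to_areas(predictions: pd.DataFrame, membership: pd.DataFrame) -> pd.DataFrame:
    """Average point predictions to areas (postcode centroids -> LSOA-like).

    ``predictions`` has (site_id, date, prediction); ``membership`` maps
    point_id -> area_id.  Every prediction point must be mapped.
    """
    key = "site_id" if "site_id" in predictions.columns else "point_id"
    mem = membership.rename(columns={membership.columns[0]: key})
    merged = predictions.merge(mem, on=key, how="left")
    unmapped = merged.loc[merged["area_id"].isna(), key].unique()
    if len(unmapped):
        raise ValueError(f"unmapped prediction point(s): {list(unmapped)[:5]}")
    out = (
        merged.groupby(["area_id", "date"], as_index=False)
        .agg(prediction=("prediction", "mean"), n_points=("prediction", "size"))
    )
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
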