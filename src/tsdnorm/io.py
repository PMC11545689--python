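"""CSV / JSON / YAML readers and writers.

All temperatures are degrees Celsius in every file; headers are mandatory;
the decimal separator is '.'.  Validation errors name the offending row so
malformed literature tables fail loudly rather than silently.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import DurationSummary, TemperatureSeries
from .hierfit import PosteriorDraws
from .tsd_curve import SexCountRecord

__all__ = [
    "read_sexcounts_csv",
    "write_sexcounts_csv",
    "read_temperature_series_csv",
    "write_temperature_series_csv",
    "read_duration_summaries_csv",
    "write_duration_summaries_csv",
    "write_posterior",
    "read_posterior",
    "write_comparison_csv",
    "write_cte_csv",
    "load_config",
]

SEXCOUNT_COLUMNS = ["temperature_C", "males", "females", "intersex",
                    "rmu", "study_id", "clutch"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_sexcounts_csv(path: str | Path) -> list[SexCountRecord]:
    """Read sexed-count records (columns ``temperature_C, males, females,
    intersex, rmu, study_id, clutch``; the last four may be empty)."""
    df = pd.read_csv(path, dtype={"rmu": str, "study_id": str, "clutch": str},
                     float_precision="round_trip")
    _require_columns(df, ["temperature_C", "males", "females"], path)
    records = []
    for i, row in df.iterrows():
        t = row["temperature_C"]
        if not math.isfinite(t):
            raise ValueError(f"{path} row {i}: non-finite temperature")
        def label(col):
            v = row.get(col, "")
            return "" if pd.isna(v) else str(v)
        try:
            records.append(
                SexCountRecord(
                    temperature=float(t),
                    males=float(row["males"]),
                    females=float(row["females"]),
                    intersex=float(row["intersex"])
                    if "intersex" in df.columns and pd.notna(row["intersex"])
                    else 0.0,
                    rmu=label("rmu"),
                    study_id=label("study_id"),
                    clutch=label("clutch"),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} row {i}: {e}") from e
    return records


def write_sexcounts_csv(records: list[SexCountRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "temperature_C": r.temperature,
                "males": r.males,
                "females": r.females,
                "intersex": r.intersex,
                "rmu": r.rmu,
                "study_id": r.study_id,
                "clutch": r.clutch,
            }
            for r in records
        ],
        columns=SEXCOUNT_COLUMNS,
    ).to_csv(path, index=False)


def read_temperature_series_csv(path: str | Path) -> TemperatureSeries:
    """Read a nest temperature series (columns ``time_min, temp_C``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_min", "temp_C"], path)
    bad = df.index[~np.isfinite(df["time_min"]) | ~np.isfinite(df["temp_C"])]
    if len(bad):
        raise ValueError(f"{path} row {bad[0]}: non-finite value")
    return TemperatureSeries(times=df["time_min"].to_numpy(dtype=float),
                             temps=df["temp_C"].to_numpy(dtype=float))


def write_temperature_series_csv(series: TemperatureSeries, path: str | Path) -> None:
    pd.DataFrame({"time_min": series.times, "temp_C": series.temps}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_duration_summaries_csv(path: str | Path) -> list[DurationSummary]:
    """Read duration summaries (columns ``temp_C, mean_days, sd_days,
    n_clutches``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["temp_C", "mean_days", "sd_days", "n_clutches"], path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                DurationSummary(
                    temperature=float(row["temp_C"]),
                    mean_days=float(row["mean_days"]),
                    sd_days=float(row["sd_days"]),
                    n=int(row["n_clutches"]),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} row {i}: {e}") from e
    return out


def write_duration_summaries_csv(data: list[DurationSummary], path: str | Path) -> None:
    rows = []
    for d in data:
        if d.temperature is None:
            raise ValueError(
                "series-based duration summaries cannot be written to the "
                "constant-temperature CSV format"
            )
        rows.append({"temp_C": d.temperature, "mean_days": d.mean_days,
                     "sd_days": d.sd_days, "n_clutches": d.n})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_posterior(draws: PosteriorDraws, path: str | Path) -> None:
    """Write draws as CSV plus a ``.meta.json`` sidecar (seed, settings,
    random-effect structure)."""
    path = Path(path)
    draws.draws.to_csv(path, index=False, float_format="%.17g")
    meta = {k: v for k, v in draws.meta.items() if k != "logpost"}
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=float)


def read_posterior(path: str | Path) -> PosteriorDraws:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return PosteriorDraws(draws=df, meta=meta)


def write_comparison_csv(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a model-comparison report
    (``model, k, n, aicc_mean, aicc_se, weight_mean, weight_se``)."""
    scores.reset_index().to_csv(path, index=False)


def write_cte_csv(rows: list[dict], path: str | Path) -> None:
    """Write per-nest CTE results (``nest_id, mean_tempC, median_cte,
    ci95_low, ci95_high, males, females``)."""
    pd.DataFrame(
        rows,
        columns=["nest_id", "mean_tempC", "median_cte", "ci95_low",
                 "ci95_high", "males", "females"],
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
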