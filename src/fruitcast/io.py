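"""CSV/JSON readers and writers for every pipeline artifact.

All files are UTF-8 CSV with ISO-8601 dates and '.' decimal separators;
JSON artifacts use sorted keys so runs diff cleanly.

Schemas
-------
temperature.csv   timestamp, temp_c
measurements.csv  fruit_id, cultivar, anthesis_date, meas_date, long_cm,
                  short_cm, harvest_date, harvest_mass_g
                  (harvest fields blank until the fruit is harvested)
calibration.csv   fruit_id, cultivar, volume_cm3, mass_g
anchors.csv       fruit_id, cultivar, scheme, E_<anchor>..., r2, qc_pass,
                  extrapolated
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .errors import SchemaError
from .synthetic_data import FruitRecord
from .thermal_time import TemperatureSeries

__all__ = [
    "write_temperature_csv",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_calibration_csv",
    "read_calibration_csv",
    "write_anchor_csv",
    "write_report_json",
]


def write_temperature_csv(series: TemperatureSeries, path) -> None:
    pd.DataFrame(
        {"timestamp": series.days.astype(str), "temp_c": series.temps}
    ).to_csv(path, index=False)


MEASUREMENT_COLUMNS = [
    "fruit_id", "cultivar", "anthesis_date", "meas_date",
    "long_cm", "short_cm", "harvest_date", "harvest_mass_g",
]


def write_measurements_csv(fruits: Iterable[FruitRecord], path) -> None:
    rows = []
    for f in fruits:
        for date, long_cm, short_cm in f.measurements:
            rows.append(
                {
                    "fruit_id": f.fruit_id,
                    "cultivar": f.cultivar,
                    "anthesis_date": f.anthesis.isoformat(),
                    "meas_date": date.isoformat(),
                    "long_cm": round(long_cm, 4),
                    "short_cm": round(short_cm, 4),
                    "harvest_date": f.harvest_date.isoformat() if f.harvest_date else "",
                    "harvest_mass_g": round(f.harvest_mass_g, 4)
                    if f.harvest_mass_g is not None
                    else "",
                }
            )
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def _parse_dates(col: pd.Series, name: str) -> pd.Series:
    parsed = pd.to_datetime(col, format="ISO8601", errors="coerce")
    bad = parsed.isna() & col.notna() & (col.astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise SchemaError(f"unparseable {name} at line {line}: {col[bad.idxmax()]!r}")
    return parsed


def read_measurements_csv(path) -> List[FruitRecord]:
    """Read per-fruit measurement records, grouping repeated rows per fruit."""
    df = pd.read_csv(path, dtype={"fruit_id": str, "cultivar": str})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"measurements CSV missing columns: {sorted(missing)}")
    df["anthesis_date"] = _parse_dates(df["anthesis_date"], "anthesis_date")
    df["meas_date"] = _parse_dates(df["meas_date"], "meas_date")
    df["harvest_date"] = _parse_dates(df["harvest_date"], "harvest_date")
    for col in ("long_cm", "short_cm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric {col} at line {int(bad.idxmax()) + 2}: {df[col][bad.idxmax()]!r}"
            )
        df[col] = vals
    df["harvest_mass_g"] = pd.to_numeric(df["harvest_mass_g"], errors="coerce")

    fruits: List[FruitRecord] = []
    for fid, grp in df.groupby("fruit_id", sort=True):
        grp = grp.sort_values("meas_date")
        first = grp.iloc[0]
        harvest_date = first["harvest_date"]
        harvest_mass = first["harvest_mass_g"]
        fruits.append(
            FruitRecord(
                fruit_id=str(fid),
                cultivar=str(first["cultivar"]),
                anthesis=first["anthesis_date"].date(),
                measurements=tuple(
                    (r.meas_date.date(), float(r.long_cm), float(r.short_cm))
                    for r in grp.itertuples()
                ),
                harvest_date=None if pd.isna(harvest_date) else harvest_date.date(),
                harvest_mass_g=None if pd.isna(harvest_mass) else float(harvest_mass),
            )
        )
    return fruits


def write_calibration_csv(calibration: Dict[str, List[Tuple[float, float]]], path) -> None:
    rows = []
    for cultivar, pairs in calibration.items():
        slug = cultivar.lower().replace(" ", "-")
        for i, (v, m) in enumerate(pairs):
            rows.append(
                {
                    "fruit_id": f"{slug}-cal-{i:04d}",
                    "cultivar": cultivar,
                    "volume_cm3": round(v, 4),
                    "mass_g": round(m, 4),
                }
            )
    pd.DataFrame(rows, columns=["fruit_id", "cultivar", "volume_cm3", "mass_g"]).to_csv(
        path, index=False
    )


def read_calibration_csv(path) -> Dict[str, List[Tuple[float, float]]]:
    df = pd.read_csv(path, dtype={"cultivar": str})
    missing = {"cultivar", "volume_cm3", "mass_g"} - set(df.columns)
    if missing:
        raise SchemaError(f"calibration CSV missing columns: {sorted(missing)}")
    out: Dict[str, List[Tuple[float, float]]] = {}
    for cultivar, grp in df.groupby("cultivar", sort=True):
        out[str(cultivar)] = list(
            zip(grp["volume_cm3"].astype(float), grp["mass_g"].astype(float))
        )
    return out


def write_anchor_csv(records: Sequence, path) -> None:
    """Write anchored-fruit rows (see pipeline.AnchorRecord)."""
    rows = []
    for r in records:
        row = {"fruit_id": r.fruit_id, "cultivar": r.cultivar, "scheme": r.scheme}
        for a, v in zip(r.anchor_taus, r.anchor_values):
            row[f"E_{int(a)}"] = round(float(v), 4)
        row.update(
            r2=round(float(r.r2), 6),
            qc_pass=bool(r.qc_pass),
            extrapolated=bool(r.extrapolated),
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report_json(reports: Sequence[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(list(reports), fh, indent=2, sort_keys=True)
        fh.write("\n")
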