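"""Tabular readers/writers, flat configuration files and run manifests.

CSV dialect: UTF-8, header row, decimal point.  Gas-exchange tables are one
instrument observation per row; common LI-6400-style header aliases
("Photo" for A, "Cond" for gs, "PARi" for PPFD, ...) are resolved
automatically, or an explicit :class:`ColumnMap` can be supplied.
Weather tables are one day per row with humidity as either ``RH`` (%) or
``ea_kPa``.  Malformed rows are rejected with their row number.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .diurnal import DailyWeather
from .estimation import GasExchangeRecord

PathLike = Union[str, Path]

#: canonical gas-exchange column -> accepted header spellings
DEFAULT_ALIASES = {
    "A": ("A", "Photo", "Asat", "An"),
    "Ca": ("Ca", "CO2S", "CO2R"),
    "Ci": ("Ci",),
    "gs": ("gs", "Cond", "gsw"),
    "PPFD": ("PPFD", "PARi", "Qin", "Q"),
    "Tleaf": ("Tleaf", "TleafC"),
    "Fs": ("Fs",),
    "Fm_prime": ("Fm_prime", "Fm'", "FmPrime", "Fmp"),
    "O2_percent": ("O2_percent", "O2", "Oxygen"),
}

_REQUIRED = ("A", "Ca", "Ci", "gs", "PPFD", "Tleaf", "Fs", "Fm_prime")


class SchemaError(ValueError):
    """A required column is missing or cannot be resolved."""


@dataclass(frozen=True)
class ColumnMap:
    """Explicit canonical-name -> CSV-header mapping (overrides aliases)."""

    mapping: dict = field(default_factory=dict)

    def resolve(self, columns: Sequence[str]) -> dict:
        """Return canonical -> actual header for the given CSV columns."""
        out = {}
        cols = list(columns)
        for canonical, aliases in DEFAULT_ALIASES.items():
            if canonical in self.mapping:
                header = self.mapping[canonical]
                if header not in cols:
                    raise SchemaError(
                        f"mapped column {header!r} for {canonical!r} not in file")
                out[canonical] = header
                continue
            for alias in aliases:
                if alias in cols:
                    out[canonical] = alias
                    break
        missing = [c for c in _REQUIRED if c not in out]
        if missing:
            raise SchemaError(f"cannot resolve required columns: {missing}")
        return out


def read_gasexchange_csv(path: PathLike,
                         colmap: Optional[ColumnMap] = None
                         ) -> list[GasExchangeRecord]:
    """Read a gas-exchange/fluorescence table into typed records."""
    df = pd.read_csv(path)
    resolved = (colmap or ColumnMap()).resolve(df.columns)
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for canonical, header in resolved.items():
            raw = row[header]
            try:
                kwargs[canonical] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {idx + 2}, column {header!r}: "
                    f"non-numeric value {raw!r}") from exc
        if "O2_percent" not in kwargs:
            kwargs["O2_percent"] = 21.0
        try:
            records.append(GasExchangeRecord(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def write_gasexchange_csv(records: Sequence[GasExchangeRecord],
                          path: PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, index=False)


_WEATHER_COLS = {"latitude": "latitude", "day_of_year": "day_of_year",
                 "radiation_MJ": "radiation_daily", "Tmax": "Tmax",
                 "Tmin": "Tmin"}


def read_weather_csv(path: PathLike) -> list[DailyWeather]:
    """Read daily weather, one row per day; humidity via RH or ea_kPa."""
    df = pd.read_csv(path)
    missing = [c for c in _WEATHER_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"weather file missing columns: {missing}")
    if "RH" not in df.columns and "ea_kPa" not in df.columns:
        raise SchemaError("weather file needs an RH or ea_kPa column")
    days = []
    for idx, row in df.iterrows():
        kwargs = {}
        try:
            for header, fname in _WEATHER_COLS.items():
                kwargs[fname] = float(row[header])
            kwargs["day_of_year"] = int(row["day_of_year"])
            if "RH" in df.columns and pd.notna(row.get("RH")):
                kwargs["rh"] = float(row["RH"])
            elif "ea_kPa" in df.columns and pd.notna(row.get("ea_kPa")):
                kwargs["ea_kPa"] = float(row["ea_kPa"])
            if "Ca" in df.columns and pd.notna(row.get("Ca")):
                kwargs["Ca"] = float(row["Ca"])
            days.append(DailyWeather(**kwargs))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
    return days


def write_weather_csv(days: Sequence[DailyWeather], path: PathLike) -> None:
    rows = []
    for d in days:
        rows.append({"latitude": d.latitude, "day_of_year": d.day_of_year,
                     "radiation_MJ": d.radiation_daily, "Tmax": d.Tmax,
                     "Tmin": d.Tmin, "RH": d.rh, "ea_kPa": d.ea_kPa,
                     "Ca": d.Ca})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flat configuration and manifests
# ---------------------------------------------------------------------------

def save_config(obj, path: PathLike) -> None:
    """Serialise a (dataclass or dict) configuration as flat key: value YAML."""
    data = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else dict(obj)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)


def load_config(path: PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    return data


def config_hash(config: dict) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_manifest(path: PathLike, *, inputs: dict, config: dict,
                       seed: Optional[int] = None, outputs: Optional[dict] = None
                       ) -> dict:
    """Write a machine-readable record sufficient to reproduce a run."""
    manifest = {"inputs": inputs, "config": config,
                "config_hash": config_hash(config), "seed": seed,
                "outputs": outputs or {}}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
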