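"""Plain-CSV readers/writers for all tables, plus GeoJSON registry export.

All tables are UTF-8, comma-separated, "." decimal, with a header row.
Schemas match the generator output: see ``neonet.synth`` column constants.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from neonet.displacement import normalize_codes
from neonet.errors import DataValidationError
from neonet.synth import (BED_COLUMNS, BIRTH_COLUMNS, DEATH_COLUMNS,
                          HOSP_COLUMNS, REGISTRY_COLUMNS)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _read(path: str | Path, required: list[str],
          code_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    for col in code_cols:
        df[col] = normalize_codes(df[col])
    return df


def read_registry(path: str | Path) -> pd.DataFrame:
    return _read(path, REGISTRY_COLUMNS, code_cols=("code",))


def read_hospitalizations(path: str | Path) -> pd.DataFrame:
    return _read(path, HOSP_COLUMNS,
                 code_cols=("residence_code", "occurrence_code"))


def read_births(path: str | Path) -> pd.DataFrame:
    return _read(path, BIRTH_COLUMNS, code_cols=("residence_code",))


def read_deaths(path: str | Path) -> pd.DataFrame:
    return _read(path, DEATH_COLUMNS, code_cols=("residence_code",))


def read_beds(path: str | Path) -> pd.DataFrame:
    return _read(path, BED_COLUMNS, code_cols=("municipality_code",))


def read_od(path: str | Path) -> pd.DataFrame:
    return _read(path, ["origin_code", "destination_code",
                        "biennium_label", "flow"],
                 code_cols=("origin_code", "destination_code"))


def registry_to_geojson(registry: pd.DataFrame, path: str | Path) -> None:
    """Export municipality seats as a GeoJSON FeatureCollection of points."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(r.seat_lon), float(r.seat_lat)]},
            "properties": {
                "code": int(r.code), "name": str(r.name),
                "region_id": int(r.region_id), "macroregion": str(r.macroregion),
                "is_region_seat": bool(r.is_region_seat),
            },
        }
        for r in registry.itertuples(index=False)
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))
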