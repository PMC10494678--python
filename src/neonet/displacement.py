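"""Record selection and origin-destination displacement tables.

A displacement is a distinct pair between the mother's municipality of
residence (origin) and the municipality where the newborn's hospitalization
occurred (destination).  Records are restricted to the neonatal period
(age 0-27 days, closed window), split into same-municipality / displaced /
out-of-state partitions, and the displaced in-state records aggregated into
an OD flow table per biennium (2008-2009 ... 2018-2019).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from neonet.errors import DataValidationError, YearRangeError
from neonet.synth import OUT_OF_STATE

NEONATAL_MAX_AGE_DAYS = 27

BIENNIUM_START = 2008
BIENNIUM_END = 2019

OD_COLUMNS = ["origin_code", "destination_code", "biennium_label", "flow"]


@dataclass(frozen=True, order=True)
class Biennium:
    """A two-year grouping of the study period, e.g. ``2008-2009`` (index 1)."""

    index: int
    label: str

    def __post_init__(self) -> None:
        start = BIENNIUM_START + 2 * (self.index - 1)
        if self.label != f"{start}-{start + 1}":
            raise DataValidationError(
                f"label {self.label!r} inconsistent with index {self.index}")


#: The six biennia of the study period, 2008-2009 .. 2018-2019.
BIENNIA = tuple(
    Biennium(index=i + 1, label=f"{BIENNIUM_START + 2 * i}-{BIENNIUM_START + 2 * i + 1}")
    for i in range((BIENNIUM_END - BIENNIUM_START + 1) // 2)
)


def assign_biennium(year: int) -> Biennium:
    """Map an admission year to its biennium (2008 -> index 1, 2019 -> index 6)."""
    if not BIENNIUM_START <= year <= BIENNIUM_END:
        raise YearRangeError(
            f"year {year} outside study period {BIENNIUM_START}-{BIENNIUM_END}")
    return BIENNIA[(int(year) - BIENNIUM_START) // 2]


def biennium_labels(years: pd.Series | np.ndarray) -> pd.Series:
    """Vectorized year -> biennium label mapping with range checking."""
    years = pd.Series(np.asarray(years))
    if len(years) and not years.between(BIENNIUM_START, BIENNIUM_END).all():
        bad = years[~years.between(BIENNIUM_START, BIENNIUM_END)].unique()
        raise YearRangeError(f"years outside study period: {sorted(bad)}")
    start = BIENNIUM_START + 2 * ((years - BIENNIUM_START) // 2)
    return start.astype(str) + "-" + (start + 1).astype(str)


def normalize_codes(codes: pd.Series | np.ndarray) -> np.ndarray:
    """Normalize municipality codes to 6 digits.

    7-digit codes (6 digits + check digit, IBGE style) are accepted with
    the check digit dropped; the out-of-state sentinel passes through.
    """
    codes = np.asarray(codes, dtype=np.int64)
    seven = (codes >= 1_000_000) & (codes != OUT_OF_STATE)
    return np.where(seven, codes // 10, codes)


def filter_neonatal(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the admissions with age 0-27 days (closed window).

    Input row order is preserved; negative ages are a data error.
    """
    if len(records) == 0:
        return records.copy()
    ages = records["age_days"]
    if (ages < 0).any():
        raise DataValidationError("negative age_days in hospitalization records")
    return records[ages <= NEONATAL_MAX_AGE_DAYS].copy()


def partition_displaced(records: pd.DataFrame, registry: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, float]:
    """Split neonatal records into (displaced, same-municipality, out-of-state).

    The three parts are disjoint and exhaustive.  Also returns, for
    reporting, the out-of-state share among all displaced admissions
    (out-of-state plus displaced in-state; the ~1% figure); the analysis
    itself uses only in-state records.
    """
    occurrence = pd.Series(normalize_codes(records["occurrence_code"]),
                           index=records.index)
    known = set(registry["code"].tolist())
    unknown = ~(occurrence.isin(known) | (occurrence == OUT_OF_STATE))
    if unknown.any():
        bad = sorted(occurrence[unknown].unique())[:5]
        raise DataValidationError(
            f"occurrence codes absent from registry and not the sentinel: {bad}")
    residence = pd.Series(normalize_codes(records["residence_code"]),
                          index=records.index)
    is_oos = occurrence == OUT_OF_STATE
    is_same = (occurrence == residence) & ~is_oos
    is_displaced = ~is_same & ~is_oos
    n_moved = int(is_oos.sum() + is_displaced.sum())
    oos_share = float(is_oos.sum() / n_moved) if n_moved else 0.0
    return (records[is_displaced].copy(), records[is_same].copy(),
            records[is_oos].copy(), oos_share)


def aggregate_od(displaced: pd.DataFrame) -> pd.DataFrame:
    """Aggregate displaced in-state records into the OD flow table.

    One row per distinct (origin, destination, biennium) with its flow
    count; total flow equals the number of input records and no zero-flow
    pairs appear.
    """
    if len(displaced) == 0:
        return pd.DataFrame(columns=OD_COLUMNS).astype(
            {"origin_code": np.int64, "destination_code": np.int64,
             "biennium_label": object, "flow": np.int64})
    origin = normalize_codes(displaced["residence_code"])
    destination = normalize_codes(displaced["occurrence_code"])
    if (origin == destination).any():
        raise DataValidationError("aggregate_od expects displaced records only")
    if (destination == OUT_OF_STATE).any():
        raise DataValidationError("aggregate_od expects in-state records only")
    table = pd.DataFrame({
        "origin_code": origin,
        "destination_code": destination,
        "biennium_label": biennium_labels(displaced["year"]).to_numpy(),
    })
    od = (table.groupby(["origin_code", "destination_code", "biennium_label"],
                        as_index=False)
          .size().rename(columns={"size": "flow"}))
    return od.sort_values(OD_COLUMNS[:3], ignore_index=True)
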