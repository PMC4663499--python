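"""Protectiveness screening of ecotoxicity threshold values (ETVs).

A water-quality guideline set specifies threshold concentrations intended to
protect 99 %, 95 % or 90 % of species. A threshold can only protect the
photosynthetic endpoint if it sits *below* the concentration at which the
endpoint is measurably inhibited; we use the IC10 as that onset-of-effect
concentration. The decision rule is

    protective  <=>  ETV < ICx

i.e. a threshold exactly equal to the ICx is flagged non-protective (at the
threshold concentration the endpoint is already inhibited by x %). Missing
ETVs are emitted with ``protective`` = NA (not assessable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .doseresponse import ICEstimate

__all__ = ["GuidelineSet", "flag_protectiveness", "protectiveness_table"]


@dataclass(frozen=True)
class GuidelineSet:
    """One guideline source's ETVs (µg/l) for one herbicide; None = missing."""

    source: str
    herbicide: str
    etv_99: float | None = None
    etv_95: float | None = None
    etv_90: float | None = None

    def __post_init__(self) -> None:
        for lvl in (99, 95, 90):
            v = getattr(self, f"etv_{lvl}")
            if v is not None and not v > 0:
                raise ValueError(f"ETV {lvl}% for {self.herbicide!r} must be > 0")

    def as_rows(self) -> list[dict]:
        return [
            {
                "herbicide": self.herbicide,
                "source": self.source,
                "protection_pct": lvl,
                "etv_ugL": getattr(self, f"etv_{lvl}"),
            }
            for lvl in (99, 95, 90)
        ]


def flag_protectiveness(
    ic: ICEstimate | float,
    guidelines: Iterable[GuidelineSet],
    *,
    herbicide: str | None = None,
    icx_level: float | None = None,
) -> pd.DataFrame:
    """Flag each ETV of each guideline set against an ICx estimate.

    Returns one row per (source, protection level):
    ``protective`` True when ETV < ICx, False when ETV >= ICx, NA when the
    ETV is missing.
    """
    if isinstance(ic, ICEstimate):
        icx_value = ic.value
        icx_level = ic.level if icx_level is None else icx_level
    else:
        icx_value = float(ic)
        icx_level = 10.0 if icx_level is None else icx_level
    if not icx_value > 0:
        raise ValueError("ICx value must be positive")

    rows = []
    for gs in guidelines:
        if herbicide is not None and gs.herbicide != herbicide:
            raise ValueError(
                f"guideline set for {gs.herbicide!r} does not match {herbicide!r}"
            )
        for row in gs.as_rows():
            etv = row["etv_ugL"]
            row["icx_level"] = icx_level
            row["icx_value"] = icx_value
            row["protective"] = pd.NA if etv is None else bool(etv < icx_value)
            rows.append(row)
    return pd.DataFrame(rows).astype({"protective": "boolean"})


def protectiveness_table(
    icx_by_herbicide: dict[str, float],
    guidelines: pd.DataFrame,
    *,
    icx_level: float = 10.0,
) -> pd.DataFrame:
    """Vectorised protectiveness flags over a long-format guideline table.

    ``guidelines`` needs columns ``herbicide``, ``source``, ``protection_pct``
    and ``etv_ugL`` (NaN = no guideline). Herbicides absent from
    ``icx_by_herbicide`` are dropped. Adds ``icx_value`` and ``protective``
    (nullable boolean) columns.
    """
    df = guidelines.copy()
    df = df[df["herbicide"].isin(icx_by_herbicide)].reset_index(drop=True)
    df["icx_level"] = icx_level
    df["icx_value"] = df["herbicide"].map(icx_by_herbicide)
    has_etv = df["etv_ugL"].notna()
    prot = pd.array([pd.NA] * len(df), dtype="boolean")
    prot[has_etv.to_numpy()] = (
        df.loc[has_etv, "etv_ugL"].to_numpy()
        < df.loc[has_etv, "icx_value"].to_numpy()
    )
    df["protective"] = prot
    return df
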