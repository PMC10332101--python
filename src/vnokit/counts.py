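"""Activity-mapping count statistics: percent-positive, density, reduction.

Two count readouts are supported: pS6-positive cells as a percent of all
DAPI-stained nuclei (vomeronasal sections) and c-Fos-positive cells per
um^2 (downstream brain regions).  A subject's value is the unweighted mean
over that subject's regions/sections; an area-weighted mean is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import DataError, round_half_away


@dataclass
class CountRegion:
    """One counted region/section of one subject."""

    subject_id: str
    region_label: str
    area_um2: float
    positive_count: int
    dapi_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise DataError(f"region {self.region_label}: area must be positive")
        if self.positive_count < 0:
            raise DataError(f"region {self.region_label}: negative positive count")
        if self.dapi_count is not None and self.positive_count > self.dapi_count:
            raise DataError(
                f"region {self.region_label}: positives ({self.positive_count}) "
                f"exceed DAPI nuclei ({self.dapi_count})"
            )


def percent_positive(region: CountRegion) -> float:
    """Positive cells as percent of DAPI nuclei in one region."""
    if not region.dapi_count:
        raise DataError(f"region {region.region_label}: DAPI count missing or zero")
    return 100.0 * region.positive_count / region.dapi_count


def density_per_area(region: CountRegion) -> float:
    """Positive cells per um^2 in one region."""
    return region.positive_count / region.area_um2


def subject_means(
    regions: Sequence[CountRegion],
    measure: str = "percent_positive",
    area_weighted: bool = False,
) -> pd.Series:
    """Per-subject mean of a region measure (unweighted by default)."""
    fn = {"percent_positive": percent_positive, "density_per_area": density_per_area}[measure]
    rows = [
        {"subject_id": r.subject_id, "value": fn(r), "area": r.area_um2} for r in regions
    ]
    df = pd.DataFrame(rows)
    if area_weighted:
        agg = df.groupby("subject_id").apply(
            lambda g: float(np.average(g["value"], weights=g["area"])),
            include_groups=False,
        )
    else:
        agg = df.groupby("subject_id")["value"].mean()
    return agg


def percent_reduction(control_value: float, test_value: float, ndigits: int = 0) -> float:
    """Percent drop from control to test, rounded half away from zero."""
    if control_value <= 0:
        raise DataError("control value must be positive")
    return round_half_away(100.0 * (control_value - test_value) / control_value, ndigits)


# -- table I/O --------------------------------------------------------------

COUNT_COLUMNS = ("subject_id", "region_label", "area_um2", "positive_count")


def read_count_table(path) -> list[CountRegion]:
    """Read a delimited count table; dapi_count column is optional."""
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"count table {path}: missing columns {missing}")
    return regions_from_table(df)


def regions_from_table(df: pd.DataFrame) -> list[CountRegion]:
    has_dapi = "dapi_count" in df.columns
    out = []
    for r in df.itertuples():
        dapi = None
        if has_dapi and pd.notna(r.dapi_count):
            dapi = int(r.dapi_count)
        out.append(
            CountRegion(str(r.subject_id), str(r.region_label), float(r.area_um2),
                        int(r.positive_count), dapi)
        )
    return out


def regions_to_table(regions: Sequence[CountRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject_id": r.subject_id, "region_label": r.region_label,
             "area_um2": r.area_um2, "positive_count": r.positive_count,
             "dapi_count": r.dapi_count}
            for r in regions
        ]
    )
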