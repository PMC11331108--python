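"""Per-taxon duration and geographic range estimation.

Durations are real-valued: the spread between the oldest and youngest
locality age-range midpoints at which a taxon occurs.  Ranges are estimated
as a rectangular bounding box resting on the extreme latitudes and
longitudes of the taxon's localities, with one degree taken as 111 km in
both directions (a square-pixel approximation; an optional cosine correction
of the longitudinal extent is available).  Range width is the square root of
range area, i.e. the side of the equivalent square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

KM_PER_DEGREE = 111.0
HEXAGON_AREA_KM2 = 1643.0


@dataclass(frozen=True)
class DurationEstimate:
    taxon_id: str
    duration: float  # My
    n_localities: int


@dataclass(frozen=True)
class RangeEstimate:
    taxon_id: str
    method: str  # bounding_box | convex_hull | hexagon_count
    area: float  # km^2
    width: float  # km
    n_localities: int


def _dated(df):
    return df.dropna(subset=["age_min", "age_max"])


def _located(df):
    return df.dropna(subset=["lat", "lon"])


def taxon_duration(taxon) -> DurationEstimate:
    """Duration as the maximum spread of locality age-range midpoints.

    A taxon known from a single dated locality has duration zero by
    construction (a singleton).
    """
    df = _dated(taxon.occurrences)
    if df.empty:
        raise ValueError(f"taxon {taxon.taxon_id}: no dated localities")
    mids = (df["age_min"].to_numpy() + df["age_max"].to_numpy()) / 2.0
    return DurationEstimate(
        taxon_id=taxon.taxon_id,
        duration=float(mids.max() - mids.min()),
        n_localities=int(df["locality_id"].nunique()),
    )


def bounding_box_area(taxon, correct_longitude: bool = False) -> RangeEstimate:
    """Rectangular bounding-box range over the taxon's located occurrences.

    area = (dlat * 111 km) * (dlon * 111 km); with ``correct_longitude`` the
    longitudinal extent is additionally scaled by cos(mean latitude).
    Longitudes are used as-is; ranges straddling the antimeridian are not
    unwrapped (no terrestrial mammal record spans it).
    """
    df = _located(taxon.occurrences)
    if df.empty:
        raise ValueError(f"taxon {taxon.taxon_id}: no located occurrences")
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    dlat_km = (lat.max() - lat.min()) * KM_PER_DEGREE
    dlon_km = (lon.max() - lon.min()) * KM_PER_DEGREE
    if correct_longitude:
        dlon_km *= math.cos(math.radians(float(lat.mean())))
    area = dlat_km * dlon_km
    return RangeEstimate(
        taxon_id=taxon.taxon_id,
        method="bounding_box",
        area=area,
        width=range_width(area),
        n_localities=int(df["locality_id"].nunique()),
    )


def range_width(area: float) -> float:
    """Side length (km) of the square with the given area (km^2)."""
    if area < 0:
        raise ValueError(f"negative area {area}")
    return math.sqrt(area)


def hexagon_range_area(n_hex: int) -> float:
    """Range area from a hexagonal-grid presence count (1,643 km^2 per cell)."""
    if n_hex < 0:
        raise ValueError(f"negative hexagon count {n_hex}")
    return n_hex * HEXAGON_AREA_KM2


def convex_hull_area(taxon) -> RangeEstimate:
    """Planar convex-hull range (supplementary estimator).

    The hull is computed in degree coordinates and scaled by 111^2 to km^2;
    collinear or degenerate point sets have zero area.
    """
    from shapely import MultiPoint

    df = _located(taxon.occurrences)
    if df.empty:
        raise ValueError(f"taxon {taxon.taxon_id}: no located occurrences")
    pts = MultiPoint(list(zip(df["lon"].to_numpy(float), df["lat"].to_numpy(float))))
    area = pts.convex_hull.area * KM_PER_DEGREE ** 2
    return RangeEstimate(
        taxon_id=taxon.taxon_id,
        method="convex_hull",
        area=float(area),
        width=range_width(float(area)),
        n_localities=int(df["locality_id"].nunique()),
    )


def expansion_area_gain(width: float, step: float = 1.0) -> tuple[float, float]:
    """Area gained by widening a square range by one linear step.

    Returns ``(absolute_gain, relative_gain)`` where the relative gain is
    per km^2 already occupied.  Widening a 10 km square to 11 km gains
    21 km^2 (0.21 per km^2); widening 100 km to 101 km gains 201 km^2
    (0.0201 per km^2) — constant linear expansion yields diminishing
    relative returns in area.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    gain = (width + step) ** 2 - width ** 2
    return gain, gain / width ** 2


def taxon_summary_frame(taxa, method: str = "bounding_box",
                        with_duration: bool = True):
    """Per-taxon summary table: durations and range estimates.

    Taxa without usable coordinates (or dates, for fossil tables) get NaN in
    the corresponding columns rather than being dropped.
    """
    import pandas as pd

    estimator = {"bounding_box": bounding_box_area,
                 "convex_hull": convex_hull_area}[method]
    rows = []
    for taxon in taxa:
        row = {"taxon": taxon.taxon_id, "n_occurrences": len(taxon.occurrences)}
        if with_duration:
            try:
                d = taxon_duration(taxon)
                row["duration_My"] = d.duration
                row["n_localities"] = d.n_localities
            except ValueError:
                row["duration_My"] = np.nan
        try:
            r = estimator(taxon)
            row.update(area_km2=r.area, width_km=r.width, method=r.method,
                       n_localities=r.n_localities)
        except ValueError:
            row.update(area_km2=np.nan, width_km=np.nan, method=method)
        rows.append(row)
    return pd.DataFrame(rows)
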