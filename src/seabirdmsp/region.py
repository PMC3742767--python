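"""Study-region geometry and the cruise calendar.

All geometry lives in one local planar frame in metres (x east, y north).
Distances used as model covariates (to the mainland, to the 200-m isobath
shelf break, and to the breeding colony) are plain Euclidean distances in
this frame; no geodesy is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from shapely.geometry import LineString, Point, Polygon, mapping, shape

__all__ = ["StudyRegion", "default_region"]


@dataclass
class StudyRegion:
    """Geographic referents for the survey and prediction domain.

    Attributes
    ----------
    boundary:
        Simple closed polygon delimiting the study area (sanctuary extent).
    colony:
        The seabird breeding colony (Southeast Farallon Island analogue);
        referent for the ``dist_sefi_m`` covariate.
    mainland:
        Coastline polyline; referent for ``dist_land_m``.
    isobath_200m:
        The 200-m depth contour marking the continental shelf break;
        referent for ``dist_200_m``.
    calendar:
        Cruise calendar as ``(year, month)`` pairs, one per cruise, in
        cruise order.  Cruise end days (needed for the trailing upwelling
        average) are derived deterministically from the cruise index.
    """

    boundary: Polygon
    colony: Point
    mainland: LineString
    isobath_200m: LineString
    calendar: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise ValueError("region boundary must be a simple, closed polygon")
        if not self.boundary.contains(self.colony):
            raise ValueError("colony must lie inside the region boundary")
        if len(self.calendar) < 1:
            raise ValueError("cruise calendar must contain at least one (year, month) entry")
        for y, m in self.calendar:
            if not 1 <= m <= 12:
                raise ValueError(f"invalid calendar month: {(y, m)}")

    @property
    def n_cruises(self) -> int:
        return len(self.calendar)

    def cruise_id(self, index: int) -> str:
        y, m = self.calendar[index]
        return f"c{index:02d}_{y}_{m:02d}"

    def cruise_end_day(self, index: int) -> int:
        # Deterministic spread of end days so cruises sharing a month still
        # get distinct 10-day trailing upwelling windows.
        return 8 + 2 * (index % 10)

    # ------------------------------------------------------------------ io
    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "properties": {"calendar": [list(c) for c in self.calendar]},
            "features": [
                {"type": "Feature", "properties": {"layer": name},
                 "geometry": mapping(geom)}
                for name, geom in [
                    ("boundary", self.boundary),
                    ("colony", self.colony),
                    ("mainland", self.mainland),
                    ("isobath_200m", self.isobath_200m),
                ]
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, gj: dict) -> "StudyRegion":
        layers = {f["properties"]["layer"]: shape(f["geometry"]) for f in gj["features"]}
        calendar = [tuple(c) for c in gj.get("properties", {}).get("calendar", [])]
        return cls(
            boundary=layers["boundary"],
            colony=layers["colony"],
            mainland=layers["mainland"],
            isobath_200m=layers["isobath_200m"],
            calendar=calendar,
        )

    @classmethod
    def load(cls, path) -> "StudyRegion":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def _default_calendar() -> list[tuple[int, int]]:
    """27 cruises over eight breeding seasons (April-September).

    Every year is surveyed in May, July and September; the three earliest
    years add one spring/summer cruise each, giving 27 cruises total.
    """
    cal: list[tuple[int, int]] = []
    extra = {2004: 4, 2005: 6, 2006: 8}
    for year in range(2004, 2012):
        months = sorted([5, 7, 9] + ([extra[year]] if year in extra else []))
        cal.extend((year, m) for m in months)
    return cal


def default_region() -> StudyRegion:
    """Synthetic shelf-and-slope study area, ~60 km (E-W) x 45 km (N-S).

    The mainland runs along the eastern edge, the 200-m isobath runs
    roughly north-south near x = 18 km, and the colony sits mid-shelf.
    Proportions mirror a central-California sanctuary setting: east-west
    transects cross the shelf break, and bin-to-referent distances fall in
    the tens-of-kilometres range.
    """
    boundary = Polygon([(0, 0), (60_000, 0), (60_000, 45_000), (0, 45_000)])
    # an irregular coastline (headlands and bays) so the three distance
    # covariates decorrelate across transect latitudes
    mainland = LineString([
        (50_000, -10_000), (58_000, 5_000), (52_000, 15_000),
        (59_000, 25_000), (53_000, 33_000), (60_000, 45_000), (56_000, 55_000),
    ])
    # the shelf break sweeps offshore-to-onshore with latitude, so the
    # three distance covariates decorrelate across transect lines
    isobath = LineString([
        (8_000, -10_000), (16_000, 5_000), (24_000, 20_000),
        (30_000, 32_000), (40_000, 45_000), (45_000, 55_000),
    ])
    colony = Point(40_000, 15_000)
    return StudyRegion(
        boundary=boundary,
        colony=colony,
        mainland=mainland,
        isobath_200m=isobath,
        calendar=_default_calendar(),
    )
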