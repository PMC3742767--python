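"""Scored human-activity footprints -> per-cell human-use cost layer.

Six consolidated ocean-use activities, each with an expert impact score
from 1 (low) to 5 (high), are represented as polygons of their dominant
spatial footprint.  A grid cell's general human-use score is the sum of
the scores of every activity whose dominant footprint overlaps the cell
(any polygon/cell overlap counts, not centroid membership), giving a
maximum possible score of 17 with the default score table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .config import DEFAULT_ACTIVITY_SCORES

__all__ = ["ActivityFootprint", "score_cells", "footprints_to_geojson",
           "footprints_from_geojson"]


@dataclass
class ActivityFootprint:
    """One activity's polygon footprint with its impact score."""

    name: str
    geometry: BaseGeometry
    score: int
    footprint_class: str = "dominant"  # general | dominant | future

    def __post_init__(self):
        if not 1 <= int(self.score) <= 5:
            raise ValueError(f"{self.name}: impact score must be in 1..5")
        if self.footprint_class not in {"general", "dominant", "future"}:
            raise ValueError(f"{self.name}: unknown footprint class {self.footprint_class!r}")


def score_cells(
    cells: pd.DataFrame,
    footprints: list[ActivityFootprint],
    cell_size_m: float = 1000.0,
    expected_names=frozenset(DEFAULT_ACTIVITY_SCORES),
) -> pd.DataFrame:
    """Sum activity impact scores over each grid cell.

    ``cells`` needs ``cell_id, cx, cy`` (centroids, metres).  Only
    dominant-class footprints contribute.  A footprint whose name is not
    one of the six consolidated activities is rejected.
    """
    for fp in footprints:
        if fp.name not in expected_names:
            raise ValueError(
                f"unknown activity {fp.name!r}; expected one of {sorted(expected_names)}"
            )
    half = cell_size_m / 2.0
    boxes = shapely.box(
        cells["cx"].to_numpy() - half, cells["cy"].to_numpy() - half,
        cells["cx"].to_numpy() + half, cells["cy"].to_numpy() + half,
    )
    total = np.zeros(len(cells), dtype=float)
    for fp in footprints:
        if fp.footprint_class != "dominant":
            continue
        hits = shapely.intersects(boxes, fp.geometry)
        total += fp.score * hits
    out = cells.copy()
    out["human_use_score"] = total
    return out


def footprints_to_geojson(footprints: list[ActivityFootprint]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "properties": {"name": fp.name, "score": int(fp.score),
                            "class": fp.footprint_class},
             "geometry": mapping(fp.geometry)}
            for fp in footprints
        ],
    }


def footprints_from_geojson(gj: dict) -> list[ActivityFootprint]:
    return [
        ActivityFootprint(
            name=f["properties"]["name"],
            geometry=shape(f["geometry"]),
            score=int(f["properties"]["score"]),
            footprint_class=f["properties"].get("class", "dominant"),
        )
        for f in gj["features"]
    ]


def save_footprints(footprints, path) -> None:
    with open(path, "w") as fh:
        json.dump(footprints_to_geojson(footprints), fh)


def load_footprints(path) -> list[ActivityFootprint]:
    with open(path) as fh:
        return footprints_from_geojson(json.load(fh))
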