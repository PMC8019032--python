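"""Readers and writers for the pipeline's file formats.

Land-patch mosaics travel as GeoJSON FeatureCollections (planar metric
coordinates; properties patch_id, land_type, category); tabular inputs are
plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely.geometry import mapping, shape

from .landscape import LandPatch

__all__ = ["read_patches", "write_patches", "read_table"]


def read_patches(path: str | Path) -> list[LandPatch]:
    """Load land patches from a GeoJSON FeatureCollection."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    patches = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        patches.append(
            LandPatch(
                patch_id=str(props["patch_id"]),
                polygon=shape(feat["geometry"]),
                land_type=str(props["land_type"]),
                category=str(props["category"]),
            )
        )
    return patches


def write_patches(patches: Sequence[LandPatch], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "patch_id": p.patch_id,
                    "land_type": p.land_type,
                    "category": p.category,
                },
            }
            for p in patches
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
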