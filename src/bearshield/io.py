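"""Plain-text serialization: stamped CSVs, GeoJSON features, YAML configs."""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping

__all__ = [
    "config_hash",
    "write_stamped_csv",
    "read_stamped_csv",
    "features_to_geojson",
    "homeranges_to_geojson",
    "write_yaml_config",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "isoformat"):
        return obj.isoformat()
    if hasattr(obj, "__fspath__"):
        return str(obj)
    return obj


def config_hash(config, exclude=("out_dir",)) -> str:
    """Short stable hash of a (dataclass or mapping) configuration.

    Output-location fields are excluded so the hash identifies the analysis,
    not where its files land.
    """
    payload = _jsonable(config)
    if isinstance(payload, dict):
        payload = {k: v for k, v in payload.items() if k not in exclude}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def write_stamped_csv(frame: pd.DataFrame, path, seed, cfg_hash: str) -> None:
    """Write a CSV with a provenance comment line (seed + config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={cfg_hash}\n")
        frame.to_csv(fh, index=False)


def read_stamped_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def features_to_geojson(features, path) -> None:
    """Write habitation points and road polylines as a GeoJSON collection."""
    out = {"type": "FeatureCollection", "features": []}
    for x, y in np.asarray(features.habitations, dtype=float):
        out["features"].append(
            {
                "type": "Feature",
                "properties": {"class": "habitation"},
                "geometry": {"type": "Point", "coordinates": [x, y]},
            }
        )
    for cls, lines in (("road", features.roads), ("forest_road", features.forest_roads)):
        for line in lines:
            out["features"].append(
                {
                    "type": "Feature",
                    "properties": {"class": cls},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": np.asarray(line, dtype=float).tolist(),
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump(out, fh)


def homeranges_to_geojson(home_ranges, path) -> None:
    out = {"type": "FeatureCollection", "features": []}
    for hr in home_ranges:
        out["features"].append(
            {
                "type": "Feature",
                "properties": {"bear_id": hr.bear_id, "year": hr.year, "area_m2": hr.area},
                "geometry": mapping(hr.polygon),
            }
        )
    with open(path, "w") as fh:
        json.dump(out, fh)


def write_yaml_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config), fh, sort_keys=True)
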