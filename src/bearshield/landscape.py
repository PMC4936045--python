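"""Synthetic landscape generation.

The study system is managed boreal forest with scattered human habitation,
a sparse network of high-traffic roads and a denser network of forest
roads.  The generator emits the covariate stack the habitat-selection
models use: Euclidean distance (km) to the nearest habitation, road and
forest road; a seven-class land-cover raster (bog, tree-rich bog,
clearcut, young, mid-aged and old forest, plus "other"); and NDVI as a
vegetation-density proxy.  Everything is produced on one common grid from
a single integer seed, so downstream stages can be tested against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridSpec

__all__ = [
    "LANDCOVER_CLASSES",
    "LANDCOVER_INDICATORS",
    "DISTANCE_LAYERS",
    "CONTINUOUS_LAYERS",
    "FeatureSet",
    "LandscapeStack",
    "LandscapeConfig",
    "compute_ndvi",
    "gen_landscape",
]

#: Land-cover classes in code order; "other" is the implicit model baseline.
LANDCOVER_CLASSES = ("bog", "trb", "clearcut", "young", "mid_aged", "old", "other")

#: The six dummy-coded classes (all-zero row = "other").
LANDCOVER_INDICATORS = LANDCOVER_CLASSES[:-1]

DISTANCE_LAYERS = ("dist_habitation", "dist_road", "dist_forest_road")
CONTINUOUS_LAYERS = DISTANCE_LAYERS + ("ndvi",)

_FEATURE_FOR_LAYER = {
    "dist_habitation": "habitations",
    "dist_road": "roads",
    "dist_forest_road": "forest_roads",
}


@dataclass
class FeatureSet:
    """Human-footprint features: habitation points and road polylines (planar m)."""

    habitations: np.ndarray  # (k, 2)
    roads: list[np.ndarray] = field(default_factory=list)  # each (m_i, 2)
    forest_roads: list[np.ndarray] = field(default_factory=list)

    def of_class(self, name: str):
        if name not in ("habitations", "roads", "forest_roads"):
            raise KeyError(f"unknown feature class {name!r}")
        return getattr(self, name)


@dataclass
class LandscapeStack:
    """Co-registered named raster layers on a single grid.

    ``continuous`` maps layer name -> float raster (distances in km, NDVI
    unitless in [-1, 1]); ``landcover`` holds integer codes indexing
    :data:`LANDCOVER_CLASSES`.
    """

    grid: GridSpec
    continuous: dict[str, np.ndarray]
    landcover: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name, layer in self.continuous.items():
            if layer.shape != shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} != grid {shape}")
            if name.startswith("dist_") and np.nanmin(layer) < 0:
                raise ValueError(f"distance layer {name!r} has negative values")
        if self.landcover.shape != shape:
            raise ValueError("landcover raster does not match the grid")
        if "ndvi" in self.continuous:
            ndvi = self.continuous["ndvi"]
            if np.nanmin(ndvi) < -1 or np.nanmax(ndvi) > 1:
                raise ValueError("NDVI outside [-1, 1]")

    def landcover_fractions(self) -> dict[str, float]:
        """Realized areal fraction of each land-cover class."""
        n = self.landcover.size
        return {
            cls: float(np.sum(self.landcover == code)) / n
            for code, cls in enumerate(LANDCOVER_CLASSES)
        }


def compute_ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index (NIR - Red)/(NIR + Red).

    Cells where both bands are zero are set to NaN (undefined index).
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if nir.shape != red.shape:
        raise ValueError("NIR and Red rasters are not co-registered (shape mismatch)")
    if np.nanmin(nir) < 0 or np.nanmin(red) < 0:
        raise ValueError("reflectance bands must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir - red) / denom
    out[denom == 0] = np.nan
    return out


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic landscape.

    Defaults emulate the study system at desk scale: habitation density of a
    few dozen settlements over a ~10 x 10 km window, forest roads ~5x denser
    than high-traffic roads, and land-cover proportions typical of managed
    boreal forest.
    """

    n_habitations: int = 40
    n_roads: int = 3
    n_forest_roads: int = 14
    landcover_props: dict[str, float] = field(
        default_factory=lambda: {
            "bog": 0.10,
            "trb": 0.10,
            "clearcut": 0.15,
            "young": 0.20,
            "mid_aged": 0.20,
            "old": 0.15,
            "other": 0.10,
        }
    )
    smooth_sigma: float = 6.0  # cells; patch size of the land-cover mosaic
    ndvi_sigma: float = 8.0
    ndvi_range: tuple[float, float] = (0.0, 0.9)


def _random_polyline(rng: np.random.Generator, grid: GridSpec, n_waypoints: int = 6) -> np.ndarray:
    """A polyline crossing the extent with lateral jitter (a road)."""
    xmin, ymin, xmax, ymax = grid.extent
    horizontal = rng.random() < 0.5
    t = np.linspace(0.0, 1.0, n_waypoints)
    if horizontal:
        xs = xmin + t * (xmax - xmin)
        y0 = rng.uniform(ymin, ymax)
        ys = y0 + rng.normal(0.0, 0.08 * (ymax - ymin), n_waypoints).cumsum()
        ys = np.clip(ys, ymin, ymax - 1e-6)
    else:
        ys = ymin + t * (ymax - ymin)
        x0 = rng.uniform(xmin, xmax)
        xs = x0 + rng.normal(0.0, 0.08 * (xmax - xmin), n_waypoints).cumsum()
        xs = np.clip(xs, xmin, xmax - 1e-6)
    return np.column_stack([xs, ys])


def _classify_by_quantile(
    field_vals: np.ndarray, props: dict[str, float]
) -> np.ndarray:
    """Threshold a continuous field into classes at target areal proportions.

    Cells are ranked by field value and assigned classes in code order, so
    realized fractions match the targets up to integer rounding and the
    mosaic inherits the field's spatial autocorrelation.
    """
    total = sum(props.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"land-cover proportions sum to {total}, expected 1")
    n = field_vals.size
    order = np.argsort(field_vals, axis=None, kind="stable")
    codes = np.empty(n, dtype=np.int8)
    start = 0
    for code, cls in enumerate(LANDCOVER_CLASSES):
        stop = n if code == len(LANDCOVER_CLASSES) - 1 else start + int(round(props[cls] * n))
        codes[order[start:stop]] = code
        start = stop
    return codes.reshape(field_vals.shape)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")


def gen_landscape(
    spec: GridSpec, config: LandscapeConfig | None = None, seed: int = 0
) -> tuple[LandscapeStack, FeatureSet]:
    """Generate a landscape stack and its human-footprint features.

    Habitations are placed by a homogeneous point process, roads are random
    crossing polylines, land cover is a smoothed-noise mosaic thresholded at
    the target class proportions, and NDVI is an independent smoothed field
    rescaled into ``config.ndvi_range``.  Distance layers are computed from
    the features and stored in kilometres.  Pure function of (spec, config,
    seed).
    """
    from .design import distance_to_features

    if config is None:
        config = LandscapeConfig()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = spec.extent

    habitations = np.column_stack(
        [
            rng.uniform(xmin, xmax, config.n_habitations),
            rng.uniform(ymin, ymax, config.n_habitations),
        ]
    )
    roads = [_random_polyline(rng, spec) for _ in range(config.n_roads)]
    forest_roads = [_random_polyline(rng, spec) for _ in range(config.n_forest_roads)]
    features = FeatureSet(habitations=habitations, roads=roads, forest_roads=forest_roads)

    shape = (spec.n_rows, spec.n_cols)
    landcover = _classify_by_quantile(
        _smooth_field(rng, shape, config.smooth_sigma), config.landcover_props
    )

    ndvi_raw = _smooth_field(rng, shape, config.ndvi_sigma)
    lo, hi = config.ndvi_range
    if not (-1.0 <= lo < hi <= 1.0):
        raise ValueError("ndvi_range must be an increasing interval within [-1, 1]")
    rmin, rmax = ndvi_raw.min(), ndvi_raw.max()
    ndvi = lo + (ndvi_raw - rmin) / (rmax - rmin) * (hi - lo)

    continuous = {"ndvi": ndvi}
    for layer in DISTANCE_LAYERS:
        continuous[layer] = distance_to_features(spec, features, _FEATURE_FOR_LAYER[layer])

    stack = LandscapeStack(grid=spec, continuous=continuous, landcover=landcover)
    return stack, features
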