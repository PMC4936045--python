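"""Covariate attachment and design-table construction.

Used and available locations are linked to the landscape layers by
nearest-cell lookup, continuous covariates are pooled-standardized (mean 0,
variance 1 over all rows of all bear-years, used and available alike,
because a single joint model is fitted), land cover is dummy-coded against
the implicit "other" baseline, and litter-survival interaction columns are
appended.  Collinearity among predictors is screened with variance
inflation factors.

Models are fitted on the natural "distance to" orientation; for reporting,
the signs of distance estimates are reversed so that positive values read
as selection *for* proximity to the feature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .grids import GridSpec
from .landscape import (
    CONTINUOUS_LAYERS,
    DISTANCE_LAYERS,
    LANDCOVER_INDICATORS,
    LandscapeStack,
)

__all__ = [
    "Standardization",
    "distance_to_features",
    "extract_at_points",
    "standardize",
    "compute_vif",
    "add_survival_interactions",
    "reverse_distance_signs",
    "build_use_avail_table",
    "interaction_col",
]


def interaction_col(term: str) -> str:
    """Column name of the litter-survival interaction for a main-effect term."""
    return f"{term}:survival"


def distance_to_features(grid: GridSpec, features, which: str) -> np.ndarray:
    """Raster of Euclidean distance (km) from each cell centre to the nearest feature.

    ``which`` is one of ``habitations`` (points), ``roads`` or
    ``forest_roads`` (polylines).  Raises if the requested class is empty.
    """
    geoms = features.of_class(which)
    if len(geoms) == 0:
        raise ValueError(f"feature class {which!r} is empty; cannot build a distance layer")
    X, Y = grid.cell_centers()
    if which == "habitations":
        tree = cKDTree(np.asarray(geoms, dtype=float))
        d, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
        return d.reshape(X.shape) / 1000.0
    pts = shapely.points(X.ravel(), Y.ravel())
    dmin = np.full(pts.shape, np.inf)
    for line in geoms:
        ls = shapely.LineString(np.asarray(line, dtype=float))
        np.minimum(dmin, shapely.distance(pts, ls), out=dmin)
    return dmin.reshape(X.shape) / 1000.0


def extract_at_points(stack: LandscapeStack, x, y) -> pd.DataFrame:
    """Raw covariate rows at planar points by nearest-cell lookup.

    Continuous layers are returned on their native scale (km, NDVI units);
    the land-cover code is expanded into the six indicator columns, with the
    "other" class mapping to all zeros.  Points outside the grid raise,
    naming the offending point.
    """
    row, col = stack.grid.index_of(x, y)
    out = {name: stack.continuous[name][row, col] for name in stack.continuous}
    codes = stack.landcover[row, col]
    for code, cls in enumerate(LANDCOVER_INDICATORS):
        out[cls] = (codes == code).astype(float)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class Standardization:
    """Per-covariate centring/scaling parameters on the raw (km / NDVI) scale."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if not s > 0:
                raise ValueError(f"standard deviation for {name!r} must be positive")

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name in self.mean:
            out[name] = (out[name] - self.mean[name]) / self.sd[name]
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name in self.mean:
            out[name] = out[name] * self.sd[name] + self.mean[name]
        return out


def standardize(
    table: pd.DataFrame, continuous_names=CONTINUOUS_LAYERS
) -> tuple[pd.DataFrame, Standardization]:
    """Centre and scale the named columns to mean 0, variance 1 (ddof=1), pooled.

    Pooling is over every row of the table (both response classes, all
    bear-years).  The parameters are returned so estimates can be
    back-transformed and new data mapped onto the same scale.
    """
    means, sds = {}, {}
    for name in continuous_names:
        col = table[name].to_numpy(dtype=float)
        sd = float(np.std(col, ddof=1))
        if not sd > 0:
            raise ValueError(f"column {name!r} has zero variance; cannot standardize")
        means[name] = float(np.mean(col))
        sds[name] = sd
    std = Standardization(mean=means, sd=sds)
    return std.apply(table), std


def compute_vif(table: pd.DataFrame, predictor_names) -> dict[str, float]:
    """Variance inflation factor of each predictor: 1 / (1 - R^2_j).

    R^2_j comes from the OLS regression of predictor j on the remaining
    predictors plus an intercept.  Exactly collinear predictors get
    ``inf``.
    """
    predictor_names = list(predictor_names)
    if len(predictor_names) < 2:
        raise ValueError("VIF needs at least two predictors")
    import statsmodels.api as sm

    X = table[predictor_names].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(predictor_names):
        yj = X[:, j]
        Xj = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(yj, Xj).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def compute_gvif(table: pd.DataFrame, groups: dict[str, list[str]]) -> dict[str, float]:
    """Generalized VIF per predictor group, df-adjusted to the single-VIF scale.

    For a group of d related columns (e.g. the land-cover dummy set)
    ``GVIF = det(R_g) det(R_rest) / det(R)``; the returned value is
    ``GVIF^(1/d)``, comparable against the same threshold as an ordinary
    VIF.  Individual dummy VIFs depend on the arbitrary choice of baseline
    class; the grouped form does not.
    """
    all_cols = [c for cols in groups.values() for c in cols]
    R = np.corrcoef(table[all_cols].to_numpy(dtype=float), rowvar=False)
    det_R = np.linalg.det(R)
    out = {}
    for name, cols in groups.items():
        idx = [all_cols.index(c) for c in cols]
        rest = [i for i in range(len(all_cols)) if i not in idx]
        det_g = np.linalg.det(R[np.ix_(idx, idx)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)]) if rest else 1.0
        if det_R <= 0:
            out[name] = float("inf")
            continue
        gvif = det_g * det_rest / det_R
        out[name] = float(gvif ** (1.0 / len(cols)))
    return out


def add_survival_interactions(table: pd.DataFrame, terms) -> pd.DataFrame:
    """Append ``term:survival`` product columns for each named main-effect term."""
    if "survival" not in table.columns:
        raise ValueError("table has no 'survival' column")
    out = table.copy()
    for term in terms:
        if term not in table.columns:
            raise KeyError(f"unknown term {term!r}")
        out[interaction_col(term)] = table[term] * table["survival"]
    return out


def reverse_distance_signs(fit, distance_terms=DISTANCE_LAYERS):
    """Reporting copy of a fit with distance-term estimates negated.

    Applies to the distance main effects and their survival interactions;
    standard errors, likelihood and AICc are untouched.  Involution: applying
    twice returns the original estimates.
    """
    flip = {t for t in distance_terms} | {interaction_col(t) for t in distance_terms}
    beta = {k: (-v if k in flip else v) for k, v in fit.beta.items()}
    return replace(fit, beta=beta)


def build_use_avail_table(
    stack: LandscapeStack,
    used: pd.DataFrame,
    available: pd.DataFrame,
    fates: dict,
) -> tuple[pd.DataFrame, Standardization]:
    """Assemble the model-ready use-availability table.

    ``used`` and ``available`` carry columns bear_id, year, x, y; ``fates``
    maps (bear_id, year) -> survival flag (1 = litter survived).  Covariates
    are extracted at every point, pooled-standardized, dummy-coded, and all
    survival interactions appended.  Raises if survival has no variation
    (the group contrast would be unidentifiable).
    """
    frames = []
    for is_used, pts in ((1, used), (0, available)):
        cov = extract_at_points(stack, pts["x"].to_numpy(), pts["y"].to_numpy())
        cov.insert(0, "is_used", is_used)
        cov.insert(1, "bear_id", pts["bear_id"].to_numpy())
        cov.insert(2, "year", pts["year"].to_numpy())
        frames.append(cov)
    table = pd.concat(frames, ignore_index=True)
    table.insert(
        3,
        "survival",
        [int(fates[(b, y)]) for b, y in zip(table["bear_id"], table["year"])],
    )
    if table["survival"].nunique() < 2:
        raise ValueError("survival has no variation: need both successful and unsuccessful bear-years")
    table, std = standardize(table)
    table = add_survival_interactions(
        table, list(CONTINUOUS_LAYERS) + list(LANDCOVER_INDICATORS)
    )
    return table, std
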