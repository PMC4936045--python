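"""Synthetic telemetry and litter-fate generation with known ground truth.

Used locations follow an exponential resource selection function: within a
mother's home disc, the density of use is proportional to
``exp(sum_j beta_j z_j(x))`` where ``z_j`` are the landscape covariates
(continuous layers standardized against the cell population, land-cover
classes as 0/1 indicators).  Successful and unsuccessful mothers get
separate coefficient vectors, so the survival-interaction contrast the
analysis estimates is known exactly.

Default coefficients reproduce the selection pattern the analysis is built
to detect: mothers with surviving litters select areas close to human
habitation while mothers that lose their litter avoid them, with weaker
group contrasts on the other covariates.  Coefficients are expressed on
the "distance" orientation (a positive coefficient on a distance covariate
means larger distances are selected, i.e. avoidance of the feature).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import Standardization
from .grids import GridSpec
from .landscape import (
    CONTINUOUS_LAYERS,
    LANDCOVER_INDICATORS,
    FeatureSet,
    LandscapeConfig,
    LandscapeStack,
    gen_landscape,
)
from .telemetry import BearYearRecord

__all__ = [
    "TruthConfig",
    "StudyConfig",
    "SimulatedStudy",
    "cell_standardization",
    "selection_score_grid",
    "simulate_bear_year",
    "simulate_fates",
    "make_study",
]

SEASON_START = (5, 1)  # 1 May: season opening of the analysis window
SEASON_END = (6, 16)  # 16 June: last observed litter loss; truncation date

# Generating coefficients (model scale, distance orientation).  The
# unsuccessful vector is the main-effect column of the fitted selection
# model this package estimates; the successful vector is main + interaction.
_BETA_UNSUCCESSFUL = {
    "dist_habitation": 0.210,
    "dist_road": 0.557,
    "dist_forest_road": 0.420,
    "ndvi": 0.188,
    "bog": -0.761,
    "trb": 0.452,
    "clearcut": -0.501,
    "young": 0.504,
    "mid_aged": 0.348,
    "old": 0.675,
}
_BETA_SUCCESSFUL = {
    "dist_habitation": -0.524,
    "dist_road": 0.338,
    "dist_forest_road": 0.349,
    "ndvi": 0.182,
    "bog": -1.159,
    "trb": 0.188,
    "clearcut": 0.560,
    "young": 0.437,
    "mid_aged": 0.557,
    "old": 0.190,
}


@dataclass
class TruthConfig:
    """Generating parameters of the synthetic study.

    ``beta_unsuccessful`` / ``beta_successful`` are selection coefficients of
    the exponential RSF for the two litter-fate groups.  ``p_litter_loss``
    matches the population's average annual cub mortality (35%), with loss
    dates concentrated early in the mating season (Beta(2, 3) over the
    season window).  ``fixes_per_day`` = 48 is the 30-min collar schedule;
    the fix-success rate and the DOP mixture jointly give ~60% of scheduled
    fixes surviving the DOP < 5 quality filter.
    """

    beta_unsuccessful: dict[str, float] = field(default_factory=lambda: dict(_BETA_UNSUCCESSFUL))
    beta_successful: dict[str, float] = field(default_factory=lambda: dict(_BETA_SUCCESSFUL))
    p_litter_loss: float = 0.35
    loss_date_beta: tuple[float, float] = (2.0, 3.0)
    n_successful: int = 19  # bear-years with surviving litters
    n_unsuccessful: int = 11  # bear-years with complete litter loss
    fixes_per_day: int = 48
    fix_success_rate: float = 0.95
    dop_high_frac: float = 0.37  # fraction of fixes with DOP >= 5 (filtered out)
    dop_low_range: tuple[float, float] = (1.0, 5.0)
    dop_high_range: tuple[float, float] = (5.0, 12.0)

    def __post_init__(self) -> None:
        for p in (self.p_litter_loss, self.fix_success_rate, self.dop_high_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if set(self.beta_unsuccessful) != set(self.beta_successful):
            raise ValueError("the two beta mappings must cover the same covariate names")

    def interaction_beta(self) -> dict[str, float]:
        """Generating survival-interaction contrast (successful minus unsuccessful)."""
        return {
            k: self.beta_successful[k] - self.beta_unsuccessful[k]
            for k in self.beta_unsuccessful
        }


def cell_standardization(stack: LandscapeStack) -> Standardization:
    """Standardization of the continuous layers against the cell population."""
    mean, sd = {}, {}
    for name in CONTINUOUS_LAYERS:
        vals = stack.continuous[name]
        mean[name] = float(np.nanmean(vals))
        sd[name] = float(np.nanstd(vals, ddof=1))
    return Standardization(mean=mean, sd=sd)


def selection_score_grid(stack: LandscapeStack, beta: dict[str, float]) -> np.ndarray:
    """Linear predictor eta = sum_j beta_j z_j evaluated on every cell.

    Continuous layers enter standardized by cell-population moments,
    land-cover classes as indicators.  Unknown covariate names raise.
    """
    std = cell_standardization(stack)
    eta = np.zeros((stack.grid.n_rows, stack.grid.n_cols))
    for name, b in beta.items():
        if name in stack.continuous:
            eta += b * (stack.continuous[name] - std.mean[name]) / std.sd[name]
        elif name in LANDCOVER_INDICATORS:
            code = LANDCOVER_INDICATORS.index(name)
            eta += b * (stack.landcover == code)
        else:
            raise KeyError(f"beta names unknown covariate {name!r}")
    return eta


def _season_bounds(year: int) -> tuple[dt.date, dt.date]:
    return dt.date(year, *SEASON_START), dt.date(year, *SEASON_END)


def _draw_dop(rng: np.random.Generator, n: int, truth: TruthConfig) -> np.ndarray:
    high = rng.random(n) < truth.dop_high_frac
    dop = rng.uniform(*truth.dop_low_range, n)
    dop[high] = rng.uniform(*truth.dop_high_range, high.sum())
    return dop


def simulate_bear_year(
    stack: LandscapeStack,
    home_center: tuple[float, float],
    home_radius: float,
    beta: dict[str, float],
    n_days: int,
    truth: TruthConfig,
    seed,
    bear_id: str = "B01",
    year: int = 2008,
) -> BearYearRecord:
    """Simulate one mother-year of GPS fixes under an exponential RSF.

    Candidate fixes follow the 30-min schedule from 1 May for ``n_days``;
    each is acquired with probability ``fix_success_rate``.  Acquired fix
    locations are drawn by rejection sampling: uniform proposals in the
    home disc, accepted with probability ``exp(eta - eta_max)`` where
    ``eta_max`` is the maximum linear predictor over disc cells.  DOP is
    drawn independently from the configured mixture, so a known fraction of
    fixes will fail the downstream quality filter.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    cx, cy = home_center
    xmin, ymin, xmax, ymax = grid.extent
    if (
        cx + home_radius <= xmin
        or cx - home_radius >= xmax
        or cy + home_radius <= ymin
        or cy - home_radius >= ymax
    ):
        raise ValueError("home disc does not intersect the grid")

    eta = selection_score_grid(stack, beta)
    if np.nanmax(np.abs(eta)) > 50:
        raise ValueError(
            "selection scores exceed |eta| = 50; rejection acceptance would underflow "
            "— use a smaller beta scale"
        )
    X, Y = grid.cell_centers()
    in_disc = (X - cx) ** 2 + (Y - cy) ** 2 <= home_radius**2
    if not in_disc.any():
        raise ValueError("home disc contains no cell centres")
    eta_max = float(eta[in_disc].max())

    season_start, _ = _season_bounds(year)
    n_slots = n_days * truth.fixes_per_day
    acquired = rng.random(n_slots) < truth.fix_success_rate
    n_keep = int(acquired.sum())

    xs = np.empty(n_keep)
    ys = np.empty(n_keep)
    filled = 0
    while filled < n_keep:
        m = max(4 * (n_keep - filled), 256)
        r = home_radius * np.sqrt(rng.random(m))
        th = rng.uniform(0.0, 2.0 * np.pi, m)
        px = cx + r * np.cos(th)
        py = cy + r * np.sin(th)
        ok = grid.contains(px, py)
        px, py = px[ok], py[ok]
        row, col = grid.index_of(px, py)
        accept = rng.random(len(px)) < np.exp(eta[row, col] - eta_max)
        px, py = px[accept], py[accept]
        take = min(len(px), n_keep - filled)
        xs[filled : filled + take] = px[:take]
        ys[filled : filled + take] = py[:take]
        filled += take

    t0 = dt.datetime.combine(season_start, dt.time(0, 0))
    step = dt.timedelta(minutes=24 * 60 // truth.fixes_per_day)
    stamps = pd.Series([t0 + i * step for i in np.flatnonzero(acquired)])
    fixes = pd.DataFrame(
        {
            "timestamp": stamps,
            "x": xs,
            "y": ys,
            "dop": _draw_dop(rng, n_keep, truth),
        }
    )
    return BearYearRecord(
        bear_id=bear_id,
        year=year,
        fixes=fixes,
        fix_rate=n_keep / n_slots if n_slots else None,
        meta={"home_center": (cx, cy), "home_radius": home_radius},
    )


def _draw_loss_date(rng: np.random.Generator, year: int, truth: TruthConfig) -> dt.date:
    start, end = _season_bounds(year)
    span = (end - start).days
    a, b = truth.loss_date_beta
    day = min(int(rng.beta(a, b) * (span + 1)), span)
    return start + dt.timedelta(days=day)


def simulate_fates(records, truth: TruthConfig, seed):
    """Assign litter fates: lost with probability ``p_litter_loss``, dated in-season.

    Lost litters receive a loss date drawn from the early-skewed Beta
    distribution over the season window; surviving litters get no date.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        if rng.random() < truth.p_litter_loss:
            out.append(
                replace(rec, fate="lost", loss_date=_draw_loss_date(rng, rec.year, truth))
            )
        else:
            out.append(replace(rec, fate="survived", loss_date=None))
    return out


@dataclass
class StudyConfig:
    """Scale and layout of a full synthetic study."""

    grid: GridSpec = field(default_factory=GridSpec)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    home_radius: float = 2000.0  # m; ~12.6 km2 mating-season range
    n_days: int | None = None  # default: full season window
    years: tuple[int, ...] = tuple(range(2005, 2013))
    # bear-years per individual mirror the monitored sample: a few mothers
    # contribute two seasons (16 individuals / 19 bear-years successful,
    # 10 / 11 unsuccessful)
    repeat_successful: int = 3
    repeat_unsuccessful: int = 1


@dataclass
class SimulatedStudy:
    """A complete synthetic data set with its generating truth."""

    landscape: LandscapeStack
    features: FeatureSet
    bear_years: list
    truth: TruthConfig
    seed: int


def make_study(config: StudyConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Generate landscape plus all bear-years with fixed group sizes.

    Group sizes come from ``truth.n_successful`` / ``truth.n_unsuccessful``
    (the monitored-sample design, not a Bernoulli draw); ``simulate_fates``
    offers the stochastic-fate alternative.  Deterministic in (config, seed).
    """
    if config is None:
        config = StudyConfig()
    ss = np.random.SeedSequence(seed)
    land_seed, *rest = ss.spawn(3)
    stack, features = gen_landscape(config.grid, config.landscape, land_seed)
    rng = np.random.default_rng(rest[0])

    truth = config.truth
    season_days = (dt.date(2000, *SEASON_END) - dt.date(2000, *SEASON_START)).days + 1
    n_days = config.n_days if config.n_days is not None else season_days

    def bear_year_plan(n_years: int, n_repeat: int, prefix: str):
        if n_years <= 0:
            return []
        n_repeat = min(n_repeat, n_years - 1)
        n_ind = n_years - n_repeat
        plan = []
        for i in range(n_ind):
            plan.append(f"{prefix}{i + 1:02d}")
        for i in range(n_repeat):
            plan.append(f"{prefix}{i + 1:02d}")  # first individuals re-monitored
        return plan

    xmin, ymin, xmax, ymax = config.grid.extent
    r = config.home_radius
    records = []
    groups = (
        ("survived", bear_year_plan(truth.n_successful, config.repeat_successful, "S"), truth.beta_successful),
        ("lost", bear_year_plan(truth.n_unsuccessful, config.repeat_unsuccessful, "U"), truth.beta_unsuccessful),
    )
    fix_seeds = iter(ss.spawn(truth.n_successful + truth.n_unsuccessful))
    used_years: dict[str, set] = {}
    for fate, plan, beta in groups:
        for bear_id in plan:
            taken = used_years.setdefault(bear_id, set())
            year = int(rng.choice([y for y in config.years if y not in taken]))
            taken.add(year)
            center = (
                rng.uniform(xmin + r, xmax - r) if xmax - xmin > 2 * r else 0.5 * (xmin + xmax),
                rng.uniform(ymin + r, ymax - r) if ymax - ymin > 2 * r else 0.5 * (ymin + ymax),
            )
            rec = simulate_bear_year(
                stack, center, r, beta, n_days, truth, next(fix_seeds), bear_id=bear_id, year=year
            )
            if fate == "lost":
                rec = replace(rec, fate="lost", loss_date=_draw_loss_date(rng, year, truth))
            else:
                rec = replace(rec, fate="survived")
            records.append(rec)
    return SimulatedStudy(
        landscape=stack, features=features, bear_years=records, truth=truth, seed=seed
    )
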