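"""Paper-style outputs: coefficient plots, importance plots, use summaries.

Coefficients are reported per litter-fate group: the unsuccessful group's
selection is the main effect of each landscape variable; the successful
group's is main + survival interaction, with the standard error combined
from the joint curvature of the fit.  Distance-to-feature estimates are
sign-reversed for display so that positive always reads "selection for".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .design import interaction_col
from .glmm import FitResult
from .landscape import CONTINUOUS_LAYERS, DISTANCE_LAYERS, LANDCOVER_INDICATORS
from .selection import CONCLUSIVE_DELTA

__all__ = ["group_estimates", "report_coefficients", "report_importance", "use_summaries"]

Z95 = 1.96


def group_estimates(fit: FitResult, reverse_distances: bool = True) -> pd.DataFrame:
    """Per-group estimates and 95% intervals for each landscape term.

    unsuccessful = main effect; successful = main + interaction with
    ``se = sqrt(var_main + var_int + 2 cov)`` from the fitted covariance.
    """
    rows = []
    for term in fit.spec.fixed_terms:
        b_main = fit.beta[term]
        se_main = fit.se[term]
        icol = interaction_col(term)
        if icol in fit.beta:
            b_succ = b_main + fit.beta[icol]
            var = (
                fit.vcov.loc[term, term]
                + fit.vcov.loc[icol, icol]
                + 2.0 * fit.vcov.loc[term, icol]
            )
            se_succ = float(np.sqrt(max(var, 0.0)))
        else:
            b_succ, se_succ = b_main, se_main
        sign = -1.0 if (reverse_distances and term in DISTANCE_LAYERS) else 1.0
        for group, b, se in (("unsuccessful", b_main, se_main), ("successful", b_succ, se_succ)):
            rows.append(
                (term, group, sign * b, se, sign * b - Z95 * se, sign * b + Z95 * se)
            )
    out = pd.DataFrame(rows, columns=["term", "group", "estimate", "se", "lo", "hi"])
    if not out.empty:
        lo = np.minimum(out["lo"], out["hi"])
        hi = np.maximum(out["lo"], out["hi"])
        out["lo"], out["hi"] = lo, hi
    return out


def report_coefficients(fit: FitResult, csv_path=None, fig_path=None) -> pd.DataFrame:
    """Coefficient table plus the two-group dot-and-interval figure."""
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to report coefficients")
    table = group_estimates(fit)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if fig_path is not None:
        terms = list(dict.fromkeys(table["term"]))
        fig, ax = plt.subplots(figsize=(7, 0.45 * len(terms) + 1.5))
        for offset, (group, color) in enumerate((("successful", "k"), ("unsuccessful", "0.6"))):
            sub = table[table["group"] == group].set_index("term").loc[terms]
            ypos = np.arange(len(terms)) + (0.15 if offset == 0 else -0.15)
            ax.errorbar(
                sub["estimate"],
                ypos,
                xerr=Z95 * sub["se"],
                fmt="o",
                color=color,
                label=group,
                capsize=2,
            )
        ax.axvline(0.0, color="0.8", lw=1)
        ax.set_yticks(np.arange(len(terms)), terms)
        ax.set_xlabel("selection coefficient (beta +/- 1.96 s.e.; positive = selection for)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return table


def report_importance(importance: pd.DataFrame, csv_path=None, fig_path=None) -> pd.DataFrame:
    """Bar chart of reported interaction importance with the conclusiveness line."""
    if importance.empty:
        raise ValueError("importance table is empty")
    if csv_path is not None:
        importance.to_csv(csv_path, index=False)
    if fig_path is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(importance["term"], importance["reported_importance"], color="0.4")
        ax.axhline(CONCLUSIVE_DELTA, color="k", lw=1, ls="--")
        ax.set_ylabel("importance of litter-survival interaction (-delta AICc_diff)")
        ax.tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return importance


def use_summaries(table: pd.DataFrame, standardization=None) -> pd.DataFrame:
    """Habitat-use summary per litter-fate group and response class.

    Medians of each continuous covariate (back-transformed to the raw
    km / NDVI scale when the standardization is supplied) and the
    proportion of points in each land-cover class.
    """
    if table.empty:
        raise ValueError("use-availability table is empty")
    work = standardization.invert(table) if standardization is not None else table
    rows = []
    for (survival, is_used), grp in work.groupby(["survival", "is_used"]):
        group = "successful" if survival == 1 else "unsuccessful"
        cls = "used" if is_used == 1 else "available"
        entry = {"group": group, "class": cls, "n": len(grp)}
        for name in CONTINUOUS_LAYERS:
            entry[f"median_{name}"] = float(grp[name].median())
        for name in LANDCOVER_INDICATORS:
            entry[f"prop_{name}"] = float(grp[name].mean())
        entry["prop_other"] = float(
            1.0 - sum(entry[f"prop_{n}"] for n in LANDCOVER_INDICATORS)
        )
        rows.append(entry)
    return pd.DataFrame(rows)
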