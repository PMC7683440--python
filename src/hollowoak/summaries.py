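"""Yearly summary tables, occupancy counts, and temporal-variability statistics.

Because the number of trees surveyed differs between years, the development of
the whole metapopulation is tracked by the average estimated population size
per sampled tree; temporal variability of a series is its coefficient of
variation, CV = SD over time / mean over time (sample SD, n-1 denominator).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def cv(series) -> float:
    """Coefficient of variation of a time series (sample SD / mean).

    Requires at least two values; a zero mean makes the CV undefined and
    returns NaN with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least two observations")
    m = x.mean()
    if m == 0:
        warnings.warn("zero mean: CV undefined", stacklevel=2)
        return float("nan")
    return float(x.std(ddof=1) / m)


def yearly_summary(estimates: pd.DataFrame) -> pd.DataFrame:
    """One row per survey year: sampling effort, captures and estimated size.

    ``estimates`` is the per-tree-year table from the two-tier estimator
    (columns ``season_year, tree_id, r, s, N_hat``).  Years with zero sampled
    trees are excluded with a warning.
    """
    required = {"season_year", "tree_id", "r", "s", "N_hat"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates missing columns: {sorted(missing)}")
    out = (
        estimates.groupby("season_year")
        .agg(n_trees_sampled=("tree_id", "size"),
             total_captures=("s", "sum"),
             total_individuals=("r", "sum"),
             estimated_total=("N_hat", "sum"))
        .reset_index()
    )
    empty = out[out.n_trees_sampled == 0]
    if len(empty):
        warnings.warn(
            f"excluding years with no sampled trees: {empty.season_year.tolist()}",
            stacklevel=2,
        )
        out = out[out.n_trees_sampled > 0]
    out["avg_per_tree"] = out.estimated_total / out.n_trees_sampled
    return out.reset_index(drop=True)


def occupancy_summary(counts: pd.DataFrame) -> tuple[int, int, float]:
    """How many sampled trees ever held the species.

    A tree counts as occupied if at least one individual was ever captured in
    it (column ``r`` per tree-year).  Returns ``(n_occupied, n_sampled,
    fraction)``.
    """
    if not {"tree_id", "r"} <= set(counts.columns):
        raise ValueError("counts table needs tree_id and r columns")
    if counts.empty:
        raise ValueError("no sampled trees")
    per_tree = counts.groupby("tree_id")["r"].max()
    n_sampled = int(per_tree.size)
    n_occupied = int((per_tree >= 1).sum())
    return n_occupied, n_sampled, n_occupied / n_sampled


def top_tree_cv(
    estimates: pd.DataFrame, min_years: int = 8, top_k: int = 7
) -> pd.DataFrame:
    """CV of the estimated population series for the largest local populations.

    Trees with at least ``min_years`` trapping years are ranked by their
    time-averaged estimated population size and the ``top_k`` largest are
    returned with their per-tree CVs.  Fewer than ``top_k`` eligible trees
    returns all of them with a warning.
    """
    g = estimates.groupby("tree_id")["N_hat"]
    stats = pd.DataFrame({"n_years": g.size(), "mean_N": g.mean()})
    eligible = stats[stats.n_years >= min_years]
    if len(eligible) < top_k:
        warnings.warn(
            f"only {len(eligible)} trees have >= {min_years} trapping years",
            stacklevel=2,
        )
    # deterministic ranking: mean size desc, then tree id
    chosen = eligible.sort_values(
        ["mean_N"], ascending=False, kind="mergesort"
    ).head(top_k)
    rows = []
    for tree_id in chosen.index:
        series = estimates.loc[estimates.tree_id == tree_id, "N_hat"]
        rows.append({
            "tree_id": tree_id,
            "n_years": int(chosen.loc[tree_id, "n_years"]),
            "mean_N": float(chosen.loc[tree_id, "mean_N"]),
            "cv": cv(series),
        })
    return pd.DataFrame(rows)


def per_tree_cv(estimates: pd.DataFrame, min_years: int = 2) -> pd.Series:
    """CV of every tree's estimated population series (NaN if mean is zero)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tree_id, grp in estimates.groupby("tree_id"):
            if len(grp) >= min_years:
                out[tree_id] = cv(grp["N_hat"])
    return pd.Series(out, name="cv")
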