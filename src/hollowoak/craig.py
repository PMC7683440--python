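"""Craig's capture-frequency abundance estimator and the two-tier allocation.

A closed population of ``N`` individuals is trapped through one season; each
individual is caught a Poisson(lambda) number of times.  Observing ``r``
distinct individuals and ``s`` total captures, the maximum-likelihood estimate
of ``N`` solves

    ln N - ln(N - r) = s / N,

which is exactly the zero-truncated-Poisson score equation
``r / N = 1 - exp(-s / N)`` with the capture rate profiled out at
``lambda_hat = s / N``.  The equation has a unique root on ``(r, inf)``
whenever at least one recapture occurred (``s > r``); with no recaptures the
estimate diverges.

Because many tree-years have too few recaptures for a stable per-tree fit,
estimation is two-tier: tree-years with more than ``threshold`` captured
individuals are solved directly; the rest are pooled within each year, Craig's
model is solved on the pooled totals, and the pooled estimate is allocated
back to trees proportionally to their captured individuals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import polygamma

logger = logging.getLogger(__name__)

TIER_DIRECT = "direct_craig"
TIER_POOLED = "pooled_rate"
TIER_ZERO = "zero"


class NoRecaptureError(ValueError):
    """s == r: every individual was caught exactly once, N is unidentifiable."""


@dataclass
class AbundanceEstimate:
    tree_id: object
    season_year: int
    r: int
    s: int
    N_hat: float
    se: float  # NaN unless tier == direct_craig
    tier: str


def _validate_rs(r: int, s: int) -> None:
    if r < 0 or s < 0 or int(r) != r or int(s) != s:
        raise ValueError(f"r and s must be non-negative integers, got r={r}, s={s}")
    if r == 0:
        raise ValueError("r must be >= 1 for Craig's model")
    if s < r:
        raise ValueError(f"total captures s={s} cannot be below individuals r={r}")


def solve_craig(r: int, s: int) -> float:
    """Root N > r of ``ln(N / (N - r)) - s / N = 0``.

    Raises :class:`NoRecaptureError` when ``s == r`` (the root escapes to
    infinity) and ``ValueError`` for invalid counts.
    """
    _validate_rs(r, s)
    if s == r:
        raise NoRecaptureError(
            f"no recaptures (r = s = {r}); population size is unidentifiable"
        )

    # Solve for v = ln(N - r): near-saturated counts (s >> r) push the root
    # exponentially close to r, so the excess N - r is resolved in log space.
    def g(v: float) -> float:
        u = math.exp(v)
        return math.log1p(r / u) - s / (r + u)

    lo = -500.0  # N - r ~ 1e-217, far below any attainable excess
    hi = math.log(2.0 * r + 1.0)
    while g(hi) > 0.0:
        hi += math.log(4.0)
        if hi > 60.0:  # pragma: no cover - unreachable for s > r
            raise RuntimeError("failed to bracket Craig root")
    v = brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
    return r + math.exp(v)


def craig_se(
    r: int,
    s: int,
    N_hat: float | None = None,
    method: str = "bootstrap",
    B: int = 1000,
    seed: int | None = None,
) -> float:
    """Standard error of the Craig estimate.

    ``method='bootstrap'`` (default): parametric bootstrap under the fitted
    Poisson capture model — round(N_hat) individuals are each caught
    Poisson(s / N_hat) times, the estimator re-solved per replicate, and the
    SD of the replicate estimates returned.  ``method='analytic'`` inverts the
    observed information of the (N, lambda) likelihood, with digamma terms for
    the falling-factorial part.
    """
    _validate_rs(r, s)
    if N_hat is None:
        N_hat = solve_craig(r, s)
    lam = s / N_hat

    if method == "analytic":
        # Observed information at the MLE for (N, lambda):
        #   I_NN = psi'(N - r + 1) - psi'(N + 1),  I_Nlam = 1,  I_ll = s / lam^2
        i_nn = float(polygamma(1, N_hat - r + 1.0) - polygamma(1, N_hat + 1.0))
        i_ll = s / lam**2
        det = i_nn * i_ll - 1.0
        if det <= 0:
            raise ValueError("observed information not positive definite")
        return math.sqrt(i_ll / det)

    if method != "bootstrap":
        raise ValueError(f"unknown SE method {method!r}")

    rng = np.random.default_rng(seed)
    n_int = max(int(round(N_hat)), r)
    estimates = []
    for _ in range(B):
        k = rng.poisson(lam, size=n_int)
        r_b = int(np.count_nonzero(k))
        s_b = int(k.sum())
        if r_b == 0 or s_b <= r_b:
            continue  # degenerate replicate carries no information about N
        estimates.append(solve_craig(r_b, s_b))
    if len(estimates) < 2:
        raise ValueError("too few informative bootstrap replicates")
    return float(np.std(estimates, ddof=1))


def summarize_captures(
    records: pd.DataFrame, surveyed: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per tree-year capture summary (r, s) from individual capture records.

    Parameters
    ----------
    records : DataFrame with columns ``season_year``, ``tree_id``,
        ``individual_id`` (one row per capture event).
    surveyed : optional DataFrame ``(tree_id, season_year)`` listing every
        surveyed tree-year; surveyed tree-years with no captures then appear
        with r = s = 0.
    """
    required = {"season_year", "tree_id", "individual_id"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"capture records missing columns: {sorted(missing)}")
    grouped = (
        records.groupby(["tree_id", "season_year"])
        .agg(r=("individual_id", "nunique"), s=("individual_id", "size"))
        .reset_index()
    )
    if surveyed is not None:
        base = surveyed[["tree_id", "season_year"]].drop_duplicates()
        grouped = base.merge(grouped, on=["tree_id", "season_year"], how="left")
        grouped[["r", "s"]] = grouped[["r", "s"]].fillna(0).astype(int)
    return grouped.sort_values(["season_year", "tree_id"]).reset_index(drop=True)


def estimate_all(
    summaries: pd.DataFrame,
    threshold: int = 10,
    pool: str = "small",
    se_method: str = "bootstrap",
    se_B: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-tier population-size estimates for every tree-year.

    Tree-years with ``r > threshold`` are solved directly with Craig's model
    (tier ``direct_craig``, with a standard error).  The remaining tree-years
    with captures are pooled within each year: Craig's model is solved on the
    pooled ``(r, s)``, the ratio ``rate = N_pooled / r_pooled`` computed, and
    each small tree assigned ``N_hat = rate * r`` (tier ``pooled_rate``).
    Tree-years with no captures get ``N_hat = 0`` (tier ``zero``).

    ``pool='all'`` pools every tree-year in the year (not only the small
    ones) when computing the rate; the allocation still applies only to the
    small trees.

    A direct-tier tree-year with no recaptures (s == r) cannot be solved and
    is demoted into the pooled tier with a logged warning.  A year whose
    pooled totals have no recaptures falls back to ``rate = 1``.

    Returns
    -------
    (estimates, yearly) : per-tree-year estimates and yearly totals
        ``(season_year, n_trees, total_captures, total_individuals,
        estimated_total)``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if pool not in ("small", "all"):
        raise ValueError("pool must be 'small' or 'all'")
    required = {"tree_id", "season_year", "r", "s"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    bad = summaries[(summaries.s < summaries.r) | (summaries.r < 0)]
    if len(bad):
        raise ValueError("invalid rows with s < r or r < 0")
    if ((summaries.s == 0) != (summaries.r == 0)).any():
        raise ValueError("s = 0 must coincide with r = 0")

    out: list[AbundanceEstimate] = []
    for year, grp in summaries.groupby("season_year"):
        direct, small = [], []
        for row in grp.itertuples(index=False):
            if row.r > threshold and row.s > row.r:
                direct.append(row)
            elif row.r > threshold:  # saturated-count tree with no recaptures
                logger.warning(
                    "tree %s year %s has r=%d > %d but no recaptures; "
                    "demoted to pooled tier", row.tree_id, year, row.r, threshold,
                )
                small.append(row)
            elif row.r > 0:
                small.append(row)
            else:
                out.append(AbundanceEstimate(row.tree_id, year, 0, 0, 0.0,
                                             float("nan"), TIER_ZERO))
        for row in direct:
            n_hat = solve_craig(row.r, row.s)
            se = craig_se(row.r, row.s, n_hat, method=se_method, B=se_B, seed=seed)
            out.append(AbundanceEstimate(row.tree_id, year, row.r, row.s,
                                         n_hat, se, TIER_DIRECT))
        if small:
            if pool == "all":
                pool_rows = direct + small
            else:
                pool_rows = small
            r_pool = sum(t.r for t in pool_rows)
            s_pool = sum(t.s for t in pool_rows)
            if s_pool > r_pool:
                rate = solve_craig(r_pool, s_pool) / r_pool
            else:
                logger.warning(
                    "year %s: pooled counts have no recaptures; using rate = 1", year
                )
                rate = 1.0
            for row in small:
                out.append(AbundanceEstimate(row.tree_id, year, row.r, row.s,
                                             rate * row.r, float("nan"), TIER_POOLED))

    est = pd.DataFrame([vars(e) for e in out]).sort_values(
        ["season_year", "tree_id"]).reset_index(drop=True)
    yearly = (
        est.groupby("season_year")
        .agg(n_trees=("tree_id", "size"), total_captures=("s", "sum"),
             total_individuals=("r", "sum"), estimated_total=("N_hat", "sum"))
        .reset_index()
    )
    return est, yearly
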