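"""AICc habitat-model selection for colonisation and extinction probabilities.

The response is per-tree binary: whether a colonisation (or extinction) was
ever observed among the years at which it was possible to observe one.  Trees
are repeated observation units, so every model is a binomial logistic
regression with a per-tree random intercept; its marginal likelihood is
integrated over the random effect by Gauss-Hermite quadrature.

Selection is two-stage, appropriate when N / (number of predictors) < 40:

1. univariable screen — every variable whose single-variable model has a
   lower AICc than the null (intercept-only) model is retained;
2. all-subsets ranking — every combination of retained variables, each fitted
   together with the exposure covariate (number of possible occasions), ranked
   by AICc with Akaike weights and McFadden pseudo-R2; models with
   delta AICc < 2 are the plausible set.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from numpy.polynomial.hermite_e import hermegauss

logger = logging.getLogger(__name__)


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order (small-sample) Akaike information criterion.

    ``AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)``; undefined (infinite) when
    ``n <= k + 1``.
    """
    if n <= k + 1:
        warnings.warn(f"AICc undefined for n={n}, k={k}", stacklevel=2)
        return float("inf")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class GLMMFit:
    """A fitted random-intercept logistic model."""

    variables: tuple[str, ...]
    loglik: float
    k: int                      # fixed effects + intercept + RE variance
    coefficients: dict          # on the original predictor scale
    sigma: float                # random-intercept SD
    converged: bool
    collapsed: bool             # variance hit zero -> plain logistic fit
    n: int


def _marginal_loglik(eta, y, starts, sigma, nodes, log_weights):
    """Marginal log-likelihood, rows pre-sorted by group.

    For each group the Bernoulli log-likelihood is evaluated at every
    quadrature node ``b = sigma * t`` and integrated against the N(0, 1)
    measure; ``starts`` are the first-row indices of the groups.
    """
    lin = eta[:, None] + sigma * nodes[None, :]
    sign = np.where(y == 1, -1.0, 1.0)
    logp = -np.logaddexp(0.0, sign[:, None] * lin)  # (n, q)
    per_group = np.add.reduceat(logp, starts, axis=0)  # (G, q)
    return float(logsumexp(per_group + log_weights[None, :], axis=1).sum())


def fit_binomial_random_intercept(
    data: pd.DataFrame,
    variables,
    outcome: str = "outcome",
    group: str = "tree_id",
    fix_variance: float | None = None,
    n_quad: int = 25,
) -> GLMMFit:
    """ML fit of a logistic regression with a per-tree random intercept.

    Predictors are standardised internally for optimiser stability and the
    coefficients mapped back to the original scale.  ``fix_variance`` pins the
    random-intercept variance (0 gives a plain logistic regression, an oracle
    cross-check).  The parameter count ``k`` is ``len(variables) + 2``
    (intercept and the variance component) regardless of whether the variance
    estimate collapsed to zero.

    Raises ``ValueError`` when the outcome has a single class.  Apparent
    separation or optimiser failure is reported via ``converged=False``.
    """
    variables = tuple(variables)
    cols = [outcome, group, *variables]
    sub = data[cols].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; model not estimable")
    # sort rows by group so the quadrature can segment-sum with reduceat
    sub = sub.sort_values(group, kind="mergesort")
    y = sub[outcome].to_numpy(dtype=float)
    groups = sub[group].to_numpy()
    starts = np.flatnonzero(
        np.r_[True, groups[1:] != groups[:-1]]
    )
    n = len(sub)
    k = len(variables) + 2

    x_raw = sub[list(variables)].to_numpy(dtype=float) if variables else \
        np.empty((n, 0))
    mu = x_raw.mean(axis=0) if x_raw.size else np.zeros(0)
    sd = x_raw.std(axis=0) if x_raw.size else np.zeros(0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (x_raw - mu) / sd
    design = np.column_stack([np.ones(n), x])

    nodes, ghw = hermegauss(n_quad)          # probabilists' Hermite: weight e^{-t^2/2}
    log_ghw = np.log(ghw / math.sqrt(2.0 * math.pi))  # N(0,1) measure
    sign = np.where(y == 1, -1.0, 1.0)

    def negloglik_beta(beta, sigma):
        eta = design @ beta
        if sigma < 1e-8:
            return float(np.logaddexp(0.0, sign * eta).sum())
        return -_marginal_loglik(eta, y, starts, sigma, nodes, log_ghw)

    beta0 = np.zeros(design.shape[1])
    beta0[0] = math.log(y.mean() / (1.0 - y.mean()))

    def profile(sigma, start):
        res = minimize(negloglik_beta, start, args=(sigma,), method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-8})
        return res

    if fix_variance is not None:
        best = profile(math.sqrt(fix_variance), beta0)
        sigma, collapsed = math.sqrt(fix_variance), False
    else:
        # The profile likelihood over sigma is smooth but can be nearly flat
        # (e.g. one observation per tree, where sigma and beta trade off), so
        # sigma is profiled on a bounded grid with warm starts and refined
        # locally; ties within 1e-4 log-units collapse to sigma = 0.
        zero_fit = profile(0.0, beta0)
        sigmas = np.concatenate([[0.0], np.exp(np.linspace(-3.0, 1.8, 13))])
        fits, start = [], zero_fit.x
        for sg in sigmas:
            res = profile(sg, start)
            fits.append(res)
            start = res.x
        nlls = np.array([f.fun for f in fits])
        i = int(np.argmin(nlls))
        # golden-ish local refinement between the neighbours of the best node
        lo = sigmas[max(i - 1, 0)]
        hi = sigmas[min(i + 1, len(sigmas) - 1)]
        sigma, best = sigmas[i], fits[i]
        for sg in np.linspace(lo, hi, 7)[1:-1]:
            res = profile(sg, best.x)
            if res.fun < best.fun - 1e-10:
                sigma, best = sg, res
        collapsed = False
        if best.fun >= zero_fit.fun - 1e-4:
            sigma, best, collapsed = 0.0, zero_fit, True
            logger.info("random-intercept variance collapsed to ~0; "
                        "fit equals plain logistic regression")

    beta_std = best.x
    converged = bool(np.isfinite(best.fun)) and np.all(np.abs(beta_std) < 50.0)

    # map standardised coefficients back to the data scale
    coefs = {}
    intercept = beta_std[0]
    for j, v in enumerate(variables):
        coefs[v] = beta_std[j + 1] / sd[j]
        intercept -= beta_std[j + 1] * mu[j] / sd[j]
    coefs["(Intercept)"] = intercept

    return GLMMFit(variables=variables, loglik=-float(best.fun), k=k,
                   coefficients=coefs, sigma=float(sigma),
                   converged=converged, collapsed=collapsed, n=n)


def univariable_screen(
    data: pd.DataFrame, variables, outcome: str = "outcome",
    group: str = "tree_id",
) -> list[str]:
    """Variables whose single-variable model beats the null model on AICc."""
    variables = list(variables)
    if not variables:
        raise ValueError("at least one candidate variable required")
    null = fit_binomial_random_intercept(data, (), outcome=outcome, group=group)
    aicc_null = aicc(null.loglik, null.k, null.n)
    selected = []
    for v in variables:
        try:
            fit = fit_binomial_random_intercept(data, (v,), outcome=outcome,
                                                group=group)
        except ValueError as exc:
            logger.warning("variable %s failed to fit (%s); not selected", v, exc)
            continue
        if not fit.converged:
            logger.warning("variable %s did not converge; not selected", v)
            continue
        if aicc(fit.loglik, fit.k, fit.n) < aicc_null:
            selected.append(v)
    return selected


@dataclass
class CandidateModel:
    variables: tuple[str, ...]
    k: int
    loglik: float
    aicc: float
    delta: float
    weight: float
    r2_mcfadden: float
    coefficients: dict
    plausible: bool


def all_subsets_rank(
    data: pd.DataFrame,
    selected,
    covariate: str | None = "n_possible_occasions",
    outcome: str = "outcome",
    group: str = "tree_id",
    max_variables: int = 20,
) -> list[CandidateModel]:
    """Fit and rank every subset of the screened variables.

    Each subset is fitted together with the exposure ``covariate``; Akaike
    weights are normalised over all converged candidate models, and McFadden's
    R2 is computed against the intercept-only model.  Ties in AICc break by
    smaller k, then lexicographic variable names.
    """
    selected = list(selected)
    if len(selected) > max_variables:
        raise ValueError(
            f"{len(selected)} selected variables would need "
            f"{2 ** len(selected)} model fits; refusing (max {max_variables})"
        )
    null = fit_binomial_random_intercept(data, (), outcome=outcome, group=group)

    fits: list[GLMMFit] = []
    for size in range(len(selected) + 1):
        for combo in itertools.combinations(selected, size):
            vars_ = tuple(combo) + ((covariate,) if covariate else ())
            try:
                fit = fit_binomial_random_intercept(
                    data, vars_, outcome=outcome, group=group)
            except ValueError as exc:
                logger.warning("subset %s failed (%s); excluded", vars_, exc)
                continue
            if not fit.converged:
                logger.warning("subset %s did not converge; excluded", vars_)
                continue
            fits.append(fit)
    if not fits:
        raise ValueError("no candidate model could be fitted")

    scores = [aicc(f.loglik, f.k, f.n) for f in fits]
    order = sorted(
        range(len(fits)),
        key=lambda i: (scores[i], fits[i].k, tuple(sorted(fits[i].variables))),
    )
    best = scores[order[0]]
    deltas = [scores[i] - best for i in order]
    rel = np.exp(-0.5 * np.asarray(deltas))
    weights = rel / rel.sum()

    out = []
    for rank, i in enumerate(order):
        f = fits[i]
        out.append(CandidateModel(
            variables=f.variables, k=f.k, loglik=f.loglik, aicc=scores[i],
            delta=float(deltas[rank]), weight=float(weights[rank]),
            r2_mcfadden=1.0 - f.loglik / null.loglik,
            coefficients=f.coefficients, plausible=deltas[rank] < 2.0,
        ))
    return out


def rank_table(models: list[CandidateModel]) -> pd.DataFrame:
    """Model-selection table: variables, k, logLik, AICc, delta, weight, R2."""
    return pd.DataFrame([{
        "variables": "+".join(m.variables) if m.variables else "(null)",
        "k": m.k, "logLik": m.loglik, "AICc": m.aicc, "delta_AICc": m.delta,
        "weight": m.weight, "r2_mcfadden": m.r2_mcfadden,
        "plausible": m.plausible,
    } for m in models])


def build_model_data(
    timelines, trees: pd.DataFrame, event_kind: str = "colonisation"
) -> pd.DataFrame:
    """Per-tree binary outcomes for the habitat models.

    For ``event_kind='colonisation'`` a tree enters with outcome 1 if any
    colonisation was observed and 0 if at least one colonisation occasion
    existed but none was observed; trees with no occasions are excluded.
    ``n_possible_occasions`` is the per-tree occasion count, the exposure
    covariate.  Habitat variables are joined from the ``trees`` table.
    """
    if event_kind not in ("colonisation", "extinction"):
        raise ValueError(f"unknown event kind {event_kind!r}")
    rows = []
    for t in timelines:
        if event_kind == "colonisation":
            occasions = sum(t.colonisation_possible)
        else:
            occasions = sum(t.extinction_possible)
        if occasions == 0:
            continue
        observed = any(e.kind == event_kind for e in t.observable_events())
        rows.append({"tree_id": t.tree_id, "outcome": int(observed),
                     "n_possible_occasions": occasions})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError(f"no trees with {event_kind} occasions")
    return out.merge(trees, on="tree_id", how="left")
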