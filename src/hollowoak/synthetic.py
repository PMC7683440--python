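"""Synthetic hollow-oak metapopulation and pitfall-trapping simulator.

Generates the kind of data a multi-decade capture-mark-recapture survey of a
tree-hollow beetle produces: a clustered landscape of hollow oaks, slow tree
demography (death and fall), colonisation/extinction dynamics of local beetle
populations, heavy-tailed within-tree adult abundances, and a per-individual
Poisson trapping process within each July-August season.

The capture model is per-individual Poisson with a common seasonal rate
``lambda``; under that model Craig's equation is exactly the maximum-
likelihood estimator of local abundance, so simulator output doubles as an
internal consistency oracle for the estimation modules.

Defaults are calibrated to the study system the package emulates: ~70 trees
in two sub-areas over 13 survey seasons spanning 25 years, annual tree
mortality ~1.1% and fall ~0.4%, realised colonisation and extinction
frequencies of a few percent per year, and per-tree adult abundances ranging
from 0 to ~100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import DEFAULT_ALPHA, connectivity

#: survey calendar: annual at first, then increasingly sparse
DEFAULT_SURVEY_YEARS = (
    1995, 1996, 1997, 1998, 1999, 2000, 2001, 2002, 2005, 2006, 2008, 2015, 2019,
)


@dataclass
class SimulationParams:
    """Knobs of the synthetic metapopulation; defaults are the study conditions."""

    n_trees: int = 70
    extent_m: float = 1500.0
    survey_years: tuple[int, ...] = DEFAULT_SURVEY_YEARS
    mortality_per_year: float = 0.011
    fall_per_year: float = 0.004
    colonisation_base: float = 0.15   # scaled down by relative connectivity
    extinction_base: float = 0.05
    dead_extinction_multiplier: float = 3.0
    carrying_capacity_scale: float = 8.0  # median adults in an occupied tree
    abundance_sigma: float = 1.0          # log-scale SD of the abundance law
    abundance_rho: float = 0.7            # AR(1) persistence of log abundance
    initial_occupancy: float = 0.5
    min_adults: int = 1
    capture_rate_lambda: float = 1.25     # expected captures per adult per season
    n_sessions: int = 20                  # trap-emptying visits per season
    early_subset_fraction: float = 0.3    # share of trees surveyed at first
    n_early_years: int = 3                # survey years using the early subset
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.extent_m <= 0:
            raise ValueError("extent_m must be positive")
        for name in ("mortality_per_year", "fall_per_year", "colonisation_base",
                     "extinction_base", "initial_occupancy",
                     "early_subset_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.capture_rate_lambda <= 0:
            raise ValueError("capture_rate_lambda must be > 0")
        if self.carrying_capacity_scale <= 0:
            raise ValueError("carrying_capacity_scale must be > 0")
        if any(b <= a for a, b in zip(self.survey_years, self.survey_years[1:])):
            raise ValueError("survey_years must be strictly increasing")
        if self.min_adults < 1:
            raise ValueError("min_adults must be >= 1")


@dataclass
class TrueState:
    """Ground truth of one simulated run (trees x calendar years)."""

    tree_ids: list
    years: list[int]           # every calendar year from first to last survey
    occupied: np.ndarray       # bool (n_trees, n_years)
    n_adults: np.ndarray       # int  (n_trees, n_years)
    alive: np.ndarray          # bool (n_trees, n_years)
    fallen: np.ndarray         # bool (n_trees, n_years)
    events: pd.DataFrame       # columns: year, tree_id, event
    surveyed: pd.DataFrame     # columns: tree_id, season_year

    def year_index(self, year: int) -> int:
        return self.years.index(year)


def generate_landscape(params: SimulationParams) -> pd.DataFrame:
    """Clustered tree landscape with habitat attributes.

    Trees fall around two cluster centres (two sub-areas of high hollow-oak
    density), coordinates clipped to the square [0, extent]^2.  Habitat
    attributes are drawn on the scales typical of veteran-oak surveys.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    n = params.n_trees
    ext = params.extent_m
    centres = np.array([[0.30, 0.55], [0.72, 0.40]]) * ext
    assign = rng.random(n) < 0.6
    idx = np.where(assign, 0, 1)
    coords = centres[idx] + rng.normal(0.0, ext / 8.0, size=(n, 2))
    coords = np.clip(coords, 0.0, ext)

    wood_mould = np.round(np.exp(rng.normal(np.log(20.0), 1.0, n)), 1)
    df = pd.DataFrame({
        "tree_id": [f"T{i:03d}" for i in range(n)],
        "x_m": coords[:, 0],
        "y_m": coords[:, 1],
        "area_label": np.where(idx == 0, "A", "B"),
        "canopy_class": rng.integers(0, 3, n),
        "entrance_direction_deg": rng.uniform(0.0, 360.0, n),
        "entrance_height_cm": np.round(rng.uniform(30.0, 450.0, n), 0),
        "entrance_size_cm2": np.round(np.exp(rng.normal(np.log(80.0), 0.8, n)), 1),
        "age_years": np.round(rng.normal(250.0, 60.0, n).clip(120.0), 0),
        "diameter_cm": np.round(rng.normal(100.0, 25.0, n).clip(40.0), 1),
        "wood_mould_dm3": wood_mould,
    })
    return df


def simulate_dynamics(trees: pd.DataFrame, params: SimulationParams) -> TrueState:
    """Annual tree demography and local-population turnover.

    Each calendar year: live trees die with probability ``mortality_per_year``
    and standing trees fall with probability ``fall_per_year``; each occupied
    tree goes extinct with probability ``extinction_base`` (multiplied for
    dead/fallen trees, habitat decay raising extinction risk); each empty
    *living* tree is colonised with probability
    ``colonisation_base * S_i / max(S)``, connectivity computed from the
    previous year's adult numbers.  Occupied trees carry a log-normal AR(1)
    abundance, rounded and truncated to at least ``min_adults``.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    years = list(range(min(params.survey_years), max(params.survey_years) + 1))
    n, t = len(trees), len(years)
    ids = trees["tree_id"].tolist()

    occupied = np.zeros((n, t), dtype=bool)
    n_adults = np.zeros((n, t), dtype=int)
    alive = np.zeros((n, t), dtype=bool)
    fallen = np.zeros((n, t), dtype=bool)
    log_ab = np.zeros(n)  # latent log abundance of occupied trees
    mu = np.log(params.carrying_capacity_scale)
    events: list[dict] = []

    # initial year
    alive[:, 0] = True
    occupied[:, 0] = rng.random(n) < params.initial_occupancy
    log_ab[occupied[:, 0]] = rng.normal(mu, params.abundance_sigma,
                                        occupied[:, 0].sum())
    n_adults[occupied[:, 0], 0] = np.maximum(
        params.min_adults, np.round(np.exp(log_ab[occupied[:, 0]]))
    ).astype(int)

    for k in range(1, t):
        year = years[k]
        # tree demography
        alive[:, k] = alive[:, k - 1] & (rng.random(n) >= params.mortality_per_year)
        fallen[:, k] = fallen[:, k - 1] | (rng.random(n) < params.fall_per_year)

        # extinction of occupied populations
        p_ext = np.full(n, params.extinction_base)
        degraded = ~alive[:, k] | fallen[:, k]
        p_ext[degraded] = np.minimum(
            1.0, params.extinction_base * params.dead_extinction_multiplier
        )
        goes_extinct = occupied[:, k - 1] & (rng.random(n) < p_ext)

        # colonisation of empty living standing trees, scaled by connectivity
        prev_p = pd.Series(n_adults[:, k - 1].astype(float), index=ids)
        s = connectivity(trees, prev_p, alpha=DEFAULT_ALPHA)["S_i"].to_numpy()
        smax = s.max()
        p_col = (params.colonisation_base * s / smax) if smax > 0 else np.zeros(n)
        colonisable = ~occupied[:, k - 1] & alive[:, k] & ~fallen[:, k]
        colonised = colonisable & (rng.random(n) < p_col)

        occupied[:, k] = (occupied[:, k - 1] & ~goes_extinct) | colonised
        for i in np.where(goes_extinct)[0]:
            events.append({"year": year, "tree_id": ids[i], "event": "extinction"})
        for i in np.where(colonised)[0]:
            events.append({"year": year, "tree_id": ids[i], "event": "colonisation"})

        # abundance: AR(1) on the log scale for survivors, fresh draw on arrival
        surv = occupied[:, k] & occupied[:, k - 1]
        log_ab[surv] = (
            params.abundance_rho * log_ab[surv]
            + (1.0 - params.abundance_rho) * mu
            + rng.normal(0.0, params.abundance_sigma
                         * np.sqrt(1.0 - params.abundance_rho ** 2), surv.sum())
        )
        log_ab[colonised] = rng.normal(mu, params.abundance_sigma, colonised.sum())
        n_adults[:, k] = 0
        occ = occupied[:, k]
        n_adults[occ, k] = np.maximum(
            params.min_adults, np.round(np.exp(log_ab[occ]))
        ).astype(int)

    # survey design: an early core subset, then the full tree set
    rng_design = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    n_early = max(1, int(round(params.early_subset_fraction * n)))
    early = set(rng_design.choice(n, size=n_early, replace=False))
    surveyed_rows = []
    for j, year in enumerate(params.survey_years):
        for i in range(n):
            if j < params.n_early_years and i not in early:
                continue
            surveyed_rows.append({"tree_id": ids[i], "season_year": year})

    return TrueState(
        tree_ids=ids, years=years, occupied=occupied, n_adults=n_adults,
        alive=alive, fallen=fallen,
        events=pd.DataFrame(events, columns=["year", "tree_id", "event"]),
        surveyed=pd.DataFrame(surveyed_rows, columns=["tree_id", "season_year"]),
    )


def simulate_capture_season(
    state: TrueState, params: SimulationParams, noiseless: bool = False
) -> pd.DataFrame:
    """Per-individual Poisson trapping across all survey seasons.

    Every adult present in a surveyed tree-year is caught ``k ~ Poisson(lambda)``
    times; adults with ``k = 0`` leave no record.  Captures are spread over
    trap-emptying sessions.  With ``noiseless=True`` every adult is caught
    exactly twice (perfect detection, useful as ground-truth observation).

    Returns a DataFrame with columns ``season_year, session, tree_id,
    individual_id`` — one row per capture event.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    surveyed = state.surveyed
    records: list[dict] = []
    for row in surveyed.itertuples(index=False):
        i = state.tree_ids.index(row.tree_id)
        k_year = state.year_index(row.season_year)
        n_ad = int(state.n_adults[i, k_year])
        if n_ad == 0:
            continue
        if noiseless:
            kvec = np.full(n_ad, 2)
        else:
            kvec = rng.poisson(params.capture_rate_lambda, size=n_ad)
        for a, k in enumerate(kvec):
            if k == 0:
                continue
            sessions = np.sort(rng.integers(0, params.n_sessions, size=k))
            ind = f"{row.tree_id}-{row.season_year}-{a:04d}"
            for sess in sessions:
                records.append({
                    "season_year": row.season_year, "session": int(sess),
                    "tree_id": row.tree_id, "individual_id": ind,
                })
    return pd.DataFrame(
        records, columns=["season_year", "session", "tree_id", "individual_id"]
    )


def simulate(params: SimulationParams, noiseless: bool = False):
    """Full simulator run: landscape, dynamics, captures.

    Returns ``(trees, state, records)``.
    """
    trees = generate_landscape(params)
    state = simulate_dynamics(trees, params)
    records = simulate_capture_season(state, params, noiseless=noiseless)
    return trees, state, records


def true_counts(state: TrueState) -> pd.DataFrame:
    """Perfect-detection per-tree-year adult counts at surveyed years."""
    rows = []
    for row in state.surveyed.itertuples(index=False):
        i = state.tree_ids.index(row.tree_id)
        rows.append({
            "tree_id": row.tree_id, "season_year": row.season_year,
            "r": int(state.n_adults[i, state.year_index(row.season_year)]),
        })
    return pd.DataFrame(rows)
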