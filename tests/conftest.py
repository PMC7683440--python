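import numpy as np
import pandas as pd
import pytest

import hollowoak as h


@pytest.fixture
def small_params():
    """A fast simulator configuration for smoke-level tests."""
    return h.SimulationParams(n_trees=25, survey_years=tuple(range(1995, 2003)),
                              seed=11)


@pytest.fixture
def default_run():
    """One full default-condition simulator run with capture summaries."""
    params = h.SimulationParams(seed=5)
    trees, state, records = h.simulate(params)
    counts = h.summarize_captures(records, state.surveyed)
    return params, trees, state, records, counts


def make_true_state(n_adults_matrix, years, tree_ids=None):
    """Hand-build a TrueState from an adults matrix (trees x years)."""
    n_adults = np.asarray(n_adults_matrix, dtype=int)
    n, t = n_adults.shape
    tree_ids = list(tree_ids) if tree_ids is not None else [f"T{i}" for i in range(n)]
    surveyed = pd.DataFrame(
        [{"tree_id": tid, "season_year": y} for tid in tree_ids for y in years]
    )
    return h.TrueState(
        tree_ids=tree_ids, years=list(years),
        occupied=n_adults > 0, n_adults=n_adults,
        alive=np.ones((n, t), dtype=bool), fallen=np.zeros((n, t), dtype=bool),
        events=pd.DataFrame(columns=["year", "tree_id", "event"]),
        surveyed=surveyed,
    )
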