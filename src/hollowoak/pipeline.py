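"""End-to-end pipeline: simulate -> estimate -> turnover -> connectivity ->
summaries -> model selection, with CSV file contracts and a run manifest.

All interchange files are UTF-8 CSV with a header row; every output carries a
``# seed=N`` comment line so a run can be re-identified, and readers therefore
use ``comment='#'``.  A stage failure aborts with a stage-tagged error and the
offending stage's partial output is kept under a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import craig, model_selection, summaries, synthetic, turnover
from .landscape import DEFAULT_ALPHA, connectivity
from .turnover import VARIANTS

logger = logging.getLogger(__name__)

CAPTURE_COLUMNS = ["season_year", "session", "tree_id", "individual_id"]
TREE_COLUMNS = ["tree_id", "x_m", "y_m"]

#: habitat variables offered to the model-selection stage
HABITAT_VARIABLES = [
    "canopy_class", "entrance_height_cm", "entrance_size_cm2",
    "age_years", "diameter_cm", "wood_mould_dm3", "S_i",
]


class SchemaError(ValueError):
    """An input table does not match its column contract."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{name}: ignoring unknown column(s) {extra}", stacklevel=2)


@dataclass
class PipelineConfig:
    out_dir: str = "hollowoak_out"
    captures_path: str | None = None   # None -> simulate
    trees_path: str | None = None
    seed: int = 0
    variant: str = "main_3seq"
    threshold: int = 10
    pool: str = "small"
    alpha: float = DEFAULT_ALPHA
    se_method: str = "analytic"
    run_model_selection: bool = True
    date_extinction_to_run_start: bool = False
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise SchemaError(
                f"config: unknown variant {self.variant!r}; "
                f"expected one of {sorted(VARIANTS)}"
            )
        if self.captures_path is not None and not Path(self.captures_path).exists():
            raise SchemaError(f"config: captures_path {self.captures_path} not found")
        if self.trees_path is not None and not Path(self.trees_path).exists():
            raise SchemaError(f"config: trees_path {self.trees_path} not found")


def write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    """Write a CSV with a seed-stamped comment header, atomically."""
    tmp = path.with_suffix(path.suffix + ".partial")
    with open(tmp, "w", newline="") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
    tmp.rename(path)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _load_inputs(config: PipelineConfig):
    if config.captures_path is None:
        params = synthetic.SimulationParams(seed=config.seed, **config.simulation)
        trees, state, records = synthetic.simulate(params)
        surveyed = state.surveyed
    else:
        records = read_csv(config.captures_path)
        require_columns(records, CAPTURE_COLUMNS, "captures")
        trees = None
        if config.trees_path is not None:
            trees = read_csv(config.trees_path)
            missing = [c for c in TREE_COLUMNS if c not in trees.columns]
            if missing:
                raise SchemaError(f"trees: missing required column(s) {missing}")
        surveyed = records[["tree_id", "season_year"]].drop_duplicates()
        state = None
    return trees, state, records, surveyed


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory.

    Outputs: ``captures.csv, trees.csv, estimates.csv, yearly_summary.csv,
    timelines.csv, rates.csv, connectivity.csv, cv_report.csv,
    model_selection_{colonisation,extinction}.csv, manifest.json``.
    Idempotent for a fixed config and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variant = VARIANTS[config.variant]
    manifest: dict = {
        "seed": config.seed,
        "variant": config.variant,
        "threshold": config.threshold,
        "pool": config.pool,
        "alpha": config.alpha,
        "date_extinction_to_run_start": config.date_extinction_to_run_start,
        "stages": {},
    }

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc
        logger.info("stage %s complete", name)
        return result

    trees, state, records, surveyed = stage(
        "simulate" if config.captures_path is None else "load",
        lambda: _load_inputs(config),
    )
    write_csv(records, out / "captures.csv", config.seed)
    if trees is not None:
        write_csv(trees, out / "trees.csv", config.seed)
    manifest["stages"]["captures"] = len(records)

    def _estimate():
        counts = craig.summarize_captures(records, surveyed)
        est, yearly = craig.estimate_all(
            counts, threshold=config.threshold, pool=config.pool,
            se_method=config.se_method, seed=config.seed,
        )
        return counts, est, yearly

    counts, estimates, yearly = stage("estimate", _estimate)
    write_csv(estimates, out / "estimates.csv", config.seed)
    manifest["stages"]["estimates"] = len(estimates)

    timelines = stage(
        "turnover",
        lambda: turnover.build_timelines(
            counts, variant, config.date_extinction_to_run_start),
    )
    rates = turnover.annual_rates(timelines, variant)
    write_csv(turnover.timelines_to_frame(timelines),
              out / "timelines.csv", config.seed)
    write_csv(rates.per_year, out / "rates.csv", config.seed)
    manifest["stages"]["timelines"] = sum(len(t.years) for t in timelines)
    manifest["colonisation_rate"] = rates.colonisation_rate
    manifest["extinction_rate"] = rates.extinction_rate

    conn = None
    if trees is not None:
        def _connectivity():
            p = estimates.groupby("tree_id")["N_hat"].mean()
            return connectivity(trees, p, alpha=config.alpha)

        conn = stage("connectivity", _connectivity)
        write_csv(conn, out / "connectivity.csv", config.seed)
        manifest["stages"]["connectivity"] = len(conn)

    def _summaries():
        ys = summaries.yearly_summary(estimates)
        tree_cv = summaries.per_tree_cv(estimates)
        top = summaries.top_tree_cv(estimates)
        return ys, tree_cv, top

    ys, tree_cv, top = stage("summaries", _summaries)
    write_csv(ys, out / "yearly_summary.csv", config.seed)
    cv_report = pd.DataFrame({
        "statistic": ["cv_yearly_average", "mean_per_tree_cv", "mean_top_tree_cv"],
        "value": [
            summaries.cv(ys.avg_per_tree),
            float(tree_cv.mean()),
            float(top.cv.mean()) if len(top) else float("nan"),
        ],
    })
    write_csv(cv_report, out / "cv_report.csv", config.seed)
    manifest["stages"]["yearly_summary"] = len(ys)

    if config.run_model_selection and trees is not None and conn is not None:
        tree_table = trees.merge(conn, on="tree_id")
        for kind in ("colonisation", "extinction"):
            def _select(kind=kind):
                data = model_selection.build_model_data(timelines, tree_table, kind)
                usable = [v for v in HABITAT_VARIABLES if v in data.columns]
                chosen = model_selection.univariable_screen(data, usable)
                ranked = model_selection.all_subsets_rank(data, chosen)
                return model_selection.rank_table(ranked)

            try:
                table = stage(f"select-models-{kind}", _select)
            except PipelineError as exc:
                # single-class outcomes are a property of the data, not a bug
                logger.warning("model selection for %s skipped: %s", kind, exc)
                continue
            write_csv(table, out / f"model_selection_{kind}.csv", config.seed)
            manifest["stages"][f"model_selection_{kind}"] = len(table)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
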