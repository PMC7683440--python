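"""Colonisation/extinction inference from yearly adult counts.

Adults of wood-mould beetles are an imperfect indicator of a local population:
larvae live hidden for 3-4 years, and the odd adult may be an immigrant that
never bred.  The rules here encode that biology:

* a year with >= 3 adults is a presence observation;
* a year with 0 adults is an absence observation, but the population is only
  *declared* absent after ``absence_run`` sequential absence observations;
* a year with 1-2 adults carries the previous effective status forward (the
  first surveyed year carries the next resolvable status backward) and
  neither extends nor resets an ongoing absence run.

"Sequential" means sequential *surveyed* years by default, even across
calendar gaps; the strict annual variant additionally requires the absence
observations to fall in consecutive calendar years and discards runs broken
by survey gaps.

Colonisations are dated to the first qualifying presence year; extinctions to
the year completing the absence run (optionally to the first year of the
run).  Rates are events divided by "possible occasions": surveyed tree-years
whose entering effective status allowed the event to be observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATUS_PRESENT = "present"
STATUS_ABSENT = "absent"
STATUS_CARRIED_PRESENT = "carried_present"
STATUS_CARRIED_ABSENT = "carried_absent"
STATUS_UNDETERMINED = "undetermined"

COLONISATION = "colonisation"
EXTINCTION = "extinction"

PRESENCE_MIN_ADULTS = 3  # >= this many adults in a year counts as presence


@dataclass(frozen=True)
class RuleVariant:
    """How many sequential absence observations declare an extinction."""

    name: str
    absence_run: int
    require_annual: bool = False

    def __post_init__(self) -> None:
        if self.absence_run < 1:
            raise ValueError("absence_run must be >= 1")


#: the main rule plus its sensitivity variants
VARIANTS: dict[str, RuleVariant] = {
    "main_3seq": RuleVariant("main_3seq", 3, False),
    "absence_1yr": RuleVariant("absence_1yr", 1, False),
    "absence_2yr": RuleVariant("absence_2yr", 2, False),
    "absence_3consecutive_annual": RuleVariant("absence_3consecutive_annual", 3, True),
}


@dataclass
class Event:
    year: int
    kind: str  # colonisation | extinction
    observable: bool = True  # False when the annual variant loses the occasion


@dataclass
class OccupancyTimeline:
    """Inferred presence history of one tree across its surveyed years."""

    tree_id: object
    years: list[int]
    counts: list[int]
    status: list[str]
    entering: list[str]  # effective status entering each surveyed year
    events: list[Event]
    colonisation_possible: list[bool]
    extinction_possible: list[bool]

    def observable_events(self) -> list[Event]:
        return [e for e in self.events if e.observable]


def _observation(count: int) -> str:
    if count < 0:
        raise ValueError(f"adult counts must be >= 0, got {count}")
    if count >= PRESENCE_MIN_ADULTS:
        return "P"
    if count == 0:
        return "A"
    return "C"


def build_timeline(
    tree_id,
    years,
    counts,
    variant: RuleVariant,
    date_extinction_to_run_start: bool = False,
) -> OccupancyTimeline:
    """Run the presence/absence state machine over one tree's counts.

    ``years`` are the calendar years in which this tree was surveyed (strictly
    increasing); ``counts`` the adults captured in each.
    """
    years = [int(y) for y in years]
    counts = [int(c) for c in counts]
    if len(years) != len(counts):
        raise ValueError("years and counts must be the same length")
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError("survey years must be strictly increasing")
    obs = [_observation(c) for c in counts]

    # Initial effective status: first non-carried observation, searched
    # forward (a leading run of 1-2 counts borrows the next resolvable year).
    initial = None
    for o in obs:
        if o == "P":
            initial = STATUS_PRESENT
            break
        if o == "A":
            initial = STATUS_ABSENT
            break

    n = len(years)
    if initial is None:  # nothing but 1-2 counts (or no surveys at all)
        return OccupancyTimeline(
            tree_id, years, counts, [STATUS_UNDETERMINED] * n,
            [STATUS_UNDETERMINED] * n, [], [False] * n, [False] * n,
        )

    status: list[str] = []
    entering: list[str] = []
    events: list[Event] = []
    state = initial
    run = 0
    run_start_year: int | None = None
    last_absence_year: int | None = None

    for i, (year, o) in enumerate(zip(years, obs)):
        entering.append(state)
        if o == "P":
            status.append(STATUS_PRESENT)
            if state == STATUS_ABSENT:
                observable = True
                if variant.require_annual and i > 0 and years[i - 1] != year - 1:
                    observable = False  # gap year: transition seen, occasion lost
                events.append(Event(year, COLONISATION, observable))
            state = STATUS_PRESENT
            run = 0
            run_start_year = None
            last_absence_year = None
        elif o == "A":
            status.append(STATUS_ABSENT)
            if state == STATUS_PRESENT:
                if (
                    variant.require_annual
                    and run > 0
                    and last_absence_year is not None
                    and year != last_absence_year + 1
                ):
                    run = 0  # run broken by a calendar gap: discard it
                    run_start_year = None
                if run == 0:
                    run_start_year = year
                run += 1
                last_absence_year = year
                if run >= variant.absence_run:
                    when = run_start_year if date_extinction_to_run_start else year
                    events.append(Event(when, EXTINCTION, True))
                    state = STATUS_ABSENT
                    run = 0
                    run_start_year = None
                    last_absence_year = None
        else:  # 1-2 adults: carry, leave any absence run untouched
            status.append(
                STATUS_CARRIED_PRESENT if state == STATUS_PRESENT
                else STATUS_CARRIED_ABSENT
            )

    col_possible: list[bool] = []
    ext_possible: list[bool] = []
    for i, year in enumerate(years):
        if entering[i] == STATUS_ABSENT:
            ok = True
            if variant.require_annual and i > 0 and years[i - 1] != year - 1:
                ok = False
            col_possible.append(ok)
            ext_possible.append(False)
        else:  # entering present
            col_possible.append(False)
            remaining = years[i:]
            if variant.require_annual:
                need = [year + k for k in range(variant.absence_run)]
                ok = all(y in remaining for y in need)
            else:
                ok = len(remaining) >= variant.absence_run
            ext_possible.append(ok)

    return OccupancyTimeline(tree_id, years, counts, status, entering, events,
                             col_possible, ext_possible)


def infer_status(counts, years, variant: RuleVariant) -> list[str]:
    """Per-year status labels for one tree (see :func:`build_timeline`)."""
    return build_timeline(None, years, counts, variant).status


def detect_events(timeline: OccupancyTimeline):
    """Events plus per-year possible-occasion flags of a built timeline."""
    return (
        timeline.observable_events(),
        timeline.colonisation_possible,
        timeline.extinction_possible,
    )


def build_timelines(
    counts: pd.DataFrame,
    variant: RuleVariant,
    date_extinction_to_run_start: bool = False,
) -> list[OccupancyTimeline]:
    """Timelines for every tree in a tidy ``(tree_id, season_year, r)`` table."""
    required = {"tree_id", "season_year", "r"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    timelines = []
    for tree_id, grp in counts.sort_values("season_year").groupby("tree_id"):
        timelines.append(
            build_timeline(tree_id, grp.season_year.tolist(), grp.r.tolist(),
                           variant, date_extinction_to_run_start)
        )
    return timelines


@dataclass
class TurnoverRates:
    """Per-year and pooled colonisation/extinction rates with denominators."""

    per_year: pd.DataFrame
    colonisation_rate: float  # pooled: total events / total occasions
    extinction_rate: float
    colonisation_rate_yearmean: float  # mean of defined per-year rates
    extinction_rate_yearmean: float


def annual_rates(timelines: list[OccupancyTimeline], variant: RuleVariant) -> TurnoverRates:
    """Turnover rates from a set of timelines.

    Per year: events dated to that year divided by possible occasions in that
    year.  Pooled: total events over total occasions across all years.  A
    year with zero occasions gets a NaN (undefined) rate, never 0.
    """
    if not timelines:
        raise ValueError("at least one timeline is required")
    all_years = sorted({y for t in timelines for y in t.years})
    rows = []
    for year in all_years:
        col_ev = ext_ev = col_occ = ext_occ = 0
        for t in timelines:
            if year in t.years:
                i = t.years.index(year)
                col_occ += t.colonisation_possible[i]
                ext_occ += t.extinction_possible[i]
            for e in t.observable_events():
                if e.year == year:
                    if e.kind == COLONISATION:
                        col_ev += 1
                    else:
                        ext_ev += 1
        rows.append({
            "season_year": year,
            "colonisations": col_ev, "colonisation_occasions": col_occ,
            "extinctions": ext_ev, "extinction_occasions": ext_occ,
            "colonisation_rate": col_ev / col_occ if col_occ else np.nan,
            "extinction_rate": ext_ev / ext_occ if ext_occ else np.nan,
        })
    per_year = pd.DataFrame(rows)
    tot = per_year[["colonisations", "colonisation_occasions",
                    "extinctions", "extinction_occasions"]].sum()
    col_rate = (tot.colonisations / tot.colonisation_occasions
                if tot.colonisation_occasions else np.nan)
    ext_rate = (tot.extinctions / tot.extinction_occasions
                if tot.extinction_occasions else np.nan)
    return TurnoverRates(
        per_year=per_year,
        colonisation_rate=float(col_rate),
        extinction_rate=float(ext_rate),
        colonisation_rate_yearmean=float(per_year.colonisation_rate.mean()),
        extinction_rate_yearmean=float(per_year.extinction_rate.mean()),
    )


def timelines_to_frame(timelines: list[OccupancyTimeline]) -> pd.DataFrame:
    """Tidy per-tree-year export of statuses and dated events."""
    rows = []
    for t in timelines:
        ev_by_year = {e.year: e.kind for e in t.observable_events()}
        for i, year in enumerate(t.years):
            rows.append({
                "tree_id": t.tree_id, "season_year": year, "count": t.counts[i],
                "status": t.status[i], "entering": t.entering[i],
                "event": ev_by_year.get(year, ""),
                "colonisation_possible": t.colonisation_possible[i],
                "extinction_possible": t.extinction_possible[i],
            })
    return pd.DataFrame(rows)
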