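# Methods

This note records the models behind each stage, the defaults and why they were
chosen, the numerical choices, and what the synthetic data do and do not show.

## Abundance estimation

**Model.** A closed local population of `N` adults is trapped through one
season; each adult is caught a Poisson(λ) number of times, independently.
Conditioning on the `r` adults seen at least once, the per-individual capture
counts are zero-truncated Poisson, and the profile maximum-likelihood estimate
of `N` given `r` distinct individuals and `s` total captures solves

    ln N − ln(N − r) = s / N,        λ̂ = s / N̂.

The equation is solved with Brent's method on `v = ln(N − r)`: for
near-saturated counts (`s ≫ r`) the root lies within `r · e^{−s/r}` of `r`,
which underflows in the natural parameterisation but is exactly representable
in log-excess space. Relative tolerance 1e−12. `s = r` (no recaptures) leaves
`N` unidentifiable and raises a dedicated error.

**Standard errors.** Two routes: a parametric bootstrap (default B = 1000)
that re-simulates `round(N̂)` adults at λ̂ and re-solves per replicate, and an
analytic inverse of the 2×2 observed information of the (N, λ) likelihood,
whose `N`-block uses trigamma terms from the falling-factorial part
(`I_NN = ψ′(N−r+1) − ψ′(N+1)`, `I_Nλ = 1`, `I_λλ = s/λ²`). The two agree to a
few per mille on typical counts. Degenerate bootstrap replicates (no
recaptures) carry no information about `N` and are dropped.

**Two-tier allocation.** Tree-years with more than 10 captured individuals
(strict `>`) are solved per tree. The remaining tree-years with captures are
pooled within each year; Craig's model is solved on the pooled totals and the
resulting ratio `N_pooled / r_pooled` multiplies each small tree's `r`. The
pool contains only the small trees by default, which avoids counting
individuals already covered by direct per-tree estimates; `pool="all"`
switches to pooling every tree for the rate, as the alternative reading of
the procedure. A year whose pooled counts contain no recaptures falls back to
ratio 1 with a logged warning, and a nominally-direct tree-year without
recaptures is demoted into the pool rather than dropped. Estimates stay
real-valued; rounding is presentation-only.

## Turnover rules

**Observations.** Per surveyed tree-year: ≥3 adults is a presence
observation, 0 adults an absence observation, and 1–2 adults a *carried*
observation that inherits the previous effective status (the first surveyed
year inherits the next resolvable status instead). Carried observations
neither extend nor reset an ongoing absence run — a stray adult or two is
treated as possible immigration noise, not as evidence either way. A series
consisting only of 1–2 counts stays undetermined.

**State machine.** Effective status flips to present at any presence
observation (a colonisation if it was absent); it flips to absent only after
`absence_run` sequential absence observations (3 for the main rule; 1 and 2
as sensitivity variants). "Sequential" counts surveyed years, including
across calendar gaps; the strict-annual variant additionally requires the
absence years to be consecutive calendar years and discards runs broken by
gaps, and likewise only scores colonisations observed across a one-year step.
Colonisations are dated to the qualifying presence year. Extinctions are
dated to the year completing the absence run by default;
`date_extinction_to_run_start=True` dates them to the first absence year,
which is also the convention under which every event falls in a year flagged
as a possible occasion.

**Occasions and rates.** A surveyed tree-year is a colonisation occasion if
the tree's entering effective status is absent, and an extinction occasion if
it is present *and* enough surveyed years remain for an absence run to be
declared (consecutive calendar years under the strict-annual variant).
Unresolvable years contribute no occasions. Rates are events/occasions, per
year and pooled across years; both the pooled rate and the mean of per-year
rates are exported because yearly occasion counts differ. A year with zero
occasions has an undefined (NaN) rate, never zero. Because completion-dated
extinctions can fall in a year whose own occasion count excludes them, the
pooled rates are the headline quantities and per-year rows are descriptive.

## Tree variables

Wood-mould volume treats the cavity as a cone over the mould surface,
`V = depth · S / 3`, reported in dm³. Entrance areas use the standard formula
of whichever shape the hole most resembles (full widths as inputs). Entrance
direction is scored by angular distance from due south: 24 sectors of 15°,
the east/west sectors equidistant from 180° sharing a category, category 1
most southerly and 12 most northerly — implemented as
`min(12, ⌊|θ − 180|/15⌋ + 1)`, which is symmetric about the north–south axis
by construction and deterministic at boundaries. Diameters measured in an
earlier campaign are projected forward by two radii of annual ring growth per
year (`d + 2 · 18 · ring width` for the 18-year default); core ages are offset
by the 14 years since coring. Wood-mould volumes from the two campaigns enter
the models as their geometric mean, with single-measurement passthrough.

## Connectivity and tree demography

`S_i = Σ_{j≠i} p_j exp(−α d_ij)` with Euclidean distances in metres, computed
exactly in O(n²). α defaults to 1/60 m⁻¹, the reciprocal of the
characteristic dispersal distance observed for the species; `p_j` is each
tree's time-averaged estimated population size including zero years (a flag
selects raw captures instead). Missing `p_j` count as zero with a warning;
co-located trees contribute at full weight. Tree mortality and fall rates are
simple per-year rates, `events / (n_at_risk × interval)`, not compounded —
the compounded form does not reproduce the published 1.1%/yr and 0.4%/yr from
the underlying counts, the simple form does. Trees with a missing census
field drop out of that rate's denominator only, so the two denominators may
differ.

## Variability summaries

CVs use the sample (n−1) standard deviation over the mean; a zero-mean series
is flagged undefined. The metapopulation trend is tracked by the average
estimated population per sampled tree, since survey effort varies between
years. Occupancy counts a tree as occupied if at least one individual was
ever captured in it — deliberately more liberal than the ≥3-adult presence
rule, which serves turnover inference, not occupancy description. The
top-tree report ranks trees by time-averaged estimated size among those with
at least eight trapping years and returns the seven largest (both
configurable), with deterministic tie-breaking by tree id.

## Habitat model selection

Each candidate model is a binomial logistic regression of a per-tree binary
outcome (any colonisation/extinction observed) with a per-tree random
intercept; the exposure covariate is the tree's number of possible occasions.
The marginal likelihood integrates the random intercept by 25-node
Gauss–Hermite quadrature. Predictors are standardised internally and
coefficients mapped back. Because the profile likelihood in σ can be almost
flat (notably with one record per tree, where σ and the fixed effects trade
off along a ridge), σ is profiled over a bounded grid with warm-started inner
BFGS fits and local refinement; fits within 1e−4 log-units of the σ = 0 limit
collapse to the plain logistic fit, logged as such. `k` counts the fixed
effects, the intercept and the variance component, whether or not the
variance collapsed. Complete separation admits no finite ML fit; such models
are flagged non-converged and excluded from screening and ranking with a
warning.

Selection is two-stage: variables whose univariable model lowers AICc
(`−2logL + 2k + 2k(k+1)/(n−k−1)`) below the intercept-only model are
retained, then every subset of the retained variables is fitted with the
exposure covariate and ranked by AICc. Akaike weights are normalised over all
converged candidates; McFadden R² is computed against the intercept-only
model; ΔAICc < 2 marks the plausible set; ties break by smaller `k`, then
variable names. A guard refuses more than 20 selected variables (2²⁰ fits).

## Synthetic data

The simulator emulates the study conditions of a 25-year survey of ~70 hollow
oaks in two sub-areas: 13 survey seasons (1995–2002, 2005, 2006, 2008, 2015,
2019, exercising gap handling), an early-years core subset of 30% of trees,
annual tree mortality 1.1%/yr and fall 0.4%/yr, colonisation scaled
multiplicatively by relative connectivity `S_i / max S` (base 0.15, giving
realised frequencies of a few per cent per year), extinction 5%/yr tripled
for dead or fallen trees, and per-adult seasonal capture rate λ = 1.25 spread
over 20 trap sessions. Within-tree abundance follows a log-normal AR(1) on
the log scale (median 8 adults, σ = 1, ρ = 0.7), rounded and truncated to
≥1 — a heavy-tailed stand-in producing per-tree counts from 0 to ~100+; no
within-tree abundance model is implied for the real species. Randomness uses
a single seed with deterministic sub-streams per stage, so identical
parameters give byte-identical outputs.

What the simulator does *not* emulate: within-season movement between trees,
sex or age structure, detection heterogeneity between individuals or trees
(λ is common), observation error in tree attributes, and habitat succession
beyond the alive/fallen flags. Tests passing on synthetic data therefore
certify the estimators and rules under their stated assumptions — Poisson
captures, closed seasons, independent trees given connectivity — not
robustness to the violations real data may contain.

A `noiseless` capture mode (every adult caught exactly twice, with a
`min_adults = 3` floor) makes observation perfect, under which the turnover
rules recover the simulator's true event log exactly — except extinctions
masked by recolonisation before three absence years accrue, which no
three-year rule can see, and extinctions within two years of the last survey,
which are truncated; the ground-truth tests filter exactly these two cases.

## Problem sizes in the test suite

The suite verifies the Craig/zero-truncated-Poisson equivalence exhaustively
for r ≤ 50, s ≤ 200, the turnover rules exhaustively over all count series of
length ≤ 6 on {0,1,2,3}, estimator recovery on 500 simulated 200-adult
seasons, and the per-tree-vs-metapopulation CV contrast on 20 default
simulator runs; these sizes give stable statistics while keeping the full
suite around a minute.
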