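# hollowoak

Capture-mark-recapture and colonisation/extinction analysis for beetle
metapopulations living in hollow trees.

Saproxylic beetles such as *Osmoderma eremita* spend their larval years inside
the wood mould of veteran-tree cavities; each hollow tree is a habitat patch,
and the trees together carry a metapopulation whose turnover is slow enough
that only multi-decade trapping surveys reveal it. `hollowoak` implements the
full analysis chain such a survey needs, driven end-to-end by a synthetic
landscape-and-trapping simulator so that every stage can be exercised and
tested without field data:

- **Abundance (Craig's model).** With `r` distinct marked individuals and `s`
  total captures in a season, the population size solves
  `ln N − ln(N − r) = s/N` — the maximum-likelihood estimate when each of the
  `N` individuals is trapped a Poisson(λ) number of times (equivalently, the
  zero-truncated-Poisson score equation `r/N = 1 − e^{−s/N}`). Tree-years with
  more than 10 captured individuals are solved directly (with bootstrap or
  observed-information standard errors); the rest are pooled within each year
  and the pooled estimate is allocated back proportionally to captures.
- **Turnover rules.** ≥3 adults in a year is a presence; 0 adults is an
  absence observation, but a local extinction is declared only after three
  sequential absence years (1- and 2-year and strict-annual sensitivity
  variants included); 1–2 adults carry the previous status, guarding against
  stray immigrants. Colonisation and extinction rates are events divided by
  the tree-years at which each event could have been observed.
- **Connectivity.** `S_i = Σ_{j≠i} p_j · exp(−α · d_ij)` with α = 1/60 m⁻¹,
  the incidence-function measure of immigration potential.
- **Variability.** Yearly summary tables, occupancy counts, and coefficients
  of variation (CV = SD/mean over time) per tree and for the yearly average
  population per sampled tree.
- **Habitat models.** Binomial logistic regressions with a per-tree random
  intercept (Gauss–Hermite marginal likelihood), screened univariably by AICc
  against the null and then ranked over all subsets with Akaike weights and
  McFadden R²; models with ΔAICc < 2 form the plausible set.

## Worked example

```python
>>> import hollowoak as h
>>> h.solve_craig(r=165, s=283)   # one season: 165 individuals, 283 captures
236.42205867688088
>>> round(h.craig_se(165, 283, method="analytic"), 1)
14.7
```

About 236 beetles were present that season; the 118 recaptures pin the
estimate down to roughly ±15. The whole pipeline runs from one call (or
`hollowoak run-all --seed 1 --out demo` on the command line):

```python
>>> out = h.run_pipeline(h.PipelineConfig(out_dir="demo", seed=1))
>>> import json; m = json.load(open(out / "manifest.json"))
>>> round(100 * m["colonisation_rate"], 1), round(100 * m["extinction_rate"], 1)
(5.0, 4.3)
```

On this synthetic run, 5.0% of the unoccupied surveyed trees were colonised
per possible occasion and 4.3% of the occupied ones lost their population —
slow turnover of the magnitude these beetle metapopulations show. The output
directory holds per-tree-year estimates, occupancy timelines, rates,
connectivity, summary tables and the two AICc model-selection tables.

## Layout

- `src/hollowoak/synthetic.py` — landscape, dynamics and trapping simulator
- `src/hollowoak/craig.py` — Craig's estimator, SEs, two-tier allocation
- `src/hollowoak/turnover.py` — presence/absence rules, events, rates
- `src/hollowoak/attributes.py` — derived tree variables (wood mould volume,
  entrance direction categories, projections)
- `src/hollowoak/landscape.py` — connectivity and tree demographic rates
- `src/hollowoak/summaries.py` — yearly tables, occupancy, CVs
- `src/hollowoak/model_selection.py` — random-intercept GLMM + AICc ranking
- `src/hollowoak/pipeline.py`, `cli.py` — file contracts, `hollowoak` CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
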