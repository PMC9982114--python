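# haus

Health appraisal of urban-environment scenarios: a library and CLI that
quantifies and monetizes the health impacts of changes to urban environments
through *impact pathways* — documented links from one environmental change
(an NDVI increase, a new park, improved heating) to one health outcome,
carrying an odds ratio, a target population and an optional activation
threshold.

For each scenario the tool computes:

- **Attributable deaths and cases** per year — the exposed group's annual
  rate is the literature rate times the pathway's odds ratio
  (rare-outcome OR ≈ RR approximation, clamped into [0, 1]), so the
  attributable count is `ne · rate · (OR − 1)`; protective pathways
  (OR < 1) come out negative.
- **Life-years lost (YLL)** from attributable deaths and mean remaining
  life expectancy, and **years lived with illness (YLD)** from attributable
  cases and illness duration capped per age stratum at remaining life
  expectancy.
- **Project-lifetime totals** with a phased-onset lag ramp (20% of full
  effect in year 1, up to 100% at year 5) and a 25-year cap.
- **Societal valuation** in GBP 2019: per-case / per-year unit costs for
  morbidity, VSL / VSLY for mortality, disaggregated by cost component
  (medical, productivity & informal care, disutility) and cost bearer
  (individual/family, employer, healthcare provider, state). Optional
  discounting (off by default).

A Monte-Carlo oracle (per-person Bernoulli draws) provides an independent
check of the closed-form arithmetic.

## Layout

| module | contents |
|---|---|
| `haus.pathways` | impact-pathway model, CSV/JSON registry I/O, threshold activation, filtering |
| `haus.population` | age/sex-structured population profiles, rate tables, exposure splits |
| `haus.engine` | attributable deaths/cases, YLL/YLD, Monte-Carlo oracle |
| `haus.valuation` | lag ramp, lifetime totals, unit values, monetization, discounting |
| `haus.runner` | scenario evaluation, percent-change reports, scenario comparison, sweeps |
| `haus.fixtures` | synthetic input generators + a packaged riverside-regeneration example |

All interchange formats are plain text (CSV / YAML / JSON); numeric fields
round-trip at full precision.

## CLI

`haus fixtures` writes a complete example input set (pathway library,
population, rates, unit values, four scenarios and a config file), which the
other commands consume:

```sh
haus fixtures --out inputs --seed 0
haus validate inputs/config.yaml
haus run inputs/config.yaml --out results
haus compare inputs/config.yaml \
    --scenarios s1_policy_compliant,s2_single_open_space,s3_dispersed_open_space \
    --out results
haus sweep inputs/config.yaml --metric ndvi_increase --values 0.15,0.24 --out results
```

Outputs: `report.csv` (one row per pathway; inactive pathways render as a
dash), `valuation.csv` (component/bearer breakdowns), `comparison.csv`
(net attributable cases per scenario, totals flagged as not adjusted for
double counting), and `manifest.json` (input digests + config echo for
auditability). Runs are deterministic: identical inputs give byte-identical
reports.

The packaged example reproduces a documented case-study skeleton (total
population 9,241; 3,000 on-site residents; a 0.7 ha open-space activation
threshold that is met by a single 1 ha park but not by dispersed pocket
parks) with back-solved odds ratios and invented unit values, all labelled
synthetic.

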