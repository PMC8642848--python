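# timeuse-coda

Compositional data analysis (CoDA) of device-measured 24-h time use —
sitting, standing, stepping and sleeping — against glycaemic outcomes
(fasting plasma glucose, FPG, and 2-h post-load glucose, 2hPLG), stratified
by diabetes risk (HbA1c < 39 vs ≥ 39 mmol/mol). Built for epidemiologists
working with thigh-worn inclinometer (e.g. activPAL) day-level summaries
who want the full analysis chain — wear-validity filtering, simplex
geometry, group comparison, ilr regression and isotemporal reallocation —
as tested, scriptable Python.

A 24-h day is a composition x = (sit, stand, step, sleep) closed to
1440 min. Modelling uses isometric log-ratio pivot coordinates with a
chosen reference behaviour,

    z1 = sqrt(3/4) ln( ref / (o1 o2 o3)^(1/3) ),
    z2 = sqrt(2/3) ln( o1 / sqrt(o2 o3) ),   z3 = sqrt(1/2) ln( o2 / o3 ),

and ordinary least squares E[ln y | z] = β0 + β1 z1 + β2 z2 + β3 z3 +
covariate effects. β1 is the association of relative time in the reference
behaviour with log glucose; rotating the reference behaviour re-expresses
the same fit, which is how per-behaviour coefficients are obtained. Moving
t minutes between two behaviours at the group's geometric-mean composition
gives an estimated glucose change 100·(exp(Δ) − 1)% with Δ = (z_new −
z_base)′β. Because the real cohort is not publicly deposited, a synthetic
cohort generator with matching statistical structure (and known ground
truth) drives the pipeline; see `docs/methods.md`.

## Layout

- `src/timeuse_coda/` — the library: `composition` (simplex geometry),
  `processing` (validity rules, exclusion cascade), `groups` (bootstrap
  percent differences, Hotelling T²), `regression` (ilr OLS, interactions,
  VIF, backward elimination), `reallocation`, `cohort` (synthetic
  generator), `pipeline`, `cli`.
- `analysis/01…05_*.py` — numbered narrative drivers that run each stage
  and write tables under `results/`.
- `results/tables/` — example outputs of the drivers at seed 1.

## Worked example

```bash
python analysis/01_simulate.py --seed 1     # 648 synthetic participants
python analysis/02_process.py               # validity + exclusions
python analysis/03_compare_groups.py --seed 1
python analysis/04_fit_models.py
python analysis/05_reallocate.py
```

`02_process.py` prints the exclusion cascade:

```
648 participants in, 567 analysable:
  excluded, insufficient valid days: 17
  excluded, known diabetes: 32
  excluded, pregnant: 1
  excluded, missing covariates: 31
  missing FPG (flagged): 0; missing 2hPLG (flagged): 6
Per-outcome samples: FPG n=567, 2hPLG n=561
```

`03_compare_groups.py` reports no overall compositional difference between
risk groups (Hotelling T² = 0.681, p = 0.878) and per-behaviour percentage
differences whose bootstrap CIs all straddle zero — the generator draws
both groups around nearly identical centres. `04_fit_models.py` recovers
the generating associations, e.g. (adjusted, per-group):

```
fpg   ~ sit   (lower risk):  beta =  0.050 ( 0.012,  0.089)
2hplg ~ step  (higher risk): beta = -0.238 (-0.399, -0.076)
```

positive sitting and negative stepping coefficients on the log-glucose
scale. `05_reallocate.py` converts the fitted models into isotemporal
estimates:

```
60 min sitting -> stepping, estimated change in 2-h glucose:
  lower risk: -1.9% (-6.3, 2.7)
  higher risk: -9.4% (-15.2, -3.3)
```

i.e. at the higher-risk group's geometric-mean day, shifting an hour of
sitting into stepping is associated with ~9% lower expected 2-h glucose in
this synthetic replicate. The same run is available as one command:
`timeuse-coda all --seed 1 --out results/run`.

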