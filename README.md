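# gcsf-cea

Cost-effectiveness analysis of **long-acting (pegylated) vs short-acting
G-CSF** as primary prophylaxis against chemotherapy-induced neutropenia
in adult women with stage II–IV breast cancer on four-cycle TC
chemotherapy (docetaxel + cyclophosphamide), from the Chinese healthcare
perspective in 2019 CNY.

The package is aimed at health-economics and HTA analysts who want a
tested, scriptable re-implementation of this class of decision model
rather than a spreadsheet: every component — the synthetic real-world
cohort, propensity-score matching, both Markov models, and the
sensitivity analyses — is a plain Python function with a deterministic
seed, and every artifact is a CSV or JSON file.

## What it computes

Two linked Markov cohort models:

1. **Chemotherapy model** (12 weeks, four 3-week cycles, undiscounted):
   states {OnChemo, FN, FN+Infection, Dead, Completed}. Per cycle,
   febrile neutropenia (FN) occurs with probability *p*<sub>FN</sub>
   (0.0116 long-acting / 0.0404 short-acting); FN may progress to
   infection and either may be fatal (0.034). Outputs per-patient cost,
   QALYs, and FN / infection / death counts per 1000 patients treated.
2. **Post-chemotherapy survival model** (35 annual cycles, 5%/yr
   discount): FN history raises the probability of a relative dose
   intensity (RDI) below 85% (0.500 with FN vs 0.247 without), and
   RDI < 85% carries a breast-cancer mortality hazard ratio of 1.73.
   Outputs discounted QALYs and life-years per arm.

Incremental results are ΔC, ΔQ, ICER = ΔC/ΔQ, and net monetary benefit
NMB = λ·ΔQ − ΔC at the willingness-to-pay threshold λ = ¥72,371/QALY.
One-way sensitivity analysis produces tornado tables; a 1000-draw
probabilistic sensitivity analysis (beta/gamma sampling) produces the
cost-effectiveness plane and acceptability curve (CEAC). A synthetic
1824-patient retrospective cohort with an optional confounded mode feeds
the propensity-score-matching stage (greedy 1:1 nearest-neighbour on the
logit of the score, caliper 0.2 SD).

See `docs/methods.md` for model structure, parameter tables, the
synthetic life table, and all numerical conventions.

## Worked example

```python
from gcsf_cea import load_parameters, make_life_table, run_base_case

params = load_parameters()          # packaged base-case configuration
life_table = make_life_table()      # synthetic Gompertz life table
res = run_base_case(params, life_table)

print(f"ΔC = ¥{res.delta_cost:,.0f}")
print(f"ΔQ (12 weeks)  = {res.delta_qalys_chemo:.4f}")
print(f"ΔQ (35 years)  = {res.delta_qalys_postchemo:.4f}")
print(f"ICER (total)   = ¥{res.cea_total.icer:,.0f}/QALY")
print(f"FN per 1000    = {res.chemo['PEG'].fn_per_1000:.0f} vs "
      f"{res.chemo['RHG'].fn_per_1000:.0f}")
```

prints

```
ΔC = ¥3,321
ΔQ (12 weeks)  = 0.0027
ΔQ (35 years)  = 0.0363
ICER (total)   = ¥85,281/QALY
FN per 1000    = 46 vs 161
```

The long-acting arm costs ¥3,321 more per patient (its acquisition-price
premium of ¥10,326 over four cycles, minus ~¥7,000 of averted FN and
infection costs), prevents 115 FN episodes per 1000 patients, and gains
0.039 QALYs overall — an ICER of ≈¥85,000/QALY against the ¥72,371
threshold, so cost-effectiveness is borderline and seed-sensitive in the
probabilistic analysis.

The same pipeline is available from the shell:

```bash
gcsf-cea all --seed 1 --out results/          # everything + manifest
gcsf-cea psa --seed 1 --n-draws 1000 --out results/
# -> P(cost-effective at WTP 72,371) = 0.425 (1000 draws)
gcsf-cea match --seed 1 --out results/
# -> matched 887 pairs (mean PS 0.509 / 0.507)
```

Subcommands: `generate-cohort`, `match`, `run-chemo`, `run-postchemo`,
`dsa`, `psa`, `all`; all accept `--config` (a YAML file mirroring the
published input tables — the packaged default is
`src/gcsf_cea/data/default_config.yaml`), `--seed` and `--out`.

## Layout

```
src/gcsf_cea/
  params.py       parameter set + YAML configuration (strict, round-tripping)
  cohort.py       synthetic retrospective cohort generator
  matching.py     propensity scores, 1:1 matching, balance diagnostics
  markov.py       generic cohort engine + microsimulation oracle
  chemo.py        model 1: chemotherapy with FN/infection/death
  postchemo.py    model 2: long-term survival via RDI
  lifetable.py    synthetic Gompertz + stage-blended cancer mortality
  cea.py          incremental metrics (ICER, NMB, dominance)
  sensitivity.py  one-way DSA, beta/gamma PSA, CEAC, CE plane
  analyze.py      run both models for both arms
  pipeline.py     end-to-end run with manifest
  cli.py          click entry points
```
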