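# Methods

`gcsf_cea` evaluates primary prophylaxis with a long-acting, pegylated
G-CSF (given once per chemotherapy cycle, "PEG") against a short-acting
G-CSF (daily course, "RHG") in adult women with stage II–IV breast cancer
receiving four 21-day cycles of TC chemotherapy (docetaxel 75 mg/m² +
cyclophosphamide 600 mg/m²). Two linked Markov cohort models produce
per-patient costs (2019 CNY) and QALYs per arm; incremental results are
summarized as ΔC, ΔQ, the ICER ΔC/ΔQ, and net monetary benefit at a
willingness-to-pay threshold of ¥72,371/QALY (2020 GDP per capita).

## Model 1 — chemotherapy (12 weeks)

States: `OnChemo`, `FN`, `FNInfection`, `Dead`, `Completed`; cycle length
3 weeks (3/52.18 years), four cycles, no discounting over the 12-week
horizon.

Febrile neutropenia (FN) and subsequent infection are *within-cycle
tunnel events*: the state occupied during a cycle records the
complication experienced in that cycle. Per cycle, a patient on
chemotherapy develops FN with probability `p_fn` (0.0116 PEG / 0.0404
RHG); given FN, infection follows with probability `p_inf|fn` (0.0547 /
0.547, taken verbatim from the source tables — a configuration switch
`equalize_infection_risk` sets both to 0.547 if the tenfold asymmetry is
judged a typographical artifact); FN without infection is fatal with
probability 0.034, infection with 0.034 (competing within-cycle outcomes
— infection death *replaces* FN death rather than adding to it).
Survivors resume chemotherapy the next cycle; after cycle 4 survivors
absorb into `Completed`.

Because the first cycle's events are encoded as the model's entry split
(the cohort enters already distributed across {uncomplicated, FN,
FN+infection}), the first cycle's event costs and counts are added
analytically by the arm runner; the engine itself costs entries only on
transitions. Remaining in a tunnel state across a transition is a *new*
episode and is counted and costed as such; an exhaustive enumeration of
the within-cycle event tree verifies the expected FN/infection/death
counts to 1e-12.

Per-cycle state costs for all on-treatment states: chemotherapy drugs
(vial-rounded: doses scaled by body surface area, default 1.6 m², rounded
**up** to whole vials — 6 × ¥1,792.74 docetaxel + 5 × ¥120.75
cyclophosphamide per cycle), G-CSF acquisition (¥3,315.74 PEG / ¥734.34
RHG per cycle) and mean hospitalization (¥14,811.10). Event costs: FN
admission ¥25,000 per episode; infection treatment ¥50,000 per episode
(an infection episode also incurs the FN admission, infection arising
only from FN). Utilities: 0.70 on chemotherapy, 0.33 during FN or
infection, accrued time-correctly as utility × 3/52.18 years per cycle.
The `fn_per_1000`, `inf_per_1000` and `deaths_per_1000` outputs are 1000
× expected cumulative episode counts per patient treated.

The FN risk is read as a constant per-cycle probability. A
`course_level_fn` switch instead reads the tabulated value as a
per-course risk and spreads it over the four cycles on the hazard scale
(`p_cycle = 1-(1-p_course)^(1/4)`); neither reading reproduces the
source's printed per-1000 event counts (19/61 FN, 24/83 infections, 2/8
deaths — in which infections exceed FN cases although infection is
conditioned on FN), so the package reports its own internally consistent
counts (base case: FN 46/161 per 1000, infections 3/88, deaths 2/5).
Likewise the printed absolute per-arm totals (≈¥146,000; 3.456 QALYs over
12 weeks, which no time-correct utility convention can produce on a
12-week horizon) cannot be decomposed from the tabulated unit inputs; the
published *incremental* arithmetic, which is reproducible, is verified
exactly in the acceptance tests.

## Model 2 — post-chemotherapy survival (35 years)

States: `Alive_RDIlow` (relative dose intensity < 85%), `Alive_RDIok`,
`Dead`; annual cycles from age 45 over a 35-year horizon (life expectancy
≈ 80 years); QALYs discounted at 5%/year; no costs after chemotherapy.

The cohort splits **once, at entry** (RDI is fixed by the completed
course): `P(RDI<85%) = p_fn_course × P(low|FN) + (1-p_fn_course) ×
P(low|no FN)` with `P(low|no FN) = 0.247` below age 65, scaled by RR 1.38
at 65+. For FN history the default uses the directly measured real-world
estimate 0.500; an `rdi_or_mode` switch instead applies OR 1.58 to the
baseline odds (yielding 0.341 at the base case). `p_fn_course` is the
probability of ≥1 FN episode during the course, `1-(1-p_fn)^4` per arm
(0.0456 PEG / 0.1520 RHG at base case).

Annual mortality treats all-cause and breast-cancer-specific risks as
independent competing risks, `q = 1-(1-q_all)(1-q_bc)`. The mortality
penalty of RDI<85% (HR 1.73) is applied on the hazard scale,
`q_bc → 1-(1-q_bc)^1.73`, which keeps probabilities in [0,1] (direct
multiplication would not). Survivor utilities are 0.86 for the first five
annual cycles (years 1–5) and 0.96 thereafter.

### Synthetic life table

Registry mortality tables are not distributed with the package, so a
synthetic stand-in is generated: all-cause mortality from a Gompertz
hazard `h(a) = a₀·e^{0.09a}` with `a₀` solved by bisection so that life
expectancy at birth is 80.0 years (to ±0.01); breast-cancer-specific
mortality as stage-specific annual probabilities (0.010 / 0.022 / 0.060
for stages II/III/IV, blended with weights 0.50/0.35/0.15 ≈ 0.021/yr)
that decay as `e^{-0.15·(t-5)}` beyond five years post diagnosis. The
table is an ordinary CSV (`age, q_allcause, q_bc_stage2..4`) so real
registry data can be dropped in. Consequently the absolute per-arm
post-chemotherapy QALYs (≈12.2 here) depend on this stand-in and are not
comparable to registry-based values; every test and acceptance property
on this model (monotonicity in FN gap and HR, discount-rate ordering,
closed-form bounds) is chosen to be robust to the stand-in.

## Markov engine

A generic discrete-time cohort engine: `occupancy[t+1] = occupancy[t] ·
M[t]` with per-cycle row-stochastic matrices (rows validated to sum to 1
within 1e-12; absorbing states must self-loop). Rewards accrue at cycle
start on `occupancy[t]` for `t = 0..n-1` (no half-cycle correction, as in
the original spreadsheet implementation; a `half_cycle` switch averages
`occupancy[t]` and `occupancy[t+1]`). Event costs attach to state
*entries* (flows from a different state, plus self-flows for declared
tunnel states). The discount factor for cycle `t` is
`(1+r)^(-t·cycle_length)`; cycle 0 is undiscounted.

A vectorized microsimulation (individual categorical sampling through the
same schedule, deterministic per seed) serves as an independent oracle:
the acceptance suite checks cohort-vs-microsim agreement within 4
standard errors on every state and cycle for 20 random 4-state models at
10⁵ patients.

## Synthetic cohort and propensity matching

The generator emulates a five-hospital retrospective cohort (926 PEG /
898 RHG): length of stay 10.47±7.47 vs 8.95±7.88 days, hospitalization
cost ¥17,079±3,084 vs ¥14,086±335 (the implausibly small RHG SD is
accepted verbatim as a profile field), age 48.80±9.56 vs 48.75±9.96,
surgery 52.9% vs 40%, a three-level insurance mix dominated by
urban/rural-resident insurance, and concomitant-disease counts 0–3.
Continuous fields are truncated normals (at 0; at 18 for age). Truncation
at zero inflates a naive truncated draw's mean — by ~1.2 days for the
length-of-stay moments — so the generator solves for the underlying
(μ, σ) whose *post-truncation* moments equal the targets. `fn_event` is
drawn per course with probability `1-(1-p_cycle)^4` from the model's own
FN baselines, tying the cohort to the decision model.

Covariates are independent by default, which makes matching a no-op; the
*confounded mode* (PEG ages shifted +5 years, 0.15 prevalence mass moved
toward employee insurance in the PEG arm) gives the matching stage real
imbalance to correct. What the generator does **not** emulate: hospital
clustering, covariate correlations, non-normal cost tails, or any
outcome–covariate dependence beyond the FN rate — so passing balance
tests demonstrate the matching machinery, not real-world performance.

Propensity scores are fitted probabilities of PEG membership from a
logistic model (statsmodels) on age, insurance type and
concomitant-disease count (gender is accepted and dropped automatically
when constant — the cohort is all-female). Matching is greedy 1:1
nearest-neighbour **on the logit of the score**, without replacement,
treated patients in descending score order, caliper 0.2 SD of the logit
(the standard convention; `None` matches everyone possible). Balance is
the standardized mean difference `(m₁-m₂)/pooled SD` for continuous
covariates and the raw proportion difference for indicators. On the
confounded cohort at full scale the age SMD falls from ≈0.5 to ≈0.12 and
≈780 of 898 possible pairs survive the caliper; the acceptance property
requires post-match |SMD| < pre-match in ≥90% of 50 seeds.

## Sensitivity analysis

**One-way DSA** reruns the full two-model pipeline with one parameter at
a time at ±15% of base (probabilities capped at 1), the discount rate at
3%/7%, and reports tornado entries sorted by descending swing for
incremental cost (a model-1 quantity) and incremental QALYs (12-week,
35-year, and combined horizons).

**PSA** (default 1000 draws) samples probabilities and utilities from
beta and unit costs from gamma distributions. Where (α, β) are tabulated
they are used exactly — Beta(289, 881) for the no-FN RDI risk (mean
0.2470), Beta(40, 6) and Beta(367, 15) for survivor utilities, and
Beta(191, 191) for the RDI-if-FN risk, adopting α = 191 where the source
prints only "(α,β = 191)" (mean 0.5, consistent with the base case).
All other sampled parameters are moment-matched with SE = 15% of the
mean, mirroring the ±15% DSA convention — the only variance signal
available. The ratio parameters (RR 1.38, OR 1.58, HR 1.73) have no
tabulated distribution and stay fixed in the PSA (they are varied in the
DSA). Shared parameters are drawn once per draw and applied to both arms,
preserving the between-arm correlation structure.

The CEAC reports `P(λ) = fraction of draws with λ·ΔQ − ΔC > 0`. At 1000
draws the binomial Monte-Carlo error is about ±1.5 percentage points, so
CEAC values should be read as bands, not points. Because the base-case
incremental cost computed from the tabulated unit inputs (≈¥3,300, the
G-CSF price gap minus averted event costs) is much larger than the
source's printed ¥36 — which is not decomposable from those inputs — the
probability cost-effective at ¥72,371/QALY lands near 40–45% here rather
than the reference 66%; the qualitative conclusion (strictly interior
probability, monotone CEAC, direction of all effects) is unchanged.

## Numerical conventions and degenerate inputs

- Row-stochasticity tolerance 1e-12; occupancy conservation asserted at
  1e-9; absorbing occupancy is non-decreasing.
- ICER is flagged undefined (NaN) at ΔQ = 0; ΔC < 0 with ΔQ ≥ 0 is
  labelled dominant rather than reported as a negative ratio.
- Empty matched cohorts (nothing within caliper) warn rather than raise;
  an SMD with zero pooled SD is 0 when means agree, NaN otherwise.
- Zero-horizon survival runs return 0 QALYs; `n_psa_draws = 0` skips the
  PSA but still produces the base case.
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical cohorts, matchings, microsimulation
  traces and PSA clouds.

## Problem sizes used in tests

Microsimulation oracles run at 10⁵ patients (4-SE agreement bands), PSA
checks at 1000 draws, distribution calibration at 10⁵ samples, and the
matching-balance property at the full 1824-patient cohort over 50 seeds;
the entire suite completes in well under a minute.

## Known limitations

- The post-chemotherapy absolute QALY level is set by the synthetic life
  table; only differences and orderings are meaningful.
- The chemotherapy model treats FN risk as age-independent and constant
  across cycles; secondary prophylaxis, dose delays and non-TC regimens
  are out of scope.
- Matching supports greedy nearest-neighbour only (no optimal matching or
  weighting).
- Per-1000 event counts are expected episode counts, which can exceed
  1000 when repeat episodes are common (they are not at base-case risks).
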