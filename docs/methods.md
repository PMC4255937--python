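# Methods

## Scope and model structure

`raretrials` simulates phase-III randomized controlled trials for rare
diseases in order to compare experimental designs before any patient is
enrolled. A *scenario* is one drug–disease–endpoint situation; a *design* is
one of ten trial conduct engines; the engine crosses N scenarios × P designs
and aggregates R replicate trials per cell. Three sub-models generate each
trial.

### Covariate distribution sub-model

A virtual patient is an independent draw of:

| parameter | distribution | default (demo) | units |
|---|---|---|---|
| age | Normal, truncated at 0 | (18, 8) | years |
| baseline biomarker E₀ | log-normal | (ln 20, 0.3) | % clearance |
| progression rate k | Normal | (−0.1, 0.3) | units/period |
| drug sensitivity sᵢ | log-normal | (0, 0.3) | — |
| prognostic score | standard Normal | — | — |
| predictive marker | Bernoulli | prevalence 0.5 | — |

Log-normal laws for strictly positive quantities (baseline, sensitivity) and
a normal law for a signed rate are conventional population-PK/PD choices.
The prognostic marker enters the progression rate linearly
(k_adj = k + 0.05 · score by default); the predictive marker multiplies the
maximal drug effect (ratio 1.3 in marker-positive patients). This is the
minimal structure that separates "associated with outcome" from "modifies
treatment effect". Cohorts are drawn uniformly without replacement, with
optional inclusion criteria and predictive-marker enrichment.

### Input–output sub-model

Disease and drug dynamics are a discrete-time indirect-response Emax model
(time unit = one treatment period):

    dosed (D_j > 0):   A_j = A_{j−1} + k_on (E(D_j) − A_{j−1})
    undosed (D_j = 0): A_j = (1 − k_off) A_{j−1}
    E(D) = sᵢ mᵢ Emax · D / (EC₅₀ + D)
    Y_j  = E₀ + k_adj · j + A_j + ε_j,   ε_j ~ N(0, σ²)

Assumptions: additivity of drug effect and disease progression; geometric
onset toward a patient-specific plateau and geometric washout after
stopping; no dose accumulation (no explicit PK compartment); measurement
noise independent across visits, including baseline. This is deliberately
the *smallest* model that exhibits every phenomenon the compared designs
exploit — onset delay (early escape decision points), carryover and washout
(crossover, N-of-1), relapse after withdrawal, and a dose–response plateau.
Demo values: Emax = 8 % clearance, EC₅₀ = 1 dose unit, tested dose 2.5,
k_on = 0.6/period (≈ 87 % of plateau after two dosed periods), k_off = 1
(complete washout in one period, i.e. no carryover past a washout period),
σ = 4 %. Adverse events are independent Bernoulli draws per period at 0.05
(dosed) / 0.02 (undosed); they feed the ranking only, not the dynamics.

### Execution sub-model

Four per-patient deviation processes, each a per-period/per-visit Bernoulli
hazard: missed visits (transient, baseline never missed; 0.05), definitive
dropout (absorbing; 0.02/period), switching to the alternative treatment
(toggling; 0.01/period), and partial compliance (dose × 0.5 with
probability 0.05/period). Deviations act on *exposure first*: the received
regimen is constructed, then outcomes are simulated from it, so
received ≠ assigned is well-defined and analyses can stay intention-to-treat.
Deviation draws and outcome noise use separate random streams.

## Designs and analyses

All multi-patient allocation uses permuted blocks (default block 4), so the
running imbalance never exceeds half a block. Per variant:

- **parallel** — one arm throughout; Welch two-sample t on the
  change-from-baseline endpoint (last observation carried forward).
- **crossover** — AB/BA, block-balanced, one washout period between equal
  phases; per-patient difference of within-phase changes (anchored at each
  phase's own first visit, which cancels patient-level progression), then a
  one-sample t.
- **factorial 2×2** — four cells, additive latent effects of the two drugs;
  primary output is the A main effect across A margins. With no second drug
  configured, drug B defaults to a zero-effect copy of drug A.
- **randomized withdrawal** — open-label active run-in (4 periods);
  responders (run-in change ≥ δ, default 3) are randomized to continue or
  withdraw to placebo; Welch t on the post-randomization change among
  randomized responders. Fewer than two responders is a recruitment failure.
- **early escape** — parallel conduct, but non-responders (change below the
  escape threshold at the escape visit, default 0 at period 3) leave the
  study; their endpoint is the change at escape. The escape rule is applied
  to non-responders of *either* arm: one-sided escape selects on noise in a
  single arm and demonstrably inflates type-I error, while symmetric escape
  keeps the comparison unbiased and, under a real effect, still removes
  almost exclusively placebo patients.
- **N-of-1 series** — each patient runs randomized pairs of single
  active/placebo periods (3 cycles, washout period between treatments);
  cycle-level differences of per-period changes are averaged per patient and
  the series is tested with a one-sample t across patients (8 by default).
- **sequential triangular** — patients enter in groups of 10; at each
  interim the efficient score Z = V·(x̄_A − x̄_B)/s and information
  V = n_A n_B/N feed the decision: stop for efficacy when Z ≥ a + cV, for
  futility when Z ≤ −a + 3cV, boundaries inclusive, apex at V = a/c.
  Constants follow the straight-line construction for one-sided size α and
  power 1 − α at the standardized reference effect θ_R:
  a = 2 ln(1/2α)/θ_R, c = θ_R/4, with no overshoot correction — discrete
  interim monitoring therefore runs slightly *conservative*, which the
  calibration tests confirm empirically rather than assume. If the final
  interim is reached without crossing, the trial is not significant
  (conservative forced decision).
- **play-the-winner (RPW urn)** — the urn starts with u = 1 ball per arm;
  each observed success adds β = 1 ball of the same arm, each failure one of
  the opposite arm (success = change ≥ δ). Enrolment is staggered one period
  per patient and the urn uses every outcome available at allocation time
  (delayed-response RPW); the limiting allocation fraction of the better arm
  is q_other/(q_better + q_other), unchanged by bounded delay. Analysis is
  the Welch t on assigned arms.
- **randomized placebo phase** — two delay groups (0 vs 3 periods); all
  patients receive active treatment from their delay until trial end, so
  every completer finishes on active. Analysis compares the change over the
  differential-exposure window (baseline to the longer delay) between delay
  groups.
- **stepped wedge** — individuals (or clusters) cross from control to active
  at one of 5 randomized steps, all active by the final period. The
  treatment effect is estimated by least squares on treatment, period *and
  patient* indicators; without the patient indicators, the between-patient
  baseline variance (log-normal E₀) makes the OLS standard errors invalid
  under the null — the within-patient formulation is the minimal repair and
  is what the calibration test certifies.

Degenerate data (zero variance in both arms, fewer than two analyzable
endpoints per arm) yield a non-significant result with a logged warning, not
an exception; fewer than three per arm adds an "underpowered" warning. The
rank-sum test is available as an alternative two-sample method.

## Metrics, ranking, seeds

Per cell: power (% significant replicates), CV (100·SD/|mean| of the effect
estimate, reported as not-applicable when |mean| < 10⁻⁸), mean patients with
at least one active period (active patient-periods reported alongside, since
"patients under active treatment" is ambiguous for within-patient designs),
mean duration (periods × period length; group-sequential and staggered
designs accumulate duration wave by wave), mean adverse events and mean
enrolment. Replicates failing recruitment are excluded from means and
counted; a cell with > 50 % failures errors out.

`rank_by_significance` orders by power with precision-then-duration
tie-breaks. `rank_weighted` min-max normalizes each criterion across
candidates (so affine rescaling cannot change the order), applies the
benefit direction, and scores with non-negative weights summing to one; a
constant column contributes zero. The direction of the active-exposure
criterion is a stakeholder judgement (benefit in severe disease, burden
otherwise) and has no default weight. `pareto_front` returns the
non-dominated set; the weighted winner always lies on the front.

Randomness flows through a SeedSequence tree: root seed → (scenario, design)
cell → replicate → three named streams (allocation / deviations / outcomes).
Cells and replicates are therefore individually reproducible, and adding
replicates or cells never perturbs earlier draws. By default one virtual
population (n = 1000) is generated per cell and cohorts are re-drawn per
replicate, mirroring the idea of one disease population sampled repeatedly;
a fresh-population-per-replicate mode exists.

## What the generator does and does not emulate

The synthetic population reproduces inter-patient variability in baseline,
progression and drug response, biomarker-defined subgroups, visit noise, and
the common protocol deviations. It does **not** model: multi-centre
(investigator-level) effects, correlated covariates (age is independent of
severity), time-varying deviation hazards or response-dependent dropout
(hooks exist but the default is outcome-independent), PK accumulation or
dose titration, or non-normal measurement error. Passing tests therefore
certify the *statistical machinery* — calibration, power orderings,
adaptive-allocation laws — under a clean, known data-generating process;
they do not certify that any particular real disease matches the demo
parameters.

## Problem sizes and numerical choices

The test suite runs calibration checks at 2000 replicates per design (99 %
exact-binomial acceptance bands around α = 5 %), power comparisons at 1000
replicates per rung, and the demo experiment at its packaged 1000
replicates; these sizes give Monte-Carlo standard errors of ~0.5–1.6
percentage points, small enough for every assertion margin used. Closed-form
identities (log-normal mean, geometric dropout survival, Emax steady state,
boundary apex) are checked against independently coded oracles; steady-state
convergence tolerances rely on the geometric contraction of the update rule
(k_onⁿ after n dosed periods). Endpoints use last-observation-carried-forward
within the relevant window; a patient with no post-baseline observation is a
missing endpoint handled by complete-case analysis.

## Known limitations

Sequential monitoring uses the normal-approximation score statistic with the
pooled-variance estimate; at very small interim samples the approximation is
rough (the first interim at n = 10 is the practical floor). The factorial
analysis ignores interaction by design. Duration is an abstract clock
(periods), not a calendar or cost model. The RPW urn assumes outcomes become
available a fixed number of periods after enrolment. None of these
limitations affect the packaged demo's comparisons, but all are the natural
places to extend the package.
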