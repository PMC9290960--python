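# Methods

## Scope and model structure

`toxcea` computes the cost-effectiveness of toxicity-testing
methodologies as the discounted cost per discounted year of correct
regulatory decision-making. The computation chains four components:

1. a lognormal population-risk model linking a chemical's potency and a
   population's exposure to an incidence fraction (`risk_model`);
2. risk-based decision rules whose geometry reduces to thresholds on the
   potency axis (`decision_framework`);
3. the decision-making value (DMV): the probability that a methodology's
   noisy potency estimate reproduces the perfect-knowledge decision
   (`dmv`);
4. discounted single-chemical and program-level cost-effectiveness
   ratios (`cea_engine`), with reference scenarios and study runners in
   `experiments`.

Everything downstream of the risk model is analytic — normal CDFs and
geometric discount sums — so the full 5,000-chemical, 5-methodology,
2-rule study runs in seconds.

## Risk model

Individual threshold doses and received doses are lognormal;
independence of the two gives the closed-form incidence
R = Φ((μ_exp − μ_tox)/√(σ_exp² + σ_tox²)). All parameters are carried in
log10 space (log10 mg/kg/day for the means, log10 units for the GSDs)
because every downstream threshold and uncertainty is naturally
expressed there; doses are exponentiated only for presentation. Doses
are in mg/kg/day throughout; there is no unit-conversion layer.

The model does **not** assume a population threshold: the population
dose-response is an unbounded sigmoid even though each individual has a
threshold. Normal quantiles are computed (scipy `ndtri`), never
hard-coded, and double precision is used throughout; the inversion
μ_tox = μ_exp − Φ⁻¹(R)·√(σ_exp² + σ_tox²) round-trips through the
forward model to relative error below 1e−10 over the tested parameter
ranges.

## Decision rules and potency geometry

The simple rule acts iff the uncontrolled risk strictly exceeds the
target risk level (TRL); a risk exactly at the TRL is acceptable. The
complex rule selects, among the ordered choice set of regulatory
actions, the cheapest (by cost *rank*; monetary action costs are out of
scope) whose post-control risk is at or below the TRL.

Because risk is monotone in potency at fixed exposure, each rule
partitions the potency axis. The no-action boundary `trl_mu_tox` and the
per-action decision points `dp_mu_tox[k]` are computed by inverting the
risk model through the baseline and per-action exposure profiles
respectively — algebraically identical to inverting in risk space, but
avoiding an extra Φ/Φ⁻¹ round trip. Action k is correct on the half-open
interval `[dp_mu_tox[k], dp_mu_tox[k-1])`, **closed at the more-toxic
end**: boundary ties are measure-zero under continuous sampling and are
fixed this way purely for determinism. Potencies below the last decision
point form a "no compliant action" region; deciding there raises an
explicit error, and the reference choice set is constructed so the
sampled potency range never reaches it.

A choice set whose derived thresholds are not strictly decreasing is
rejected as ambiguous, with one deliberate exception: an action exactly
as lenient as no action shares the TRL threshold and simply owns an
empty region.

## Decision-making value

The potency estimate is modelled as Normal(μ_tox + bias, σ(μ̂_tox)) in
log10 space, centred on the **true** potency plus bias (all reference
methodologies are unbiased). The DMV is the normal probability mass the
estimate assigns to the truth's decision interval — one side of
`trl_mu_tox` for the simple rule, the truth's region for the complex
rule — i.e. a difference of normal CDFs at consecutive thresholds.
Uncertainty in the exposure parameters and in σ_tox is treated as zero:
the framework's simplifying assumption is that only the potency estimate
carries decision-relevant measurement error.

Degenerate cases: σ(μ̂_tox) = 0 yields DMV 1 everywhere, including a
truth exactly on a threshold (the point estimate equals the truth and
the shared half-open tie-break puts both in the same region); a truth on
a threshold with positive uncertainty and zero bias yields exactly 0.5
under the simple rule. No floor is applied to small DMVs. The complex
DMV never exceeds the simple DMV, since the simple rule's correct set is
a union of complex-rule regions.

## Cost-effectiveness accounting

Discounting uses the year-1-undiscounted convention
d(y) = (1 + r)^−(y−1), applied identically to costs and outcomes.

*Single chemical*: the full testing cost is charged in year 1; the DMV
accrues in each year from duration + 1 through the time horizon.

*Program*: with a constant annual budget, a cohort of
`floor(budget / cost)` chemicals starts testing **every** year 1..TH —
including years too late to finish within the horizon — and each cohort
is fully funded (discounted) at launch; a chemical started in year s
contributes DMV·d(y) for y in [s + duration, TH]. Charging late cohorts
while crediting them nothing is a deliberate design choice: it is the
unique simple annual-cohort policy consistent with the reference
duration-effect results (49-fold at TH 11, 3.4-fold at TH 20, 14-fold
averaged), and it captures the real opportunity cost of slow tests at
short horizons. Leftover budget below one chemical's cost is discarded,
not banked; the reference fixtures divide evenly so no remainder policy
is exercised.

Cohort size and DMV enter cost and outcome symmetrically, so the
per-chemical program CER factorises as `unit_cer(cost, duration, r, TH)
/ dmv`. Two scaling laws are therefore *exact*, not approximate: a
k-fold cheaper test gives exactly k-fold lower CER under a fixed budget,
and scaling all DMVs by c scales every CER by 1/c.

Horizon averaging takes the arithmetic mean of the per-horizon program
CERs over integer horizons (11–20 by default); every horizon must exceed
the methodology's duration. Population aggregates are the mean and the
maximum of per-chemical horizon-averaged CERs; in the fold-reduction
table the mean column is the ratio of population-mean CERs and the max
column is the largest per-chemical CER ratio between the two
methodologies — for the uncertainty comparison this is the chemical
whose decision is most affected by measurement error.

## Reference scenario and defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| TRL | 1e−6 | incidence fraction | severe-endpoint target; configurable |
| σ_tox | 1 | log10 units | interindividual toxicity spread |
| Baseline exposure | μ −8, σ 0.5 | log10 mg/kg/day | uncontrolled doses |
| Actions 1–3 exposure | (−8.5, 0.4), (−8.8, 0.4), (−14, 0.1) | log10 mg/kg/day | increasingly stringent controls; action 3 protective for any sampled potency |
| Methodologies | 10 y/$5M/σ 1 base; fivefold reductions in cost, time, uncertainty, all | — | isolate each lever's effect |
| Budget | 10 | $M/year | funds 2 base-case or 10 cheap chemicals/year |
| Discount rate | 3 | %/year | standard public-policy rate |
| Horizons | 11–20 | years | shortest useful through plausible methodology lifetime |
| Population | 5,000 μ_tox ~ U(−5, 2) | log10 mg/kg/day | deliberately wide potency range |

With these fixtures the derived decision geometry is `trl_mu_tox` ≈
−2.6855 (0.002 mg/kg/day), decision points ≈ −3.3804 (0.0004), −3.6804
(0.0002) and −9.2229. The narrow action-2 band (0.3 log10 units) is what
drives the largest complex-rule CERs: a σ = 1 estimate lands in it with
probability ≈ 0.12 even when the truth is dead-centre.

## What the population sampler does and does not emulate

`sample_population` draws potencies log-uniformly on [−5, 2] — the study
condition, chosen wide to expose the CER-vs-potency relationship — with
a logged seed (numpy `default_rng`). It does not emulate a realistic
market potency distribution, chemical-specific exposure heterogeneity,
per-chemical testing-cost variation, or correlation between potency and
exposure. Passing tests therefore demonstrate the framework's internal
consistency and its published illustrative results, not the
cost-effectiveness ranking that would obtain for a real chemical
inventory.

## Verification strategy

Closed forms are tested against independent brute-force oracles: the
risk model against adaptive quadrature of the dose-response/dose-density
integral (|Δ| < 1e−8 over random parameter sets), the DMV against 10⁶
draw Monte-Carlo classification (within 3 binomial standard errors at
every grid point), the complex rule against region lookup at 1,000
random potencies, and the program CER against an explicit year-by-year
cohort ledger. Published aggregate values over the 5,000-chemical
population are matched within ±10 % (the original sampling is not
reproducible); deterministic ratios to two significant figures; cost
ratios exactly.

## Known limitations

- Lognormality of both variability distributions is assumed, not fitted.
- Uncertainty enters only through the potency estimate; exposure
  parameters and σ_tox are treated as known.
- Benefit–cost balancing rules, value-of-information analysis,
  incremental CERs for retesting, tiered testing strategies, and
  under-regulation penalties are out of scope.
- The CER counts correct decisions only; two methodologies with equal
  correct-decision counts but different error profiles score alike.
- Budget carry-over and variable annual budgets are not modelled.
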