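# toxcea

Cost-effectiveness analysis of toxicity-testing methodologies.

Regulatory agencies face tens of thousands of chemicals with little or no
toxicity data, and a growing menu of testing methodologies — *in vivo*
batteries, *in vitro* assays, *in silico* predictions — that differ in
three ways that matter: what a test costs, how long it takes, and how
uncertain its toxicity estimate is. `toxcea` puts all three on a single
scale, the **cost per correct regulatory decision**, so that a testing
program can ask which methodology buys the most correct decisions per
dollar.

The package is aimed at risk analysts and decision scientists designing
chemical-testing programs, and at anyone studying how measurement
uncertainty propagates into regulatory decision quality.

## The model

**Population risk.** Individual threshold doses (the dose at which an
individual experiences an adverse effect) and the doses people actually
receive are both taken as lognormal. With log10 parameters
(μ<sub>tox</sub>, σ<sub>tox</sub>) for toxicity and
(μ<sub>exp</sub>, σ<sub>exp</sub>) for exposure, the fraction of the
population affected has the closed form

&nbsp;&nbsp;&nbsp;&nbsp;R = Φ((μ<sub>exp</sub> − μ<sub>tox</sub>) / √(σ<sub>exp</sub>² + σ<sub>tox</sub>²))

which inverts analytically: the potency at which the risk equals a target
level TRL is μ<sub>tox</sub> = μ<sub>exp</sub> − Φ⁻¹(TRL)·√(σ<sub>exp</sub>² + σ<sub>tox</sub>²).

**Decision rules.** The *simple rule* acts iff the uncontrolled risk
exceeds the TRL. The *complex rule* selects the cheapest regulatory
action from an ordered choice set that brings the risk to or below the
TRL. Both rules partition the potency axis into decision regions whose
boundaries — the TRL threshold and the per-action *decision points* —
come from the inversion above.

**Decision-making value (DMV).** A methodology reports a noisy potency
estimate, μ̂<sub>tox</sub> ~ Normal(μ<sub>tox</sub> + bias, σ(μ̂<sub>tox</sub>)).
The DMV is the probability that the decision made from the estimate
matches the decision perfect knowledge would give — analytically, the
normal probability mass the estimate assigns to the truth's own decision
region.

**Cost-effectiveness ratio (CER).** Discounted testing cost divided by
discounted correct-decision-years (DMV accrued each year after the test
completes, through the time horizon), with year-1-undiscounted factors
(1 + r)<sup>−(y−1)</sup>. At the program level, a fixed annual budget
launches a new cohort of `floor(budget / cost)` chemicals every year of
the horizon; each cohort is fully funded at launch and its chemicals
contribute outcomes from completion to the horizon. Lower CER is better.

## Worked example

The single-chemical ledger for a $5M, 10-year test whose results support
decisions with probability 0.9 in years 11–20 at a 3 % discount rate:

```sh
$ toxcea table1
...
NPV cost (millions $): 5.00
NPV outcome (correct-decision-years): 5.88
CER (millions $ per outcome): 0.85
```

Reading: the test costs $5M up front and yields 5.88 discounted years of
correct-decision capability, so each discounted correct-decision-year
costs $0.85M.

The full two-rule study over 5,000 chemicals with log-uniform potency on
[−5, 2] log10 mg/kg/day, comparing a base-case methodology (10 years,
$5M, potency-estimate SD 1 log10 unit) against fivefold reductions in
cost, duration, uncertainty, and all three:

```sh
$ toxcea reproduce --seed 1
Average and maximum CER (millions $ per outcome):
                     mean_cer_simple  max_cer_simple  mean_cer_complex  max_cer_complex
methodology
base case                       15.3            26.1                23              111
reduced cost                    3.05            5.22               4.6             22.1
reduced time                    1.07            1.83              1.61             7.77
reduced uncertainty             13.5            26.1              14.4             29.9
all reduced                    0.189           0.366             0.203             0.42

Fold-reductions in CER relative to the base case:
                                                     mean_ratio_simple  mean_ratio_complex  max_ratio_simple  max_ratio_complex
reduction
due lower cost (...)                                                 5                   5                 5                  5
due shorter duration (...)                                        14.2                14.2              14.2               14.2
due less uncertainty (...)                                        1.13                1.59              1.51               4.59
due lower cost, shorter duration, and less unc...                 80.5                 114               108                327
```

Reading: cutting cost fivefold cuts the CER exactly fivefold for every
chemical; cutting duration fivefold is worth 14-fold (averaged over
11–20-year horizons; 49-fold at an 11-year horizon, 3.4-fold at 20);
cutting uncertainty fivefold is worth only 1.1-fold on average under the
simple rule but up to 4.6-fold for chemicals whose potency sits near a
decision point under the complex rule.

Other entry points: `toxcea run --config scenario.yaml --seed 1 --out
results/` evaluates a custom scenario file (schema in
`ScenarioSuite.from_dict`), and `toxcea curves --rule complex --seed 1
--out results/` writes the per-chemical CER-vs-potency curve data. The
same functionality is available as a library; see
`toxcea.experiments.run_suite`.

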