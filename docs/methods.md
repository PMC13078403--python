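# Methods

## Decision problem and model structure

The package evaluates a digital technology that predicts relapse in people
newly abstinent after treatment for alcohol or opioid use disorder,
provided on top of standard care for the first year of abstinence. The
comparator is standard care alone (reactive, event-driven response to
relapse). Outcomes are discounted costs (UK health and social care
perspective, GBP), QALYs, relapse burden, and net monetary benefit at a
willingness-to-pay threshold λ (default £20,000/QALY).

Both models are deterministic Markov cohort models over five states with a
3-month cycle, the cohort starting entirely in abstinence:

* **AUD**: abstinence, relapse, treatment start, treatment continuation,
  death. From relapse, a fraction B (0.80/cycle) starts treatment and a
  small fraction E (0.002/cycle) recovers spontaneously. Treatment start
  leads to continuation with probability C (0.58) or drops out back to
  relapse (F = 1 − C). Completing the continuation cycle means recovery
  (D = 1) back to abstinence. Two treatment cycles ≈ the typical 6-month
  treatment episode.
* **OUD**: abstinence, relapse, medically supervised withdrawal (MSW),
  medication for opioid use disorder (MOUD), death. B = 0.9, E = 0. MSW
  (≈12 weeks) continues to MOUD with probability C = 1; MOUD is an
  open-ended maintenance state with no relapse exit and a slow per-cycle
  recovery D = 0.02 to abstinence.

Relapse risk from abstinence is a banded per-cycle probability: AUD 0.13
(cycles 1–4), 0.08 (5–12), 0.03 (13+); OUD 0.35 (cycle 1), 0.06 (2–4),
0.04 (5–8), 0.02 (9+). Bands are indexed by model cycle (calendar time
since the cohort achieved abstinence), not by personal time: someone
re-achieving abstinence in cycle 7 faces the cycle-7 band.

### Intervention arm

The device multiplies the relapse transition by `m` (base 0.85) during the
provisioned cycles (base: cycles 1–4). People re-achieving abstinence
after the first year do not receive a second device. Hooks exist for
effects on treatment-seeking and recovery rates (multipliers defaulting
to 1, same active window); products are clipped at the probability ceiling
of 1 because the base rates already sit at or near 1. The relapse product
`A·m` is never clipped — exceeding 1 raises an error, since that signals a
mis-specified parameter set rather than a saturated rate.

### Mortality

Death is possible from every state. Published inputs are *relative*
mortality rates (AUD: abstinence 1.04, relapse 1.24; OUD: abstinence 1.0,
relapse 6.14, MSW 6.04, MOUD 3.55). The baseline level they multiply is
not published; the package supplies annual baselines of 0.0025 (male) and
0.0016 (female) — the order of magnitude of a UK mid-adult cohort —
blended by the cohort's male proportion and converted per cycle as
`1 − (1 − p)^(1/4)`. **This is an implementer-supplied assumption**,
exposed as two ordinary parameters; at these levels mortality shifts the
1-year incremental results by under 1 %. No relative rate is published for
the AUD treatment states; they carry the relapse (recently drinking)
rate 1.24, an assumption isolated in the fixture's `mortality_rr` map.

Competing risks: death is applied first at `q_s = RR_s·q0` and the
conditional transition row is scaled by `1 − q_s`. This keeps the printed
probabilities interpretable as conditional-on-survival and guarantees
row-stochastic matrices for any admissible parameters.

## Accrual conventions

There is no half-cycle correction. Instead each stream is tied to a
defined point of the cycle (both points are exposed as toggles on
`Accrual`):

* **Costs accrue on the post-transition (end-of-cycle) occupancy.** State
  costs in these models are care costs triggered by events — a relapse or
  a treatment cycle is paid for when it occurs — so they follow the state
  a person moves *into* during the cycle. The first (pre-model) abstinent
  cycle start therefore incurs no cost.
* **Utilities accrue on the pre-transition (start-of-cycle) occupancy**:
  a cycle's quality of life reflects the state in which it is lived.
  Full-year utilities contribute one quarter per cycle; death contributes
  zero.

Both streams use the discount factor of the cycle's start,
`(1 + r)^(−(c−1)/4)` with r = 0.035/year, so cycle 1 is undiscounted.

The device charge applies to the cohort mass alive at the start of each
provisioned cycle, in the intervention arm only: everyone alive keeps the
device whether abstinent or relapsed (provision is fixed for the year, with
no stopping rule), and the dead are not charged.

**Relapse burden** is the expected number of person-cycles spent in the
relapse state (end-of-cycle relapse occupancy summed over the horizon).
With a quarterly cycle this reads naturally as "relapse quarters"; because
the mean sojourn in relapse is short (the exit probability per cycle is
B + E ≈ 0.8–0.9), it closely tracks, and slightly exceeds, the count of
distinct relapse episodes. Per-cycle *entries* into relapse (re-entries
counted again) are retained on `CohortTrace.relapse_entries` for flow
analyses. The savings-per-relapse-avoided statistic divides the unrounded
cost difference by the unrounded relapse-burden difference.

These conventions were fixed as a set — event-driven costing, time-lived
utility, person-cycle relapse burden — and the package's end-to-end tests
show they reproduce the published alcohol-model incrementals and both
models' cost and relapse columns within the tolerance discussed below.

## Sensitivity and threshold analyses

* **One-way**: each parameter in the published limits table is set to its
  lower then upper printed limit (others at base) and the model
  re-evaluated; entries are ranked by the larger |NMB − base NMB|. The
  printed limits are used verbatim, not a blanket ±20 % recomputation;
  where a limit pair is inverted relative to the base (an oddity of the
  opioid table's treatment-seeking row) both values are still simply
  evaluated. Rows whose lower, upper and base coincide (device price,
  structural zeros) are skipped — the price is owned by the threshold
  analysis. The two discount rates are separate entries. Grouped rows
  (treatment-state cost/utility; the AUD drinking mortality rate, which
  also backs the treatment states) move all their states together.
* **Two-way**: NMB over a grid of annual prices {100, 250, 350, 700} ×
  relapse-rate reductions {5, 10, 15, 20 %}, default 1-year horizon; cell
  (e, p) re-evaluates with `m = 1 − e` and a per-cycle price `p/4`.
* **Break-even**: NMB and ΔC are affine in the annual price (the charged
  alive mass does not depend on price), so the root follows exactly from
  two evaluations; the tests confirm agreement with numerical
  root-finding to 1e-6. The cost-neutral price depends on the horizon:
  longer horizons bank more treatment savings against the same four
  charged cycles (AUD: ≈£230/yr at 1 year, ≈£359/yr at 5 years).

## Synthetic parameter sets and the microsimulation oracle

`random_parameter_set` draws structurally valid parameterisations for
property tests: non-increasing relapse bands in [0.01, 0.5], utilities
ordered abstinence ≥ treatment ≥ relapse, costs in [0, 5000], relative
mortality rates in [0.5, 10], discount rates in [0, 0.05], effect
multipliers in [0.5, 1.1]. These ranges bracket the published values and
keep every draw admissible (e.g. `A·m ≤ 0.55`); the generator is
deterministic in its seed. It emulates parameter structure only — not
correlations between real-world parameters, patient heterogeneity, or
time-varying treatment quality — so passing property tests demonstrates
engine correctness over the valid parameter space, not clinical realism.

`microsim` pushes individual trajectories (categorical sampling) through
exactly the matrices the cohort engine uses and accrues costs, utilities,
charges and relapse person-cycles under the same conventions. Cohort
outputs equalling the Monte-Carlo means within 3 standard errors (tested
at n up to 200,000, both models and arms, plus random parameter sets)
validates the engine and economics arithmetic. A separate hand-computed
three-cycle trace in the test suite validates the AUD pathway translation
itself. The oracle deliberately shares the matrix builder, so it does not
re-test the pathway translation; it is a test instrument, not a research
simulator.

## Numerical choices

* Matrix rows are validated to sum to 1 within 1e-12; cohort mass is
  conserved within 1e-10 over 80 cycles; absorbing rows must be exact
  identity rows.
* Zero-effect parameter sets (m = 1, price 0) produce bitwise-identical
  arms, so incrementals are exactly 0.0, not merely small.
* CSV table cells round currency half-up to whole GBP (ties away from
  zero), relapses to 2 and QALYs to 4 decimals; the JSON companions keep
  full precision. Reports contain no timestamps; manifests carry content
  hashes so reruns are byte-identical.
* `savings_per_relapse_avoided` is `None` (not an exception) when the
  intervention does not reduce relapse burden.

## Reproduction tolerances and known limitations

Because the published record omits the baseline mortality level, the
cycle-accrual convention and the charging rule, reproduction of the
published model outputs is targeted at about ±10 % relative (±£15 absolute
for money values under £200), and the end-to-end tests assert at that
band. Within it, the package reproduces the alcohol model's 1-year
incrementals (cost difference, NMB, relapse difference, saving per relapse
avoided, and the published threshold-grid cells) and the opioid model's
cost and relapse columns.

One published quantity resists reproduction: the opioid model's 1-year
QALY difference (and hence its NMB and the high-price threshold cells).
With the published opioid utilities (abstinence 0.90, treatment 0.62 for
both MSW and MOUD, relapse 0.57), any accrual convention consistent with
the published relapse and cost columns yields an incremental QALY of
0.012–0.016, roughly twice the published 0.0068; solving the published
per-arm QALYs for the utilities instead implies a maintenance-state
utility above 1, which is inadmissible. The package implements the
published utilities and reports the larger QALY gain; the affected
end-to-end checks document this rather than adjusting inputs to match.
Five- and twenty-year opioid results are additionally sensitive to the
MOUD exit rate and mortality assumptions and should be read as
order-of-magnitude.

Other limitations: no probabilistic sensitivity analysis (deliberate for
an early model with no device-specific effectiveness data); health and
social care perspective only (no criminal-justice or welfare costs); no
polysubstance pathway; population-level NMB requires the user to supply an
eligible-population count (`population_nmb`) — no treatment statistics are
packaged.
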