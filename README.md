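# relapsehta

Early health-economic evaluation of a relapse-predicting digital technology
for people who have achieved abstinence after treatment for alcohol use
disorder (AUD) or opioid use disorder (OUD).

Relapse is the dominant clinical and economic risk in the first year after
abstinence. A digital device that flags imminent relapse lets clinicians
intervene early, reducing relapses, treatment episodes and their costs. At
the pre-clinical stage no device-specific effectiveness data exist, so the
question an early evaluation answers is *conditional*: **if** the device
reduces first-year relapse rates by some fraction, what may it cost per
patient per year and remain cost-effective (or outright cost-saving) for a
UK provider? The package is aimed at health economists and technology
developers doing this kind of early assessment.

## The models

Two deterministic Markov cohort models with quarterly (3-month) cycles:

* **AUD**: states *abstinence → relapse → treatment start → treatment
  continuation → (abstinence)*, plus absorbing *death*. Dropouts from
  treatment return to relapse; completing continuation means recovery.
* **OUD**: states *abstinence → relapse → medically supervised withdrawal
  (MSW) → medication for opioid use disorder (MOUD) → (abstinence)*, plus
  *death*. MOUD is open-ended maintenance: no relapse from MOUD, slow exit
  to abstinence.

Relapse risk from abstinence is a banded per-cycle probability `A(c)` (high
in year one, falling thereafter). Death is applied first each cycle at a
state-specific probability `q_s = RR_s · q0` (relative mortality rate times
a sex-blended baseline); the remaining transitions, conditional on
survival, are scaled by `1 − q_s`, so every row is stochastic by
construction.

The intervention arm multiplies the relapse transition by an effect
multiplier `m` (base 0.85, i.e. a 15 % reduction) and charges the device
price (base £25 per cycle, £100 per annum) for the first four cycles —
the provisioned year. The comparator arm is standard of care.

Outputs per horizon (1, 5, 20 years), discounted at 3.5 % per annum:

```
ΔC   incremental discounted cost (intervention − comparator)
ΔQ   incremental discounted QALYs (full-year utilities, quarter per cycle)
ΔR   incremental relapse burden (person-cycles spent in relapse)
NMB  = λ·ΔQ − ΔC   with λ = £20,000 per QALY
```

plus the saving per relapse avoided `−ΔC / −ΔR`, one-way sensitivity
analysis over the published parameter limits (tornado ordering), a two-way
price × effect threshold grid, and closed-form break-even prices
(`NMB = 0` or `ΔC = 0`, exact by price linearity).

A vectorised individual-level microsimulation consumes the same transition
matrices and serves as an independent oracle for the cohort arithmetic.

## Worked example

```python
from relapsehta import evaluate, fixture

_, params, limits = fixture("aud")
res = evaluate("aud", params, horizon_years=1)
print(f"dCost = {res.d_costs:.2f}  dQALY = {res.d_qalys:.4f}  "
      f"NMB = {res.nmb:.2f}  save/relapse = {res.savings_per_relapse_avoided:.0f}")
```

prints

```
dCost = -128.38  dQALY = 0.0019  NMB = 167.22  save/relapse = 1654
```

Over the first year the device saves about £128 per patient (fewer relapse
and treatment cycles more than offset the £100 device charge), gains a
small amount of quality-adjusted life, and yields a net monetary benefit of
about £167 at £20,000/QALY — cost-effective and cost-saving. The
`examples/` scripts walk through the base cases, the tornado analysis, the
threshold grid with break-even pricing, and the microsimulation
cross-check, each printing the numbers it computes.

The same analyses are available from a shell:

```sh
relapsehta run --model aud --horizons 1,5,20 --out reports
relapsehta owsa --model oud --out reports
relapsehta threshold --model oud --out reports
relapsehta breakeven --model aud --effect 0.15 --criterion cost_neutral
relapsehta validate --model aud
```

`run` writes a CSV in the published table layout with the stable header
`horizon_years,row,relapses,savings_per_relapse_avoided_gbp,qalys,costs_gbp,nmb_gbp`
(rows `SOC plus app`, `SOC`, `Difference per patient`; currency rounded
half-up to whole GBP) plus a full-precision JSON companion and a manifest
with content hashes. Tornado and threshold CSVs follow the layouts
documented in `relapsehta.reporting`.

## Layout

```
src/relapsehta/    library (parameters, markov, pathways, economics,
                   sensitivity, synthetic, reporting, cli)
src/relapsehta/fixtures/  packaged base-case parameter YAML for both models
examples/          narrative scripts, one per capability
tests/             pytest suite incl. end-to-end reproduction checks
docs/methods.md    model documentation and design choices
```
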