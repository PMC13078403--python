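"""Two-way threshold analysis and break-even pricing.

Maps 1-year NMB over a grid of annual device prices and relapse-rate
reductions, then solves (in closed form, from the price linearity of NMB
and cost difference) for the break-even annual price at the base 15 percent
effect.
"""

from relapsehta import (COST_NEUTRAL, NMB_ZERO, breakeven_price, fixture,
                        threshold_grid)

for model in ("aud", "oud"):
    _, params, _ = fixture(model)
    grid = threshold_grid(model, params)
    print(f"\n=== {model.upper()} 1-year NMB grid (GBP) ===")
    print(grid.to_frame().round(0).to_string())
    for criterion in (NMB_ZERO, COST_NEUTRAL):
        price = breakeven_price(model, params, 0.15, 1, criterion)
        print(f"break-even annual price ({criterion}, 15% effect, 1 year): "
              f"{price:.0f} GBP")

print("\nCells above zero are price/effect combinations at which the device"
      "\nis cost-effective; cost_neutral prices leave provider spend unchanged.")
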