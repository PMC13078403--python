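"""One-way sensitivity analysis: which parameters drive the result?

Each published parameter is moved to its printed lower and upper limit with
everything else at base; the entries are ranked by the larger NMB departure
from the base case (the ordering of a tornado diagram).
"""

from relapsehta import fixture, owsa

for model in ("aud", "oud"):
    _, params, limits = fixture(model)
    res = owsa(model, params, limits, horizon_years=1)
    print(f"\n=== {model.upper()} tornado (1-year NMB, base "
          f"{res.base_nmb:.0f} GBP) ===")
    for e in res.entries[:6]:
        print(f"{e.parameter:<32} low {e.nmb_at_lower:8.1f}  "
              f"high {e.nmb_at_upper:8.1f}  spread {e.spread:7.1f}")

print("\nOnly the device's own relapse effect can flip the NMB negative:"
      "\nevery other parameter moves both arms together and largely cancels.")
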