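"""Base-case cost-utility results for both pathway models.

Runs the packaged alcohol and opioid parameter sets over the three standard
horizons and prints per-arm and incremental discounted costs, QALYs,
relapse burden and net monetary benefit.
"""

from relapsehta import evaluate, fixture

for model in ("aud", "oud"):
    _, params, _ = fixture(model)
    print(f"\n=== {model.upper()} model ===")
    for horizon in (1, 5, 20):
        res = evaluate(model, params, horizon)
        print(f"{horizon:>2}-year horizon: "
              f"dCost = {res.d_costs:8.2f} GBP, "
              f"dQALY = {res.d_qalys:8.4f}, "
              f"dRelapses = {res.d_relapses:7.4f}, "
              f"NMB = {res.nmb:8.2f} GBP")
        spr = res.savings_per_relapse_avoided
        if spr is not None:
            print(f"               saving per relapse avoided = {spr:.0f} GBP")

print("\nA negative cost difference is a saving for the provider; a positive"
      "\nNMB means the device is cost-effective at 20,000 GBP per QALY.")
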