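"""Report writers: base-case tables, tornado tables, threshold grids.

CSV cells follow the published table layout — currency as whole GBP rounded
half-up, relapses to 2 decimals, QALYs to 4 — while a companion JSON file
retains full precision so rounding never contaminates downstream use.  All
output is deterministic for a given configuration; the run manifest records
the configuration and a content hash instead of timestamps.

Stable CSV headers (bit-exact interface):

* base case: ``horizon_years,row,relapses,savings_per_relapse_avoided_gbp,
  qalys,costs_gbp,nmb_gbp`` with rows ``SOC plus app`` / ``SOC`` /
  ``Difference per patient`` per horizon;
* tornado: ``parameter,base_value,lower_value,upper_value,nmb_at_lower,
  nmb_at_upper,base_nmb,spread``;
* threshold grid: first column ``effect``, then one column per annual price.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .economics import Accrual, EconResult
from .sensitivity import OWSAResult, ThresholdGrid

ROW_APP = "SOC plus app"
ROW_SOC = "SOC"
ROW_DIFF = "Difference per patient"

BASE_CASE_COLUMNS = ("horizon_years", "row", "relapses",
                     "savings_per_relapse_avoided_gbp", "qalys", "costs_gbp",
                     "nmb_gbp")


def round_gbp(value: float | None) -> int | None:
    """Whole pounds, ties away from zero (half-up on the magnitude)."""
    if value is None:
        return None
    q = Decimal(repr(float(value))).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    return int(q)


def base_case_frame(results: list[EconResult]) -> pd.DataFrame:
    """Printed-layout base-case table, one three-row block per horizon."""
    rows = []
    for res in results:
        rows.append({"horizon_years": res.horizon_years, "row": ROW_APP,
                     "relapses": round(res.app.relapses, 2),
                     "savings_per_relapse_avoided_gbp": None,
                     "qalys": round(res.app.qalys, 4),
                     "costs_gbp": round_gbp(res.app.costs), "nmb_gbp": None})
        rows.append({"horizon_years": res.horizon_years, "row": ROW_SOC,
                     "relapses": round(res.soc.relapses, 2),
                     "savings_per_relapse_avoided_gbp": None,
                     "qalys": round(res.soc.qalys, 4),
                     "costs_gbp": round_gbp(res.soc.costs), "nmb_gbp": None})
        spr = res.savings_per_relapse_avoided
        rows.append({"horizon_years": res.horizon_years, "row": ROW_DIFF,
                     "relapses": round(res.d_relapses, 2),
                     "savings_per_relapse_avoided_gbp": round_gbp(spr),
                     "qalys": round(res.d_qalys, 4),
                     "costs_gbp": round_gbp(res.d_costs),
                     "nmb_gbp": round_gbp(res.nmb)})
    return pd.DataFrame(rows, columns=list(BASE_CASE_COLUMNS))


def results_to_json(results: list[EconResult]) -> list[dict]:
    """Full-precision machine-readable form of the base-case results."""
    out = []
    for res in results:
        out.append({
            "model": res.model_id,
            "horizon_years": res.horizon_years,
            "wtp_per_qaly": res.wtp_per_qaly,
            "soc": asdict(res.soc),
            "soc_plus_app": asdict(res.app),
            "difference": {"qalys": res.d_qalys, "costs": res.d_costs,
                           "relapses": res.d_relapses},
            "nmb": res.nmb,
            "savings_per_relapse_avoided": res.savings_per_relapse_avoided,
        })
    return out


def _write(path: Path, text: str) -> str:
    path.write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


def write_run(outdir: str | Path, model_id: str, results: list[EconResult],
              accrual: Accrual, config: dict | None = None) -> dict:
    """Write base-case CSV + JSON and a manifest; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = base_case_frame(results)
    csv_hash = _write(outdir / f"{model_id}_base_case.csv",
                      frame.to_csv(index=False))
    json_hash = _write(outdir / f"{model_id}_base_case.json",
                       json.dumps(results_to_json(results), indent=2) + "\n")
    manifest = {
        "model": model_id,
        "horizons_years": [r.horizon_years for r in results],
        "accrual": {"costs": accrual.costs, "outcomes": accrual.outcomes},
        "config": config or {},
        "files": {f"{model_id}_base_case.csv": csv_hash,
                  f"{model_id}_base_case.json": json_hash},
    }
    _write(outdir / f"{model_id}_manifest.json",
           json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_owsa(outdir: str | Path, result: OWSAResult) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{result.model_id}_owsa.csv"
    result.to_frame().to_csv(path, index=False)
    return path


def write_threshold(outdir: str | Path, grid: ThresholdGrid,
                    rounded: bool = True) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = grid.to_frame()
    if rounded:
        frame = frame.map(round_gbp)
    path = outdir / f"{grid.model_id}_threshold.csv"
    frame.to_csv(path)
    (outdir / f"{grid.model_id}_threshold.json").write_text(json.dumps({
        "model": grid.model_id,
        "horizon_years": grid.horizon_years,
        "prices_per_annum": list(grid.prices_per_annum),
        "effect_reductions": list(grid.effect_reductions),
        "nmb": grid.nmb.tolist(),
    }, indent=2) + "\n")
    return path
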