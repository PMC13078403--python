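"""Parameter types, packaged base-case parameter sets, and config-file IO.

The two decision models share one parameter container.  Every transition
probability is a per-3-month-cycle probability; relapse risk is banded over
cycles (high in the first year after abstinence, falling thereafter).
Utilities are full-year values (a cycle accrues one quarter of the stated
utility), costs are GBP per state per cycle, and mortality enters as
relative rates against a baseline all-cause annual probability blended over
sex.  The baseline mortality level is an implementation-supplied assumption
(no published figure accompanies the relative rates); see ``docs/methods.md``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml

try:  # Python >= 3.9
    from importlib import resources
except ImportError:  # pragma: no cover
    import importlib_resources as resources  # type: ignore

log = logging.getLogger(__name__)

SCHEMA_ID = "relapsehta-params/1"
DEFAULT_WTP = 20_000.0

AUD = "aud"
OUD = "oud"
MODEL_IDS = (AUD, OUD)

AUD_STATES = ("abstinence", "relapse", "treatment_start",
              "treatment_continuation", "death")
OUD_STATES = ("abstinence", "relapse", "msw", "moud", "death")


class SchemaError(ValueError):
    """Parameter file violates the published schema (lists offending keys)."""

    def __init__(self, message: str, keys: Iterable[str] = ()):
        self.keys = tuple(keys)
        if self.keys:
            message = f"{message}: {', '.join(self.keys)}"
        super().__init__(message)


class ParameterRangeError(ValueError):
    """A numeric parameter is outside its admissible range."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered state labels of one model plus its absorbing set."""

    model_id: str
    states: tuple[str, ...]
    absorbing: frozenset[str] = frozenset({"death"})

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise SchemaError("duplicate state names", self.states)
        if not self.absorbing <= set(self.states):
            raise SchemaError("absorbing states not in state list",
                              sorted(self.absorbing - set(self.states)))
        if "death" not in self.absorbing:
            raise SchemaError("death must be absorbing")

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def transient(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s not in self.absorbing)

    @property
    def treatment_states(self) -> tuple[str, ...]:
        """The two in-treatment states (start/continuation or msw/moud)."""
        return tuple(s for s in self.states
                     if s not in ("abstinence", "relapse", "death"))


def aud_space() -> StateSpace:
    return StateSpace(AUD, AUD_STATES)


def oud_space() -> StateSpace:
    return StateSpace(OUD, OUD_STATES)


def space_for(model_id: str) -> StateSpace:
    if model_id == AUD:
        return aud_space()
    if model_id == OUD:
        return oud_space()
    raise SchemaError("unknown model id", [model_id])


@dataclass(frozen=True)
class BandedRate:
    """Piecewise-constant per-cycle probability over 1-based cycle bands.

    ``bands`` is a sequence of ``(first_cycle, prob)``; each band applies
    from its first cycle until the next band begins, the last band applying
    indefinitely.
    """

    bands: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands",
                           tuple((int(c), float(p)) for c, p in self.bands))
        if not self.bands:
            raise SchemaError("banded rate needs at least one band")
        firsts = [c for c, _ in self.bands]
        if firsts[0] != 1:
            raise SchemaError("first band must start at cycle 1")
        if any(b >= a for b, a in zip(firsts, firsts[1:])):
            raise SchemaError("band start cycles must be strictly increasing")
        bad = [f"band{i + 1}" for i, (_, p) in enumerate(self.bands)
               if not 0.0 <= p <= 1.0]
        if bad:
            raise ParameterRangeError(
                f"band probabilities outside [0, 1]: {', '.join(bad)}")

    def at(self, cycle: int) -> float:
        """Probability of the band containing ``cycle`` (1-based)."""
        if cycle < 1:
            raise ParameterRangeError(f"cycle must be >= 1, got {cycle}")
        prob = self.bands[0][1]
        for first, p in self.bands:
            if cycle >= first:
                prob = p
            else:
                break
        return prob


@dataclass(frozen=True)
class PathwayParams:
    """All transition, cost, utility, mortality and intervention parameters.

    ``mortality_rr``, ``state_cost_per_cycle`` and ``utility_full_year`` map
    non-death state names to values.  ``seeking_effect_multiplier`` and
    ``recovery_effect_multiplier`` are hooks for intervention effects beyond
    the relapse rate; they default to 1 (no effect in the base case).
    """

    relapse_rate: BandedRate
    treatment_seeking: float
    treatment_continuation: float
    recovery_after_treatment: float
    spontaneous_recovery: float
    mortality_rr: Mapping[str, float]
    prop_male: float
    state_cost_per_cycle: Mapping[str, float]
    utility_full_year: Mapping[str, float]
    baseline_annual_mortality_male: float = 0.0025
    baseline_annual_mortality_female: float = 0.0016
    discount_rate_costs: float = 0.035
    discount_rate_outcomes: float = 0.035
    wtp_per_qaly: float = DEFAULT_WTP
    app_effect_multiplier: float = 0.85
    app_cost_per_cycle: float = 25.0
    app_active_cycles: int = 4
    seeking_effect_multiplier: float = 1.0
    recovery_effect_multiplier: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mortality_rr", dict(self.mortality_rr))
        object.__setattr__(self, "state_cost_per_cycle",
                           dict(self.state_cost_per_cycle))
        object.__setattr__(self, "utility_full_year",
                           dict(self.utility_full_year))

    # Derived complements -------------------------------------------------
    @property
    def dropout(self) -> float:
        """Probability of leaving treatment after the first cycle."""
        return 1.0 - self.treatment_continuation

    @property
    def nonrecovery(self) -> float:
        """Probability of relapsing on completing treatment."""
        return 1.0 - self.recovery_after_treatment

    def baseline_annual_mortality(self) -> float:
        """Sex-blended annual all-cause mortality of the cohort."""
        return (self.prop_male * self.baseline_annual_mortality_male
                + (1.0 - self.prop_male) * self.baseline_annual_mortality_female)

    def baseline_cycle_mortality(self) -> float:
        """Per-cycle baseline mortality, 1 - (1 - p_annual)^(1/4)."""
        return 1.0 - (1.0 - self.baseline_annual_mortality()) ** 0.25

    def validate(self, space: StateSpace) -> None:
        """Raise on any out-of-range value or state-map mismatch."""
        probs = {
            "treatment_seeking": self.treatment_seeking,
            "treatment_continuation": self.treatment_continuation,
            "recovery_after_treatment": self.recovery_after_treatment,
            "spontaneous_recovery": self.spontaneous_recovery,
            "prop_male": self.prop_male,
            "baseline_annual_mortality_male": self.baseline_annual_mortality_male,
            "baseline_annual_mortality_female": self.baseline_annual_mortality_female,
        }
        bad = [k for k, v in probs.items() if not 0.0 <= v <= 1.0]
        if bad:
            raise ParameterRangeError(
                f"probabilities outside [0, 1]: {', '.join(sorted(bad))}")
        if self.treatment_seeking + self.spontaneous_recovery > 1.0 + 1e-12:
            raise ParameterRangeError(
                "treatment_seeking + spontaneous_recovery exceeds 1")
        expected = set(space.transient)
        for name, mapping, lo_ok in (
            ("mortality_rr", self.mortality_rr, lambda v: v >= 0),
            ("state_cost_per_cycle", self.state_cost_per_cycle, lambda v: v >= 0),
            ("utility_full_year", self.utility_full_year,
             lambda v: 0.0 <= v <= 1.0),
        ):
            if set(mapping) != expected:
                raise SchemaError(
                    f"{name} must map exactly the non-death states",
                    sorted(set(mapping) ^ expected))
            bad = [f"{name}.{k}" for k, v in mapping.items() if not lo_ok(v)]
            if bad:
                raise ParameterRangeError(
                    f"values out of range: {', '.join(sorted(bad))}")
        for name, v in (("app_effect_multiplier", self.app_effect_multiplier),
                        ("seeking_effect_multiplier", self.seeking_effect_multiplier),
                        ("recovery_effect_multiplier", self.recovery_effect_multiplier),
                        ("app_cost_per_cycle", self.app_cost_per_cycle),
                        ("wtp_per_qaly", self.wtp_per_qaly)):
            if v < 0:
                raise ParameterRangeError(f"{name} must be >= 0, got {v}")
        if self.app_active_cycles < 0:
            raise ParameterRangeError("app_active_cycles must be >= 0")
        for name, r in (("discount_rate_costs", self.discount_rate_costs),
                        ("discount_rate_outcomes", self.discount_rate_outcomes)):
            if r < 0:
                raise ParameterRangeError(f"{name} must be >= 0, got {r}")


@dataclass(frozen=True)
class SensitivityLimits:
    """Printed (lower, upper) bounds per canonical parameter name.

    Bounds are stored as printed; a lower bound above the base (or upper
    below it) is legal and the sensitivity analysis simply evaluates both.
    """

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bounds",
            {k: (float(v[0]), float(v[1])) for k, v in dict(self.bounds).items()})

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bounds

    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)


class ModelInputs(NamedTuple):
    """One model's state space, base-case parameters and printed limits."""

    space: StateSpace
    params: PathwayParams
    limits: SensitivityLimits


# ---------------------------------------------------------------------------
# Canonical parameter names: getters/setters used by files and sensitivity.
# Grouped names ("*.treatment", AUD "mortality_rr.relapse") move every state
# that shares the printed estimate.

def _states_for_group(space: StateSpace, group: str) -> tuple[str, ...]:
    if group == "treatment":
        return space.treatment_states
    return (group,)


def get_param(space: StateSpace, params: PathwayParams, name: str) -> float:
    """Base value behind a canonical parameter name."""
    if name.startswith("relapse_rate.band"):
        i = int(name.rsplit("band", 1)[1]) - 1
        return params.relapse_rate.bands[i][1]
    if "." in name:
        attr, group = name.split(".", 1)
        if attr not in ("mortality_rr", "state_cost_per_cycle",
                        "utility_full_year"):
            raise SchemaError("unknown parameter name", [name])
        mapping = getattr(params, attr)
        state = _states_for_group(space, group)[0]
        if state not in mapping:
            raise SchemaError("unknown parameter name", [name])
        return mapping[state]
    if name == "relapse_rate" or not hasattr(params, name):
        raise SchemaError("unknown parameter name", [name])
    return getattr(params, name)


def set_param(space: StateSpace, params: PathwayParams, name: str,
              value: float) -> PathwayParams:
    """Return a copy of ``params`` with the named parameter set to ``value``."""
    if name.startswith("relapse_rate.band"):
        i = int(name.rsplit("band", 1)[1]) - 1
        bands = list(params.relapse_rate.bands)
        if not 0 <= i < len(bands):
            raise SchemaError("unknown relapse band", [name])
        bands[i] = (bands[i][0], float(value))
        return replace(params, relapse_rate=BandedRate(tuple(bands)))
    if "." in name:
        attr, group = name.split(".", 1)
        if attr not in ("mortality_rr", "state_cost_per_cycle",
                        "utility_full_year"):
            raise SchemaError("unknown parameter name", [name])
        mapping = dict(getattr(params, attr))
        targets = _states_for_group(space, group)
        unknown = [s for s in targets if s not in mapping]
        if unknown:
            raise SchemaError("unknown parameter name", [name])
        if attr == "mortality_rr" and group == "relapse":
            # The recently-using relative mortality estimate also backs the
            # AUD treatment states (shared source); move them together.
            if space.model_id == AUD:
                targets = targets + space.treatment_states
        for s in targets:
            mapping[s] = float(value)
        return replace(params, **{attr: mapping})
    if not hasattr(params, name) or name in ("relapse_rate",):
        raise SchemaError("unknown parameter name", [name])
    return replace(params, **{name: float(value)})


# ---------------------------------------------------------------------------
# File IO

_SCALARS = (
    "treatment_seeking", "treatment_continuation", "recovery_after_treatment",
    "spontaneous_recovery", "prop_male", "baseline_annual_mortality_male",
    "baseline_annual_mortality_female", "discount_rate_costs",
    "discount_rate_outcomes", "wtp_per_qaly", "app_effect_multiplier",
    "app_cost_per_cycle", "app_active_cycles", "seeking_effect_multiplier",
    "recovery_effect_multiplier",
)
_MAPS = ("mortality_rr", "state_cost_per_cycle", "utility_full_year")
_TOP_KEYS = {"schema", "model", "relapse_rate", "limits", *_SCALARS, *_MAPS}
_OPTIONAL = {"wtp_per_qaly", "limits", "seeking_effect_multiplier",
             "recovery_effect_multiplier", "baseline_annual_mortality_male",
             "baseline_annual_mortality_female"}


def _inputs_to_dict(inputs: ModelInputs) -> dict:
    p = inputs.params
    doc: dict = {"schema": SCHEMA_ID, "model": inputs.space.model_id}
    doc["relapse_rate"] = [{"first_cycle": c, "prob": v}
                           for c, v in p.relapse_rate.bands]
    for key in _SCALARS:
        doc[key] = getattr(p, key)
    for key in _MAPS:
        doc[key] = dict(getattr(p, key))
    doc["limits"] = {k: list(v) for k, v in inputs.limits.bounds.items()}
    return doc


def _inputs_from_dict(doc: dict, origin: str = "<dict>") -> ModelInputs:
    if not isinstance(doc, dict):
        raise SchemaError(f"{origin}: parameter document must be a mapping")
    unknown = sorted(set(doc) - _TOP_KEYS)
    if unknown:
        raise SchemaError(f"{origin}: unknown keys", unknown)
    missing = sorted(_TOP_KEYS - _OPTIONAL - set(doc))
    if missing:
        raise SchemaError(f"{origin}: missing keys", missing)
    if doc["schema"] != SCHEMA_ID:
        raise SchemaError(f"{origin}: unsupported schema", [str(doc["schema"])])
    space = space_for(doc["model"])
    if "wtp_per_qaly" not in doc:
        log.warning("%s: wtp_per_qaly missing, using default %.0f",
                    origin, DEFAULT_WTP)
    bands = tuple((b["first_cycle"], b["prob"]) for b in doc["relapse_rate"])
    kwargs = {k: doc[k] for k in _SCALARS if k in doc}
    kwargs["app_active_cycles"] = int(kwargs.get("app_active_cycles", 4))
    params = PathwayParams(
        relapse_rate=BandedRate(bands),
        mortality_rr=doc["mortality_rr"],
        state_cost_per_cycle=doc["state_cost_per_cycle"],
        utility_full_year=doc["utility_full_year"],
        **kwargs,
    )
    params.validate(space)
    limits = SensitivityLimits(
        {k: tuple(v) for k, v in doc.get("limits", {}).items()})
    for name, (lo, hi) in limits.bounds.items():
        get_param(space, params, name)  # raises SchemaError if unknown
        if lo > hi:
            # stored as printed; evaluation uses min/max of the pair
            log.debug("%s: limits for %s are inverted (%s > %s)",
                      origin, name, lo, hi)
    return ModelInputs(space, params, limits)


def load_params(path: str | Path) -> ModelInputs:
    """Load a YAML (or JSON) parameter file and validate it."""
    path = Path(path)
    text = path.read_text()
    doc = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text))
    return _inputs_from_dict(doc, origin=str(path))


def write_params(inputs: ModelInputs, path: str | Path) -> Path:
    """Write a parameter set to YAML (or JSON by extension); round-trip safe."""
    path = Path(path)
    doc = _inputs_to_dict(inputs)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def _load_fixture(name: str) -> ModelInputs:
    ref = resources.files("relapsehta") / "fixtures" / f"{name}.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _inputs_from_dict(doc, origin=f"fixture:{name}")


def fixture_aud() -> ModelInputs:
    """Packaged base-case parameter set for the alcohol pathway."""
    return _load_fixture(AUD)


def fixture_oud() -> ModelInputs:
    """Packaged base-case parameter set for the opioid pathway."""
    return _load_fixture(OUD)


def fixture(model_id: str) -> ModelInputs:
    return _load_fixture(space_for(model_id).model_id)
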