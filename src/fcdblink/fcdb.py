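"""Food-composition-database (FCDB) data model and component harmonization.

An FCDB is a table of food items by nutritional components, expressed per
100 g of the edible part.  Each cell carries a value *state*: a measured
amount, a trace flag (below the analytical quantification criterion), a
missing cell, or an imputed amount with the imputation method recorded.

This module owns

* the component registry (codes, units, trace thresholds),
* the trace-resolution rule (<0.6 / <0.06 / <0.006 -> 0.5 / 0.05 / 0.005),
* the definitional formulas that align component definitions between two
  databases (available carbohydrates, vitamin A and E equivalents,
  short-chain saturated fatty acids, residual PUFAs),
* plain-text FCDB file I/O with configurable trace/missing sentinels.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Unit",
    "ValueState",
    "MissingPolicy",
    "ComponentDef",
    "ComponentRegistry",
    "NutrientValue",
    "FoodItem",
    "FcdbError",
    "MissingSummandWarning",
    "NegativeValueWarning",
    "TRACE_IMPUTED",
    "KJ_PER_KCAL",
    "impute_trace",
    "available_carbohydrates",
    "beta_carotene_equivalents",
    "retinol_equivalent",
    "alpha_tocopherol_equivalents",
    "short_chain_sfa",
    "other_pufas",
    "kcal_to_kj",
    "default_registry",
    "load_fcdb",
    "write_fcdb",
]

KJ_PER_KCAL = 4.184

#: trace threshold -> imputed constant (same unit as the component)
TRACE_IMPUTED: dict[float, float] = {0.6: 0.5, 0.06: 0.05, 0.006: 0.005}


class FcdbError(ValueError):
    """Raised on FCDB contract violations (bad state, unknown component...)."""


class MissingSummandWarning(UserWarning):
    """A missing summand was treated as zero in a derived component."""


class NegativeValueWarning(UserWarning):
    """A derived amount was negative and floored at zero."""


class Unit(str, enum.Enum):
    G = "g"
    MG = "mg"
    UG = "μg"
    KCAL = "kcal"
    KJ = "kJ"


class ValueState(str, enum.Enum):
    MEASURED = "measured"
    TRACE = "trace"
    MISSING = "missing"
    IMPUTED = "imputed"


class MissingPolicy(str, enum.Enum):
    """What to do with a missing summand inside a derived component."""

    ZERO_WITH_FLAG = "zero_with_flag"
    PROPAGATE = "propagate"


@dataclass(frozen=True)
class ComponentDef:
    """One registered component: code, display name, unit, trace threshold.

    ``trace_threshold`` is the analytical quantification criterion under
    which the database records a trace flag instead of an amount; ``None``
    for components that never carry trace flags.
    """

    code: str
    name: str
    unit: Unit
    trace_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.trace_threshold is not None and self.trace_threshold not in TRACE_IMPUTED:
            raise FcdbError(
                f"component {self.code!r}: trace threshold must be one of "
                f"{sorted(TRACE_IMPUTED)} or None, got {self.trace_threshold}"
            )


class ComponentRegistry:
    """Ordered, code-unique collection of :class:`ComponentDef`."""

    def __init__(self, components: Iterable[ComponentDef]):
        self._defs: dict[str, ComponentDef] = {}
        for c in components:
            if c.code in self._defs:
                raise FcdbError(f"duplicate component code {c.code!r}")
            self._defs[c.code] = c

    @property
    def codes(self) -> list[str]:
        return list(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self) -> Iterator[ComponentDef]:
        return iter(self._defs.values())

    def __contains__(self, code: str) -> bool:
        return code in self._defs

    def __getitem__(self, code: str) -> ComponentDef:
        try:
            return self._defs[code]
        except KeyError:
            raise FcdbError(f"unknown component code {code!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComponentRegistry":
        """Read a registry file with columns code,name,unit,trace_threshold."""
        defs = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                thr = row.get("trace_threshold", "").strip()
                defs.append(
                    ComponentDef(
                        code=row["code"].strip(),
                        name=row["name"].strip(),
                        unit=Unit(row["unit"].strip()),
                        trace_threshold=float(thr) if thr else None,
                    )
                )
        return cls(defs)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "name", "unit", "trace_threshold"])
            for c in self:
                w.writerow([c.code, c.name, c.unit.value,
                            "" if c.trace_threshold is None else c.trace_threshold])


@dataclass(frozen=True)
class NutrientValue:
    """An amount per 100 g edible part together with its value state."""

    amount: float | None
    state: ValueState
    method: str | None = None  # imputation strategy tag when state == IMPUTED

    def __post_init__(self) -> None:
        has_amount = self.amount is not None
        if self.state in (ValueState.MEASURED, ValueState.IMPUTED) and not has_amount:
            raise FcdbError(f"state {self.state.value} requires an amount")
        if self.state in (ValueState.TRACE, ValueState.MISSING) and has_amount:
            raise FcdbError(f"state {self.state.value} must not carry an amount")
        if self.state is ValueState.IMPUTED and not self.method:
            raise FcdbError("imputed value requires a method tag")

    @classmethod
    def measured(cls, amount: float) -> "NutrientValue":
        return cls(float(amount), ValueState.MEASURED)

    @classmethod
    def trace(cls) -> "NutrientValue":
        return cls(None, ValueState.TRACE)

    @classmethod
    def missing(cls) -> "NutrientValue":
        return cls(None, ValueState.MISSING)

    @classmethod
    def imputed(cls, amount: float, method: str) -> "NutrientValue":
        return cls(float(amount), ValueState.IMPUTED, method)

    @property
    def resolved(self) -> bool:
        return self.state in (ValueState.MEASURED, ValueState.IMPUTED)


@dataclass
class FoodItem:
    """One FCDB entry: a component->value map per 100 g edible part."""

    food_id: str
    name: str
    cooked: bool
    values: dict[str, NutrientValue] = field(default_factory=dict)

    def amount(self, code: str) -> float | None:
        v = self.values.get(code)
        return v.amount if v is not None and v.resolved else None

    @property
    def finalized(self) -> bool:
        """True when every component value is measured or imputed."""
        return all(v.resolved for v in self.values.values())

    def validate_against(self, registry: ComponentRegistry) -> None:
        got, want = set(self.values), set(registry.codes)
        if got != want:
            extra, miss = sorted(got - want), sorted(want - got)
            raise FcdbError(
                f"item {self.food_id!r} keyed off-registry "
                f"(extra={extra}, absent={miss})"
            )


# --------------------------------------------------------------------------
# trace resolution

def impute_trace(value: NutrientValue, definition: ComponentDef) -> NutrientValue:
    """Resolve a trace flag to the threshold-specific constant.

    Trace amounts sit below the analytical criterion (<0.6, <0.06 or
    <0.006 in the component's unit) and are imputed as 0.5, 0.05 and
    0.005 respectively.
    """
    if value.state is not ValueState.TRACE:
        raise FcdbError("impute_trace expects a value in state 'trace'")
    if definition.trace_threshold is None:
        raise FcdbError(
            f"component {definition.code!r} has no trace threshold; "
            "a trace flag on it is invalid"
        )
    return NutrientValue.imputed(TRACE_IMPUTED[definition.trace_threshold], "trace-rule")


# --------------------------------------------------------------------------
# definitional harmonization formulas
#
# All formulas are linear with non-negative weights; missing summands are
# handled per MissingPolicy (default: treat as zero, emit a warning), except
# available_carbohydrates where a missing input propagates.

def _linear(
    terms: Sequence[float | None],
    weights: Sequence[float],
    policy: MissingPolicy,
    what: str,
) -> float | None:
    if all(t is None for t in terms):
        return None
    if any(t is None for t in terms):
        if policy is MissingPolicy.PROPAGATE:
            return None
        warnings.warn(
            f"{what}: missing summand treated as 0", MissingSummandWarning,
            stacklevel=3,
        )
    return float(sum(w * t for w, t in zip(weights, terms) if t is not None))


def available_carbohydrates(
    carb_by_difference: float | None, total_fiber: float | None
) -> float | None:
    """Carbohydrate-by-difference minus total dietary fiber, floored at 0.

    Returns ``None`` when either input is missing.
    """
    if carb_by_difference is None or total_fiber is None:
        return None
    out = carb_by_difference - total_fiber
    if out < 0:
        warnings.warn(
            f"available carbohydrates negative ({out:.4g} g); floored at 0",
            NegativeValueWarning, stacklevel=2,
        )
        out = 0.0
    return float(out)


def beta_carotene_equivalents(
    beta: float | None, alpha: float | None, cryptoxanthin: float | None,
    policy: MissingPolicy = MissingPolicy.ZERO_WITH_FLAG,
) -> float | None:
    """1 β-carotene + 0.5 α-carotene + 0.5 β-cryptoxanthin (μg)."""
    return _linear([beta, alpha, cryptoxanthin], [1.0, 0.5, 0.5], policy,
                   "β-carotene equivalents")


def retinol_equivalent(
    retinol: float | None, bce: float | None,
    policy: MissingPolicy = MissingPolicy.ZERO_WITH_FLAG,
) -> float | None:
    """Retinol + 1/6 β-carotene equivalents (μg)."""
    return _linear([retinol, bce], [1.0, 1.0 / 6.0], policy, "retinol equivalent")


def alpha_tocopherol_equivalents(
    alpha_toc: float | None, beta_toc: float | None, gamma_toc: float | None,
    delta_toc: float | None, alpha_t3: float | None, beta_t3: float | None,
    gamma_t3: float | None,
    policy: MissingPolicy = MissingPolicy.ZERO_WITH_FLAG,
) -> float | None:
    """α-T + 0.4 β-T + 0.1 γ-T + 0.01 δ-T + 0.3 α-T3 + 0.05 β-T3 + 0.01 γ-T3 (mg)."""
    return _linear(
        [alpha_toc, beta_toc, gamma_toc, delta_toc, alpha_t3, beta_t3, gamma_t3],
        [1.0, 0.4, 0.1, 0.01, 0.3, 0.05, 0.01],
        policy, "α-tocopherol equivalents",
    )


def short_chain_sfa(
    c4: float | None, c6: float | None, c8: float | None, c10: float | None,
    policy: MissingPolicy = MissingPolicy.ZERO_WITH_FLAG,
) -> float | None:
    """Sum of butyric (C4:0), caproic (C6:0), caprylic (C8:0), capric (C10:0) acids."""
    return _linear([c4, c6, c8, c10], [1.0] * 4, policy, "short-chain SFA")


def other_pufas(
    pufa_components: Mapping[str, float | None],
    pufa_codes: Sequence[str] | None = None,
    policy: MissingPolicy = MissingPolicy.ZERO_WITH_FLAG,
) -> float:
    """Sum source-only PUFA components into a residual "other PUFAs" value.

    ``pufa_codes`` restricts the sum to a configured list of codes present
    in the source database but absent from the target one; by default every
    key of the mapping is summed.  Missing entries are skipped (flagged via
    :class:`MissingSummandWarning` under the default policy); an empty map
    sums to 0.
    """
    codes = list(pufa_codes) if pufa_codes is not None else list(pufa_components)
    terms = [pufa_components.get(c) for c in codes]
    if not terms or all(t is None for t in terms):
        if any(t is None for t in terms):
            warnings.warn("other PUFAs: all summands missing, returning 0",
                          MissingSummandWarning, stacklevel=2)
        return 0.0
    out = _linear(terms, [1.0] * len(terms), policy, "other PUFAs")
    return 0.0 if out is None else out


def kcal_to_kj(kcal: float) -> float:
    return kcal * KJ_PER_KCAL


# --------------------------------------------------------------------------
# default registry (synthetic 20-component set)

def default_registry() -> ComponentRegistry:
    """A compact 20-component registry used by the synthetic data bundle."""
    G, MG, UG, KCAL, KJ = Unit.G, Unit.MG, Unit.UG, Unit.KCAL, Unit.KJ
    return ComponentRegistry([
        ComponentDef("energy_kcal", "Energy", KCAL),
        ComponentDef("energy_kj", "Energy", KJ),
        ComponentDef("water", "Water", G),
        ComponentDef("protein", "Total proteins", G),
        ComponentDef("fat", "Total fats", G),
        ComponentDef("carb", "Available carbohydrates", G),
        ComponentDef("fiber", "Total dietary fiber", G),
        ComponentDef("alcohol", "Alcohol", G),
        ComponentDef("ash", "Ash", G),
        ComponentDef("sodium", "Sodium", MG),
        ComponentDef("chloride", "Chloride", MG),
        ComponentDef("potassium", "Potassium", MG),
        ComponentDef("calcium", "Calcium", MG),
        ComponentDef("iron", "Iron", MG, trace_threshold=0.06),
        ComponentDef("zinc", "Zinc", MG, trace_threshold=0.06),
        ComponentDef("retinol", "Retinol", UG, trace_threshold=0.6),
        ComponentDef("beta_carotene", "β-carotene", UG),
        ComponentDef("vitamin_d", "Vitamin D", UG, trace_threshold=0.06),
        ComponentDef("alpha_tocopherol", "α-tocopherol", MG, trace_threshold=0.006),
        ComponentDef("vitamin_b12", "Vitamin B12", UG, trace_threshold=0.06),
    ])


# --------------------------------------------------------------------------
# file I/O
#
# One row per food item; fixed columns food_id,name,cooked then one column
# per registry code.  Cells hold a number, the trace sentinel, or the
# missing sentinel.

def load_fcdb(
    path: str | Path,
    registry: ComponentRegistry,
    trace_token: str = "tr",
    missing_token: str = "",
) -> list[FoodItem]:
    items: list[FoodItem] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        absent = [c for c in registry.codes if c not in cols]
        if absent:
            raise FcdbError(f"FCDB file {path} lacks component columns {absent}")
        for i, row in enumerate(reader, start=2):
            values: dict[str, NutrientValue] = {}
            for code in registry.codes:
                cell = (row[code] or "").strip()
                if cell == missing_token:
                    values[code] = NutrientValue.missing()
                elif cell == trace_token:
                    values[code] = NutrientValue.trace()
                else:
                    try:
                        values[code] = NutrientValue.measured(float(cell))
                    except ValueError:
                        raise FcdbError(
                            f"{path}:{i}: non-numeric cell {cell!r} for {code!r}"
                        ) from None
            items.append(FoodItem(
                food_id=row["food_id"].strip(),
                name=row.get("name", "").strip(),
                cooked=row.get("cooked", "0").strip() in ("1", "true", "True"),
                values=values,
            ))
    return items


def write_fcdb(
    items: Sequence[FoodItem],
    path: str | Path,
    registry: ComponentRegistry,
    trace_token: str = "tr",
    missing_token: str = "",
    float_fmt: str = "%.6g",
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["food_id", "name", "cooked", *registry.codes])
        for item in items:
            row: list[str] = [item.food_id, item.name, "1" if item.cooked else "0"]
            for code in registry.codes:
                v = item.values.get(code, NutrientValue.missing())
                if v.state is ValueState.MISSING:
                    row.append(missing_token)
                elif v.state is ValueState.TRACE:
                    row.append(trace_token)
                else:
                    assert v.amount is not None
                    row.append(float_fmt % v.amount)
            w.writerow(row)


def finalize_traces(item: FoodItem, registry: ComponentRegistry) -> FoodItem:
    """Return a copy with every trace flag resolved via :func:`impute_trace`."""
    values = {
        code: impute_trace(v, registry[code]) if v.state is ValueState.TRACE else v
        for code, v in item.values.items()
    }
    return replace(item, values=values)
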