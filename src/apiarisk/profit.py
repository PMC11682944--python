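"""Colony-level beekeeper profit under pesticide-exposure scenarios.

The model represents a beekeeper who produces honey and rents colonies for
commercial blueberry pollination.  Per-colony seasonal profit is

    π = (1 − h) · P · Q  +  RF  −  (Cop + Crep)

with P the honey price ($/lb), Q the effective honey yield (whole lbs),
RF the pollination rental fee, Cop the seasonal operating cost, Crep the
colony replacement cost (0 when the colony survives), and h ∈ [0, 1] a
health variable scaling honey revenue down for indirect (behavioural /
physiological) effects: h = 0 means no indirect impact, h = 1 a total
productivity loss.

Scenarios are a timing × effect × replacement grid.  Sublethal exposure
manifesting in early summer cuts the honey crop by 30% (the colony is
impaired all season); manifesting in fall by 7%; a colony that dies in fall
is assumed to have produced 18.5% less (the midpoint) before failing, while
a colony that dies in early summer produces nothing.  Dead colonies are
replaced either by a purchased package or by splitting an existing colony
and adding a purchased or in-house queen.

All currency arithmetic is exact decimal (cents); reduced yields are
rounded half-up to whole pounds before revenue is computed.
"""

from __future__ import annotations

import enum
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Timing",
    "Effect",
    "Replacement",
    "Scenario",
    "ProfitParameters",
    "SensitivityOverride",
    "BREAK_EVEN_NEVER",
    "BREAK_EVEN_ALWAYS",
    "DEFAULT_SENSITIVITY_OVERRIDES",
    "effective_honey_yield",
    "colony_profit",
    "profit_at",
    "break_even_health",
    "scenario_grid",
    "sensitivity_analysis",
    "profit_curve",
]

CENT = Decimal("0.01")

#: Sentinel: the cell is unprofitable even at h = 0 (no positive break-even h).
BREAK_EVEN_NEVER = "none (<0)"
#: Sentinel: the cell is profitable even at h = 1.
BREAK_EVEN_ALWAYS = "any"


class Timing(str, enum.Enum):
    NONE = "none"
    EARLY_SUMMER = "early_summer"
    FALL = "fall"


class Effect(str, enum.Enum):
    NONE = "none"
    SUBLETHAL = "sublethal"
    LETHAL = "lethal"


class Replacement(str, enum.Enum):
    NOT_APPLICABLE = "not_applicable"
    PACKAGE = "package"
    SPLIT_PURCHASED_QUEEN = "split_purchased_queen"
    SPLIT_INHOUSE_QUEEN = "split_inhouse_queen"


class ProfitParameters(BaseModel):
    """Economic parameters, pound basis (price $/lb × yield in whole lbs)."""

    model_config = ConfigDict(frozen=True)

    honey_price_per_lb: Decimal = Decimal("8.42")
    base_honey_yield_lb: int = Field(59, ge=0)
    rental_fee: Decimal = Decimal("124")
    operating_cost: Decimal = Decimal("400")
    replacement_cost_package: Decimal = Decimal("240")
    replacement_cost_split_purchased_queen: Decimal = Decimal("55")
    replacement_cost_split_inhouse_queen: Decimal = Decimal("28.75")
    reduction_sublethal_summer: Decimal = Decimal("0.30")
    reduction_sublethal_fall: Decimal = Decimal("0.07")
    reduction_lethal_fall: Decimal = Decimal("0.185")

    @model_validator(mode="after")
    def _validate(self) -> "ProfitParameters":
        money = [
            self.honey_price_per_lb,
            self.rental_fee,
            self.operating_cost,
            self.replacement_cost_package,
            self.replacement_cost_split_purchased_queen,
            self.replacement_cost_split_inhouse_queen,
        ]
        if any(m < 0 for m in money):
            raise ValueError("monetary parameters must be non-negative")
        for name in ("reduction_sublethal_summer", "reduction_sublethal_fall", "reduction_lethal_fall"):
            f = getattr(self, name)
            if not (0 <= f <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (
            self.reduction_sublethal_fall
            <= self.reduction_lethal_fall
            <= self.reduction_sublethal_summer
        ):
            raise ValueError(
                "reduction fractions must satisfy fall sublethal <= fall lethal <= summer sublethal"
            )
        return self

    def replacement_cost(self, replacement: Replacement) -> Decimal:
        return {
            Replacement.NOT_APPLICABLE: Decimal("0"),
            Replacement.PACKAGE: self.replacement_cost_package,
            Replacement.SPLIT_PURCHASED_QUEEN: self.replacement_cost_split_purchased_queen,
            Replacement.SPLIT_INHOUSE_QUEEN: self.replacement_cost_split_inhouse_queen,
        }[Replacement(replacement)]


class Scenario(BaseModel):
    """One timing × effect × replacement cell with a health value h ∈ [0, 1]."""

    model_config = ConfigDict(frozen=True)

    timing: Timing = Timing.NONE
    effect: Effect = Effect.NONE
    replacement: Replacement = Replacement.NOT_APPLICABLE
    health: float = Field(0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _validate(self) -> "Scenario":
        if self.effect == Effect.NONE:
            if self.timing != Timing.NONE:
                raise ValueError("effect 'none' requires timing 'none'")
            if self.health != 0:
                raise ValueError("effect 'none' requires health 0")
            if self.replacement != Replacement.NOT_APPLICABLE:
                raise ValueError("effect 'none' requires replacement 'not_applicable'")
        else:
            if self.timing == Timing.NONE:
                raise ValueError(f"effect {self.effect.value!r} requires a timing")
        if self.effect == Effect.LETHAL:
            if self.replacement == Replacement.NOT_APPLICABLE:
                raise ValueError("lethal effect requires a replacement strategy")
            if self.timing == Timing.EARLY_SUMMER and self.health != 1:
                raise ValueError("a colony lost in early summer has health 1")
        if self.effect == Effect.SUBLETHAL and self.replacement != Replacement.NOT_APPLICABLE:
            raise ValueError("sublethal effect does not involve replacement")
        return self


def _round_lbs(value: Decimal) -> int:
    return int(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def effective_honey_yield(params: ProfitParameters, scenario: Scenario) -> int:
    """Seasonal honey yield in whole pounds under the scenario's direct effect.

    Reduced yields are rounded half-up to whole pounds: with the default
    59 lb crop this gives 41 lbs (30% summer-sublethal cut), 55 lbs (7%
    fall-sublethal cut) and 48 lbs (18.5% fall-lethal cut); a colony lost in
    early summer yields nothing.
    """
    base = Decimal(params.base_honey_yield_lb)
    if scenario.effect == Effect.NONE:
        return params.base_honey_yield_lb
    if scenario.effect == Effect.SUBLETHAL:
        frac = (
            params.reduction_sublethal_summer
            if scenario.timing == Timing.EARLY_SUMMER
            else params.reduction_sublethal_fall
        )
        return _round_lbs(base * (1 - frac))
    # lethal
    if scenario.timing == Timing.EARLY_SUMMER:
        return 0
    return _round_lbs(base * (1 - params.reduction_lethal_fall))


def _to_decimal_h(h: Union[float, Decimal]) -> Decimal:
    d = h if isinstance(h, Decimal) else Decimal(str(h))
    if not (0 <= d <= 1):
        raise ValueError(f"health value must lie in [0, 1], got {h}")
    return d


def profit_at(
    params: ProfitParameters,
    timing: Timing,
    effect: Effect,
    replacement: Replacement,
    h: Union[float, Decimal],
) -> Decimal:
    """π = (1 − h)·P·Q + RF − Cop − Crep, to the cent, at an explicit h."""
    yield_lb = effective_honey_yield(
        params,
        Scenario.model_construct(
            timing=Timing(timing), effect=Effect(effect), replacement=Replacement(replacement), health=0.0
        ),
    )
    hd = _to_decimal_h(h)
    revenue = (1 - hd) * params.honey_price_per_lb * yield_lb
    profit = revenue + params.rental_fee - params.operating_cost - params.replacement_cost(replacement)
    return profit.quantize(CENT, rounding=ROUND_HALF_UP)


def colony_profit(params: ProfitParameters, scenario: Scenario) -> Decimal:
    """Per-colony seasonal profit in dollars, exact to the cent."""
    return profit_at(params, scenario.timing, scenario.effect, scenario.replacement, scenario.health)


def break_even_health(
    params: ProfitParameters,
    scenario: Scenario,
    rounded: bool = True,
) -> Union[Decimal, str]:
    """Health value h* at which profit crosses zero, to 4 decimals.

    Solves (1 − h)·P·Q + RF − Cop − Crep = 0, i.e.
    h* = 1 − (Cop + Crep − RF) / (P·Q).  Returns ``BREAK_EVEN_NEVER`` when
    the cell loses money even at h = 0 (h* < 0) and ``BREAK_EVEN_ALWAYS``
    when it is profitable even at h = 1 (h* > 1).  The exact (unrounded) h*
    zeroes the profit identically; the reported 4-decimal value can leave a
    residual profit of up to P·Q × 5e-5 (about a cent at the defaults), so
    pass ``rounded=False`` when the exact root is needed.
    """
    yield_lb = effective_honey_yield(params, scenario)
    if yield_lb == 0:
        raise ValueError("break-even health is undefined when honey revenue is zero")
    revenue = params.honey_price_per_lb * yield_lb
    h_star = 1 - (
        params.operating_cost + params.replacement_cost(scenario.replacement) - params.rental_fee
    ) / revenue
    if h_star < 0:
        return BREAK_EVEN_NEVER
    if h_star > 1:
        return BREAK_EVEN_ALWAYS
    if not rounded:
        return h_star
    return h_star.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP)


#: The evaluated grid cells: baseline plus timing × effect × replacement.
_GRID_CELLS: list[tuple[Timing, Effect, Replacement]] = [
    (Timing.NONE, Effect.NONE, Replacement.NOT_APPLICABLE),
    (Timing.EARLY_SUMMER, Effect.SUBLETHAL, Replacement.NOT_APPLICABLE),
    (Timing.EARLY_SUMMER, Effect.LETHAL, Replacement.PACKAGE),
    (Timing.EARLY_SUMMER, Effect.LETHAL, Replacement.SPLIT_PURCHASED_QUEEN),
    (Timing.FALL, Effect.SUBLETHAL, Replacement.NOT_APPLICABLE),
    (Timing.FALL, Effect.LETHAL, Replacement.PACKAGE),
    (Timing.FALL, Effect.LETHAL, Replacement.SPLIT_PURCHASED_QUEEN),
]


def _grid_rows(
    params: ProfitParameters,
    cells: Iterable[tuple[Timing, Effect, Replacement]] = _GRID_CELLS,
    yield_override: Optional[int] = None,
) -> list[dict]:
    rows = []
    for timing, effect, replacement in cells:
        if yield_override is not None:
            cell_params = _with_yield_override(params, timing, effect, yield_override)
        else:
            cell_params = params

        summer_lethal = effect == Effect.LETHAL and timing == Timing.EARLY_SUMMER
        no_effect = effect == Effect.NONE

        profit_h0 = (
            None if summer_lethal else profit_at(cell_params, timing, effect, replacement, 0)
        )
        profit_h1 = (
            None if no_effect else profit_at(cell_params, timing, effect, replacement, 1)
        )
        yield_lb = effective_honey_yield(
            cell_params,
            Scenario.model_construct(timing=timing, effect=effect, replacement=replacement, health=0.0),
        )
        if no_effect or summer_lethal or yield_lb == 0:
            h_star: Optional[Union[Decimal, str]] = None
        else:
            h_star = break_even_health(
                cell_params,
                Scenario.model_construct(timing=timing, effect=effect, replacement=replacement, health=0.0),
            )
        rows.append(
            {
                "timing": timing.value,
                "effect": effect.value,
                "replacement": replacement.value,
                "honey_yield_lb": yield_lb,
                "profit_h0": profit_h0,
                "profit_h1": profit_h1,
                "break_even_h": h_star,
            }
        )
    return rows


def scenario_grid(params: ProfitParameters = ProfitParameters()) -> pd.DataFrame:
    """Profit at h = 0 and h = 1 plus break-even h for every grid cell.

    At the default parameters this reproduces the canonical result table:
    baseline $220.78; summer sublethal $69.22 → −$276.00 (h* = 0.2005);
    summer lethal −$516.00 (package) / −$331.00 (split); fall sublethal
    $187.10 → −$276.00 (h* = 0.4040); fall lethal −$111.84 → −$516.00
    (package, break-even "none (<0)") and $73.16 → −$331.00 (split,
    h* = 0.1810).
    """
    return pd.DataFrame(
        _grid_rows(params),
        columns=["timing", "effect", "replacement", "honey_yield_lb", "profit_h0", "profit_h1", "break_even_h"],
    )


class SensitivityOverride(BaseModel):
    """One ceteris-paribus parameter change for the sensitivity analysis.

    Exactly one of ``honey_fraction`` (fraction of the full crop actually
    produced), ``rental_fee`` (reduced pollination fee, $) or
    ``replacement`` (alternative replacement strategy for lethal cells)
    must be set.
    """

    model_config = ConfigDict(frozen=True)

    honey_fraction: Optional[Decimal] = None
    rental_fee: Optional[Decimal] = None
    replacement: Optional[Replacement] = None

    @model_validator(mode="after")
    def _exactly_one(self) -> "SensitivityOverride":
        set_fields = [
            f
            for f in ("honey_fraction", "rental_fee", "replacement")
            if getattr(self, f) is not None
        ]
        if len(set_fields) != 1:
            raise ValueError(f"exactly one override field must be set, got {set_fields or 'none'}")
        if self.honey_fraction is not None and not (0 <= self.honey_fraction <= 1):
            raise ValueError("honey_fraction must lie in [0, 1]")
        if self.rental_fee is not None and self.rental_fee < 0:
            raise ValueError("rental_fee must be non-negative")
        return self

    @property
    def name(self) -> str:
        if self.honey_fraction is not None:
            return "honey_fraction"
        if self.rental_fee is not None:
            return "rental_fee"
        return "replacement"

    @property
    def value(self) -> str:
        return str(getattr(self, self.name).value if self.name == "replacement" else getattr(self, self.name))


#: The standard override set: honey output at 10/50/90% of a full crop,
#: rental fee cut to 50%/75%, and in-house-queen split replacement.
DEFAULT_SENSITIVITY_OVERRIDES: tuple[SensitivityOverride, ...] = (
    SensitivityOverride(honey_fraction=Decimal("0.10")),
    SensitivityOverride(honey_fraction=Decimal("0.50")),
    SensitivityOverride(honey_fraction=Decimal("0.90")),
    SensitivityOverride(rental_fee=Decimal("62")),
    SensitivityOverride(rental_fee=Decimal("93")),
    SensitivityOverride(replacement=Replacement.SPLIT_INHOUSE_QUEEN),
)


def _with_yield_override(
    params: ProfitParameters, timing: Timing, effect: Effect, yield_lb: int
) -> ProfitParameters:
    """Clamp the effective yield of a cell by adjusting reductions; summer-lethal stays 0."""
    # handled in _grid_rows by passing yield through directly; here we fake a
    # params whose base yield and reductions produce exactly yield_lb.
    if effect == Effect.LETHAL and timing == Timing.EARLY_SUMMER:
        return params
    return params.model_copy(
        update={
            "base_honey_yield_lb": yield_lb,
            "reduction_sublethal_summer": Decimal("0"),
            "reduction_sublethal_fall": Decimal("0"),
            "reduction_lethal_fall": Decimal("0"),
        }
    )


def sensitivity_analysis(
    params: ProfitParameters = ProfitParameters(),
    overrides: Sequence[SensitivityOverride] = DEFAULT_SENSITIVITY_OVERRIDES,
) -> pd.DataFrame:
    """Re-evaluate the scenario grid under each single-parameter override.

    ``honey_fraction`` f replaces the effective yield with round(base × f)
    in every cell whose baseline yield is nonzero (a colony lost in early
    summer still yields nothing); ``rental_fee`` substitutes the reduced
    fee; ``replacement`` swaps the replacement strategy into the lethal
    cells.  All other parameters stay at their defaults (ceteris paribus).
    """
    frames = []
    for ov in overrides:
        if ov.honey_fraction is not None:
            yield_lb = _round_lbs(Decimal(params.base_honey_yield_lb) * ov.honey_fraction)
            rows = _grid_rows(params, yield_override=yield_lb)
        elif ov.rental_fee is not None:
            rows = _grid_rows(params.model_copy(update={"rental_fee": ov.rental_fee}))
        else:
            cells = [
                (t, e, ov.replacement if e == Effect.LETHAL else r) for t, e, r in _GRID_CELLS
            ]
            # drop the duplicate lethal cells (package and split collapse to one)
            seen: set[tuple] = set()
            cells = [c for c in cells if not (c in seen or seen.add(c))]
            rows = _grid_rows(params, cells=cells)
        block = pd.DataFrame(rows)
        block.insert(0, "override", ov.name)
        block.insert(1, "override_value", ov.value)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def profit_curve(
    params: ProfitParameters,
    scenario: Scenario,
    h_grid: Sequence[float],
) -> pd.DataFrame:
    """Profit as a function of h over ``h_grid``; linear with slope −P·Q."""
    rows = []
    for h in h_grid:
        hd = _to_decimal_h(h)
        rows.append(
            {
                "h": float(hd),
                "profit": profit_at(params, scenario.timing, scenario.effect, scenario.replacement, hd),
            }
        )
    return pd.DataFrame(rows, columns=["h", "profit"])


def plot_profit_curves(params: ProfitParameters, path: str) -> None:
    """Write a profit-vs-h figure for the non-baseline grid cells (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h_grid = [i / 100 for i in range(101)]
    fig, ax = plt.subplots(figsize=(7, 5))
    for timing, effect, replacement in _GRID_CELLS[1:]:
        scenario = Scenario.model_construct(
            timing=timing, effect=effect, replacement=replacement, health=0.0
        )
        curve = profit_curve(params, scenario, h_grid)
        label = f"{timing.value} {effect.value}"
        if replacement != Replacement.NOT_APPLICABLE:
            label += f" ({replacement.value})"
        ax.plot(curve["h"], [float(p) for p in curve["profit"]], label=label)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("health variable h")
    ax.set_ylabel("per-colony profit ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
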