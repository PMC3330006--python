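"""Budget-impact arithmetic of the appraisal's economics cluster.

Two elementary quantities feed the economics criteria of the matrix: the
incremental cost per patient of the candidate intervention over its
comparator, and the projected budget impact over a covered population per
period. Amounts are exact decimals (2 dp) in a single labelled currency;
no conversion, discounting or cost-effectiveness modelling is performed —
externally modelled figures (e.g. cost per QALY) are stored as given
inputs elsewhere, never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

__all__ = ["Money", "CostInputs", "incremental_cost", "budget_impact"]

_TWO_DP = Decimal("0.01")


def _as_money(value) -> Decimal:
    return Decimal(str(value)).quantize(_TWO_DP)


@dataclass(frozen=True)
class Money:
    """An exact currency amount at 2 decimal places."""

    amount: Decimal
    currency: str = "ZAR"

    def __float__(self) -> float:
        return float(self.amount)

    def __str__(self) -> str:
        return f"{self.currency} {self.amount:,.2f}"


@dataclass(frozen=True)
class CostInputs:
    """Unit prices and covered population for the budget computation."""

    price_intervention: Decimal | None
    price_comparator: Decimal | None
    population_per_period: int | None = None
    currency: str = "ZAR"

    def __post_init__(self) -> None:
        for name in ("price_intervention", "price_comparator"):
            v = getattr(self, name)
            if v is not None:
                v = _as_money(v)
                if v < 0:
                    raise ValueError(f"{name} must be non-negative")
                object.__setattr__(self, name, v)
        if self.population_per_period is not None and self.population_per_period < 0:
            raise ValueError("population_per_period must be non-negative")


def incremental_cost(c: CostInputs) -> Money:
    """Incremental cost per patient: intervention price − comparator price.

    May be negative when the intervention is cheaper.
    """
    if c.price_intervention is None or c.price_comparator is None:
        raise ValueError("both prices are required for the incremental cost")
    return Money(c.price_intervention - c.price_comparator, c.currency)


def budget_impact(c: CostInputs) -> Money:
    """Projected budget impact per period: incremental cost × population."""
    if c.population_per_period is None:
        raise ValueError("population_per_period is required for the budget impact")
    inc = incremental_cost(c)
    return Money(inc.amount * c.population_per_period, c.currency)
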