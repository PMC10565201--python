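"""Demand response to price changes and the three scenario outcomes.

Quantities respond to price through a constant-elasticity (exponential-decay)
relationship ``Q1 = Q0 (P1/P0)^elasticity``, which is exact for large price
changes where the familiar linear approximation overstates the response.
Scenario outcomes are annual consumption in 20 g units, annual government
excise revenue, and premature deaths averted among smokers who quit because
of the price rise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .markets import ConsumptionInputs, MarketSegment, MortalityAssumptions
from .pricing import PriceDecomposition

__all__ = [
    "SegmentState",
    "ScenarioResult",
    "quantity_response",
    "revenue",
    "deaths_averted",
    "apply_illicit_downscale",
]


def quantity_response(q0: float, p0: float, p1: float, elasticity: float) -> float:
    """Post-change quantity under constant-elasticity demand.

    ``q0 (p1/p0)**elasticity``; with a negative elasticity a price rise
    shrinks the quantity and the decay never crosses zero.
    """
    if p0 <= 0 or p1 <= 0:
        raise ValueError("prices must be positive")
    if q0 < 0:
        raise ValueError("baseline quantity must be non-negative")
    return q0 * (p1 / p0) ** elasticity


@dataclass(frozen=True)
class SegmentState:
    """Baseline and post-change price/quantity pair for one segment."""

    segment: MarketSegment
    q0: float
    p0: float
    q1: float
    p1: float

    def __post_init__(self) -> None:
        if self.q0 <= 0:
            raise ValueError("q0 must be positive")
        if self.p0 <= 0 or self.p1 <= 0:
            raise ValueError("prices must be positive")
        if self.q1 < 0:
            raise ValueError("q1 must be non-negative")

    @property
    def rel_reduction(self) -> float:
        """Relative consumption reduction ``1 - q1/q0``; negative if demand grew."""
        return 1.0 - self.q1 / self.q0

    @classmethod
    def from_response(cls, segment: MarketSegment, q0: float,
                     p1: float) -> "SegmentState":
        q1 = quantity_response(q0, segment.base_price, p1, segment.elasticity)
        return cls(segment=segment, q0=q0, p0=segment.base_price, q1=q1, p1=p1)


def revenue(states: Sequence[SegmentState],
            decomps: Sequence[PriceDecomposition]) -> float:
    """Annual government excise revenue, USD.

    Post-change quantities multiplied by the per-unit tax (duty + specific +
    ad valorem) of each segment's decomposition, summed over segments.
    """
    if len(states) != len(decomps):
        raise ValueError("states and decompositions must align")
    return sum(s.q1 * d.total_tax for s, d in zip(states, decomps))


def deaths_averted(states: Sequence[SegmentState],
                   mort: MortalityAssumptions) -> float:
    """Premature deaths averted by the price-induced consumption fall.

    The per-segment relative reductions are summed *unweighted* across
    segments, scaled by the smoker base, and by the fractions of the
    reduction attributed to quitting and of quitters who would have died
    prematurely.  Segments whose price fell contribute with negative sign;
    the aggregate is floored at zero.
    """
    if not states:
        raise ValueError("states must be non-empty")
    total_reduction = sum(s.rel_reduction for s in states)
    deaths = (mort.quit_fraction * mort.mortality_fraction
              * mort.smoker_base * total_reduction)
    return max(deaths, 0.0)


def apply_illicit_downscale(value: float, inputs: ConsumptionInputs) -> float:
    """Scale an outcome down by the illicit (non-tax-paid) consumption share.

    A reporting utility: survey-based consumption includes illicit use that
    generates no tax, so taxed outcomes may be reported net of it.  The
    packaged calibrated baseline already embeds this adjustment, so
    reproduction runs leave it off.
    """
    if value < 0:
        raise ValueError("value must be non-negative")
    return value * (1.0 - inputs.illicit_fraction)


@dataclass(frozen=True)
class ScenarioResult:
    """Aggregate outcome of one solved tax scenario.

    Percent changes are relative to the zero-specific-excise base scenario
    (``100 * (scenario - base) / base``).
    """

    label: str
    approach: str
    specific: float
    states: tuple[SegmentState, ...]
    decomps: tuple[PriceDecomposition, ...]
    total_q1: float
    weighted_price: float
    burden: float
    revenue: float
    deaths_averted: float
    consumption_change_pct: float
    revenue_change_pct: float
    price_change_pct: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "decomps", tuple(self.decomps))
        if self.revenue < 0:
            raise ValueError("revenue must be non-negative")
        if not 0.0 <= self.burden < 1.0:
            raise ValueError("burden must be in [0, 1)")

    def to_record(self) -> dict:
        """Flat record shaped like a published scenario-table row."""
        return {
            "scenario": self.label,
            "approach": self.approach,
            "specific_excise": self.specific,
            "quantity_units": self.total_q1,
            "quantity_change_pct": self.consumption_change_pct,
            "deaths_averted": self.deaths_averted,
            "revenue_usd": self.revenue,
            "revenue_change_pct": self.revenue_change_pct,
            "retail_price_usd": self.weighted_price,
            "price_change_pct": self.price_change_pct,
            "tax_burden": self.burden,
        }
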