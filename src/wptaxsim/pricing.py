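"""Retail-price decomposition and tax-policy application.

The retail price of one 20 g unit is split additively into five components:
CIF/ex-factory cost, import duty, specific excise, ad valorem excise and the
residual industry margin.  Duty is levied on the CIF price; the ad valorem
excise on CIF + duty; the margin is whatever remains of the observed retail
price.  A :class:`TaxPolicy` replaces the specific excise (and optionally
removes the ad valorem component) while holding CIF, duty and — under full
pass-through — the margin fixed, so that the tax change is passed one-for-one
into the retail price.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .markets import MarketSegment

__all__ = [
    "PriceDecomposition",
    "TaxPolicy",
    "decompose_baseline",
    "apply_policy",
    "weighted_average",
    "tax_burden",
]

COMPONENT_TOL = 1e-9

APPROACH_SIMPLE = "simple"
APPROACH_MIXED = "mixed"


@dataclass(frozen=True)
class PriceDecomposition:
    """Additive split of a per-unit retail price, USD per 20 g.

    ``retail`` always equals the sum of the five components.
    """

    cif: float
    duty_amount: float
    specific: float
    advalorem_amount: float
    margin: float
    retail: float

    def __post_init__(self) -> None:
        total = (self.cif + self.duty_amount + self.specific
                 + self.advalorem_amount + self.margin)
        if abs(total - self.retail) > COMPONENT_TOL:
            raise ValueError(
                f"retail ({self.retail:.12f}) must equal the component sum "
                f"({total:.12f})")
        for name in ("cif", "duty_amount", "specific", "advalorem_amount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_tax(self) -> float:
        """Duty + specific + ad valorem, USD per unit."""
        return self.duty_amount + self.specific + self.advalorem_amount

    @property
    def burden(self) -> float:
        """Tax share of this decomposition's own retail price."""
        return self.total_tax / self.retail


@dataclass(frozen=True)
class TaxPolicy:
    """A uniform specific-excise policy.

    ``approach`` is ``"simple"`` (ad valorem removed, specific only) or
    ``"mixed"`` (specific added on top of the existing ad valorem).
    ``shift_rate`` adds that fraction of the per-unit tax change to the
    industry margin (positive = overshifting, negative = undershifting);
    zero means full one-for-one pass-through.
    """

    approach: str
    specific: float
    shift_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.approach not in (APPROACH_SIMPLE, APPROACH_MIXED):
            raise ValueError(f"approach must be 'simple' or 'mixed', got "
                             f"{self.approach!r}")
        if self.specific < 0:
            raise ValueError("specific must be non-negative")
        if not -1.0 <= self.shift_rate <= 1.0:
            raise ValueError("shift_rate must be in [-1, 1]")

    @property
    def keep_advalorem(self) -> bool:
        return self.approach == APPROACH_MIXED


def decompose_baseline(segment: MarketSegment) -> PriceDecomposition:
    """Decompose a segment's observed baseline retail price.

    Duty is ``duty_rate * cif``; the ad valorem amount is
    ``advalorem_rate * (cif + duty)``; the margin is the residual.  A negative
    residual means the stated price cannot cover cost plus taxes and raises a
    ``ValueError`` naming the segment.
    """
    duty = segment.duty_rate * segment.cif
    advalorem = segment.advalorem_rate * (segment.cif + duty)
    margin = segment.base_price - (segment.cif + duty + segment.specific + advalorem)
    if margin < -COMPONENT_TOL:
        raise ValueError(
            f"segment {segment.name!r}: negative baseline margin "
            f"({margin:.6f}); taxes and CIF exceed the retail price")
    return PriceDecomposition(
        cif=segment.cif,
        duty_amount=duty,
        specific=segment.specific,
        advalorem_amount=advalorem,
        margin=max(margin, 0.0),
        retail=segment.base_price,
    )


def apply_policy(base: PriceDecomposition, policy: TaxPolicy) -> PriceDecomposition:
    """Apply a tax policy to a baseline decomposition.

    CIF and duty are unchanged; the specific excise is replaced by the
    policy's; the ad valorem amount is kept (mixed) or dropped (simple); the
    margin moves by ``shift_rate`` times the per-unit tax change and is
    floored at zero (with a warning) if undershifting would drive it negative.
    The new retail price is the sum of the resulting components.
    """
    advalorem = base.advalorem_amount if policy.keep_advalorem else 0.0
    new_tax = base.duty_amount + policy.specific + advalorem
    delta_tax = new_tax - base.total_tax
    margin = base.margin + policy.shift_rate * delta_tax
    if margin < 0.0:
        warnings.warn(
            f"undershifting drove the margin to {margin:.6f}; flooring at 0",
            stacklevel=2)
        margin = 0.0
    retail = base.cif + base.duty_amount + policy.specific + advalorem + margin
    return PriceDecomposition(
        cif=base.cif,
        duty_amount=base.duty_amount,
        specific=policy.specific,
        advalorem_amount=advalorem,
        margin=margin,
        retail=retail,
    )


def _check_weights(decomps: Sequence[PriceDecomposition],
                   weights: Sequence[float]) -> float:
    if len(decomps) != len(weights):
        raise ValueError("decompositions and weights must align")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return total


def weighted_average(decomps: Sequence[PriceDecomposition],
                     weights: Sequence[float]) -> PriceDecomposition:
    """Quantity-weighted mean decomposition across segments.

    Each component is averaged with the given (typically consumption)
    weights; the averaged retail price equals the sum of the averaged
    components by linearity.
    """
    total = _check_weights(decomps, weights)

    def avg(attr: str) -> float:
        return sum(w * getattr(d, attr) for d, w in zip(decomps, weights)) / total

    return PriceDecomposition(
        cif=avg("cif"),
        duty_amount=avg("duty_amount"),
        specific=avg("specific"),
        advalorem_amount=avg("advalorem_amount"),
        margin=avg("margin"),
        retail=avg("retail"),
    )


def tax_burden(decomps: Sequence[PriceDecomposition],
               weights: Sequence[float]) -> float:
    """Market-weighted tax burden: total tax over total retail value.

    Returns ``sum_m w_m tax_m / sum_m w_m retail_m`` — the fraction of the
    quantity-weighted retail price that is tax.
    """
    _check_weights(decomps, weights)
    tax = sum(w * d.total_tax for d, w in zip(decomps, weights))
    value = sum(w * d.retail for d, w in zip(decomps, weights))
    return tax / value
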