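"""Random but structurally valid market parameter sets for testing.

The model's "data" are aggregate parameters — shares, prices, elasticities,
tax rates — so synthesis means sampling parameter sets, not microdata.
Shares come from a flat Dirichlet simplex; prices, elasticities and tax
rates are uniform on configurable ranges; the CIF cost is drawn so the
implied baseline industry margin stays above a configurable floor.  All
draws are seeded and deterministic.

:func:`generate_scenario_truth` additionally returns the specific excise
whose post-change-weighted burden equals a requested target, computed by
iterative grid refinement — deliberately independent of the package's
root-finding solver so it can serve as an oracle in parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markets import Market, MarketSegment
from .pricing import APPROACH_MIXED, APPROACH_SIMPLE

__all__ = ["SynthSpec", "generate_market", "generate_scenario_truth", "grid_burden"]


@dataclass(frozen=True)
class SynthSpec:
    """Sampling ranges for one synthetic market draw."""

    n_segments: int = 4
    seed: int = 0
    price_range: tuple[float, float] = (0.05, 3.0)
    elasticity_range: tuple[float, float] = (-1.2, -0.2)
    advalorem_range: tuple[float, float] = (0.0, 2.5)
    duty_range: tuple[float, float] = (0.0, 0.3)
    quantity_range: tuple[float, float] = (1e8, 1e10)
    margin_floor: float = 0.02

    def __post_init__(self) -> None:
        if not 1 <= self.n_segments <= 8:
            raise ValueError("n_segments must be in 1..8")
        for name in ("price_range", "elasticity_range", "advalorem_range",
                     "duty_range", "quantity_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be well-ordered")
        if self.price_range[0] <= 0:
            raise ValueError("prices must be positive")
        if self.elasticity_range[1] >= 0:
            raise ValueError("elasticity_range must be negative")
        if self.duty_range[0] < 0 or self.advalorem_range[0] < 0:
            raise ValueError("tax-rate ranges must be non-negative")
        if self.quantity_range[0] <= 0:
            raise ValueError("quantities must be positive")
        if not 0.0 <= self.margin_floor <= 0.9:
            raise ValueError("margin_floor must be in [0, 0.9]")


def generate_market(spec: SynthSpec) -> Market:
    """Draw one market; identical output for identical spec (incl. seed).

    Shares are Dirichlet(1, ..., 1) (uniform on the simplex) and re-normalised
    against floating-point drift.  The CIF draw is bounded above by
    ``(1 - margin_floor) * price / ((1 + duty)(1 + advalorem)(...))`` so the
    baseline margin is at least ``margin_floor`` of the retail price.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_segments
    shares = rng.dirichlet(np.ones(k))
    shares = shares / shares.sum()
    prices = rng.uniform(*spec.price_range, size=k)
    elasticities = rng.uniform(*spec.elasticity_range, size=k)
    duty_rates = rng.uniform(*spec.duty_range, size=k)
    advalorem_rates = rng.uniform(*spec.advalorem_range, size=k)
    # cif * (1 + duty) * (1 + advalorem-on-(cif+duty)) <= (1 - floor) * price
    gross_up = (1.0 + duty_rates) * (1.0 + advalorem_rates)
    cif_max = (1.0 - spec.margin_floor) * prices / gross_up
    if np.any(cif_max <= 0):
        raise ValueError("infeasible ranges: no CIF satisfies the margin floor")
    cifs = rng.uniform(0.0, cif_max)
    base_quantity = rng.uniform(*spec.quantity_range)
    segments = tuple(
        MarketSegment(
            name=f"segment_{i}",
            share=float(shares[i]),
            base_price=float(prices[i]),
            elasticity=float(elasticities[i]),
            cif=float(cifs[i]),
            duty_rate=float(duty_rates[i]),
            advalorem_rate=float(advalorem_rates[i]),
        )
        for i in range(k)
    )
    return Market(segments=segments, base_quantity=float(base_quantity),
                  name=f"synthetic_seed{spec.seed}")


def grid_burden(market: Market, S: np.ndarray, approach: str = APPROACH_SIMPLE,
                ) -> np.ndarray:
    """Vectorised post-change-weighted burden at each excise level in ``S``.

    A self-contained numpy re-statement of the pricing/demand arithmetic,
    kept independent of the pricing and solver modules so grid searches over
    it are a genuine cross-check.
    """
    if approach not in (APPROACH_SIMPLE, APPROACH_MIXED):
        raise ValueError("approach must be 'simple' or 'mixed'")
    S = np.atleast_1d(np.asarray(S, dtype=float))[:, None]
    p0 = np.array([s.base_price for s in market.segments])
    e = np.array([s.elasticity for s in market.segments])
    q0 = np.array([s.share for s in market.segments]) * market.base_quantity
    cif = np.array([s.cif for s in market.segments])
    duty = np.array([s.duty_rate for s in market.segments]) * cif
    advalorem = np.array([s.advalorem_rate for s in market.segments]) * (cif + duty)
    baseline_specific = np.array([s.specific for s in market.segments])
    margin = p0 - cif - duty - baseline_specific - advalorem
    if approach == APPROACH_SIMPLE:
        advalorem = np.zeros_like(advalorem)
    p1 = cif + duty + S + advalorem + margin
    tax = duty + S + advalorem
    q1 = q0 * (p1 / p0) ** e
    return (q1 * tax).sum(axis=1) / (q1 * p1).sum(axis=1)


def generate_scenario_truth(spec: SynthSpec, target_burden: float,
                            approach: str = APPROACH_SIMPLE,
                            tol: float = 1e-13) -> tuple[Market, float]:
    """A synthetic market plus the true excise hitting ``target_burden``.

    The truth is located by geometric bracketing followed by iterative grid
    refinement (65-point grids shrunk until the bracket is below ``tol``),
    using only :func:`grid_burden`.  Raises if the target is below the
    burden at zero excise.
    """
    if not 0.0 < target_burden < 1.0:
        raise ValueError("target_burden must be in (0, 1)")
    market = generate_market(spec)
    floor = float(grid_burden(market, 0.0, approach)[0])
    if abs(floor - target_burden) <= 1e-12:
        return market, 0.0
    if target_burden < floor:
        raise ValueError(
            f"unachievable target {target_burden:.4f}: burden at zero excise "
            f"is already {floor:.4f}")
    lo, hi = 0.0, 1.0
    for _ in range(200):
        if float(grid_burden(market, hi, approach)[0]) > target_burden:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError("failed to bracket the target burden")
    # refinement cannot outrun float spacing at the bracket's magnitude
    while hi - lo > max(tol, 8 * np.spacing(hi)):
        grid = np.linspace(lo, hi, 65)
        values = grid_burden(market, grid, approach)
        idx = int(np.searchsorted(values, target_burden))
        idx = min(max(idx, 1), len(grid) - 1)
        lo, hi = float(grid[idx - 1]), float(grid[idx])
    return market, 0.5 * (lo + hi)
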