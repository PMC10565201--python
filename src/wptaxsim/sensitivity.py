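"""One-at-a-time sensitivity analysis around a solved tax scenario.

Three parameter families are perturbed, one at a time, and the scenario's
outcomes (consumption, deaths averted, revenue) are re-evaluated and
reported as relative percent differences from the unperturbed run:

* ``elasticity_low`` / ``elasticity_high`` — replace a segment's (or every
  segment's) own-price elasticity with a confidence-interval bound;
* ``cif_down`` / ``cif_up`` — scale the CIF/ex-factory cost by ``1 -/+
  magnitude`` (default 50%), with duty recomputed from the new CIF and the
  industry margin held at its original estimate;
* ``undershift`` / ``overshift`` — scale the industry margin by ``1 -/+
  magnitude`` (default 10%), the industry absorbing part of, or adding to,
  the price change.

By default the *original solved* specific excise is kept fixed — the
statutory tax is what it is, and the perturbation asks how wrong the
projected outcomes would be if a parameter had been mis-estimated.  Pass
``resolve=True`` to instead re-solve the excise to the same target burden
under each perturbation.  Baseline observed prices and quantities are never
perturbed: only the scenario-side price build-up changes.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .markets import Market, MortalityAssumptions
from .pricing import PriceDecomposition, decompose_baseline
from .solver import ScenarioSpec, run_scenario

__all__ = [
    "SensitivitySpec",
    "DIMENSIONS",
    "perturb_market",
    "placeholder_bounds",
    "paper_sensitivity_specs",
    "sensitivity_report",
]

DIMENSIONS = ("elasticity_low", "elasticity_high", "cif_down", "cif_up",
              "overshift", "undershift")

OUTCOMES = ("consumption", "deaths_averted", "revenue")


@dataclass(frozen=True)
class SensitivitySpec:
    """One perturbation: which family, how much, and which segments."""

    dimension: str
    magnitude: float = 0.0
    segment_scope: str = "all"
    elasticity_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.dimension.startswith("elasticity") and not self.elasticity_bounds:
            raise ValueError(
                f"{self.dimension} requires per-segment elasticity_bounds")

    @property
    def name(self) -> str:
        scope = "" if self.segment_scope == "all" else f":{self.segment_scope}"
        return f"{self.dimension}{scope}"


def placeholder_bounds(market: Market, width: float = 0.20,
                       ) -> dict[str, tuple[float, float]]:
    """Synthetic elasticity CI bounds at +/- ``width`` of each point estimate.

    These are NOT published confidence intervals — the published ones live in
    supplementary material that is not machine-readable here.  They exist so
    the sensitivity machinery is exercisable; substitute real bounds where
    available.  "low" is the more negative (more elastic) bound.
    """
    return {
        s.name: (s.elasticity * (1.0 + width), s.elasticity * (1.0 - width))
        for s in market.segments
    }


def perturb_market(market: Market, spec: SensitivitySpec,
                   ) -> tuple[Market, list[PriceDecomposition] | None]:
    """Apply a single perturbation; the input market is never modified.

    Returns the (possibly replaced) market plus, for the cost-side
    dimensions, the perturbed baseline price decompositions to use in place
    of the market's own.  Exactly one parameter family differs from the
    original.
    """
    base_decomps = [decompose_baseline(s) for s in market.segments]

    if spec.dimension in ("elasticity_low", "elasticity_high"):
        idx = 0 if spec.dimension == "elasticity_low" else 1
        segs = []
        for s in market.segments:
            in_scope = spec.segment_scope in ("all", s.name)
            if in_scope:
                if s.name not in spec.elasticity_bounds:
                    raise ValueError(f"no elasticity bounds for segment {s.name!r}")
                segs.append(dataclasses.replace(
                    s, elasticity=spec.elasticity_bounds[s.name][idx]))
            else:
                segs.append(s)
        return dataclasses.replace(market, segments=tuple(segs)), None

    market = copy.deepcopy(market)
    if spec.dimension in ("cif_down", "cif_up"):
        sign = -1.0 if spec.dimension == "cif_down" else 1.0
        out = []
        for seg, d in zip(market.segments, base_decomps):
            cif = d.cif * (1.0 + sign * spec.magnitude)
            duty = seg.duty_rate * cif
            advalorem = seg.advalorem_rate * (cif + duty)
            out.append(PriceDecomposition(
                cif=cif, duty_amount=duty, specific=d.specific,
                advalorem_amount=advalorem, margin=d.margin,
                retail=cif + duty + d.specific + advalorem + d.margin))
        return market, out

    # over/undershift: the industry scales its margin.
    sign = 1.0 if spec.dimension == "overshift" else -1.0
    out = []
    for d in base_decomps:
        margin = d.margin * (1.0 + sign * spec.magnitude)
        out.append(PriceDecomposition(
            cif=d.cif, duty_amount=d.duty_amount, specific=d.specific,
            advalorem_amount=d.advalorem_amount, margin=margin,
            retail=d.cif + d.duty_amount + d.specific + d.advalorem_amount + margin))
    return market, out


def paper_sensitivity_specs(
    market: Market,
    elasticity_bounds: Mapping[str, tuple[float, float]] | None = None,
    cif_magnitude: float = 0.50,
    shift_magnitude: float = 0.10,
    per_segment_elasticity: bool = True,
) -> list[SensitivitySpec]:
    """The published one-at-a-time design: elasticity CIs, CIF +/-50%, shift +/-10%.

    Elasticity runs default to one segment at a time (the published per-
    segment outcome ranges imply per-segment runs); set
    ``per_segment_elasticity=False`` for joint perturbation of all segments.
    """
    if elasticity_bounds is None:
        elasticity_bounds = placeholder_bounds(market)
    specs: list[SensitivitySpec] = []
    scopes = [s.name for s in market.segments] if per_segment_elasticity else ["all"]
    for dim in ("elasticity_low", "elasticity_high"):
        for scope in scopes:
            specs.append(SensitivitySpec(dimension=dim, segment_scope=scope,
                                         elasticity_bounds=elasticity_bounds))
    for dim in ("cif_down", "cif_up"):
        specs.append(SensitivitySpec(dimension=dim, magnitude=cif_magnitude))
    for dim in ("overshift", "undershift"):
        specs.append(SensitivitySpec(dimension=dim, magnitude=shift_magnitude))
    return specs


def sensitivity_report(market: Market, base_spec: ScenarioSpec,
                       specs: Sequence[SensitivitySpec],
                       mort: MortalityAssumptions,
                       resolve: bool = False) -> pd.DataFrame:
    """Relative percent outcome differences for each perturbation.

    Solves the unperturbed scenario once, then evaluates each perturbation —
    at the same statutory excise by default, or re-solved to the target
    burden with ``resolve=True`` — and reports ``100 * (perturbed -
    original) / original`` for consumption, deaths averted and revenue.
    """
    original = run_scenario(market, base_spec, mort)
    ref = {"consumption": original.total_q1,
           "deaths_averted": original.deaths_averted,
           "revenue": original.revenue}
    rows = []
    for spec in specs:
        try:
            pert_market, decomps = perturb_market(market, spec)
            fixed = None if resolve else original.specific
            result = run_scenario(pert_market, base_spec, mort,
                                  decomps=decomps, specific=fixed)
        except (ValueError, RuntimeError) as err:
            raise RuntimeError(f"sensitivity run {spec.name!r} failed: {err}") from err
        vals = {"consumption": result.total_q1,
                "deaths_averted": result.deaths_averted,
                "revenue": result.revenue}
        for outcome in OUTCOMES:
            rows.append({
                "dimension": spec.dimension,
                "segment_scope": spec.segment_scope,
                "outcome": outcome,
                "percent_difference":
                    100.0 * (vals[outcome] - ref[outcome]) / ref[outcome],
            })
    return pd.DataFrame(rows, columns=["dimension", "segment_scope", "outcome",
                                       "percent_difference"])
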