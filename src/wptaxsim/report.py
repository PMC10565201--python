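"""Publication-style outputs: scenario tables, plots and the single-share run.

Two table layouts are produced for each tax-structure approach: a
*tax-structure table* (market-weighted price components per scenario) and an
*impact table* (consumption, deaths averted, revenue, weighted retail price,
with percent changes against the base scenario).  Scenario rows are weighted
by post-change quantities — the segment mix shifts toward the premium
segments as cheap segments are suppressed — while the base row uses baseline
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .demand import ScenarioResult
from .markets import Market, MortalityAssumptions, who_secondary_mortality, \
    who_single_share_market
from .pricing import APPROACH_MIXED, APPROACH_SIMPLE, weighted_average
from .solver import (
    BURDEN_TOL,
    ScenarioSpec,
    base_result,
    paper_scenarios,
    run_scenario,
    run_scenario_battery,
)

__all__ = [
    "ReportBundle",
    "tax_structure_table",
    "impact_table",
    "build_report_bundle",
    "run_secondary_who",
    "plot_outcomes",
]

STRUCTURE_COLUMNS = ["scenario", "cif", "duty", "specific", "advalorem", "retail"]
IMPACT_COLUMNS = ["scenario", "quantity_units", "quantity_change_pct",
                  "deaths_averted", "revenue_usd", "revenue_change_pct",
                  "retail_price_usd", "price_change_pct"]


def _structure_row(label: str, result: ScenarioResult) -> dict:
    w = weighted_average(result.decomps, [s.q1 for s in result.states])
    return {"scenario": label, "cif": w.cif, "duty": w.duty_amount,
            "specific": w.specific, "advalorem": w.advalorem_amount,
            "retail": w.retail}


def tax_structure_table(market: Market,
                        results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Market-weighted price components, one row per scenario plus the base."""
    base = base_result(market)
    rows = [_structure_row(f"base scenario, {100 * base.burden:.1f}% tax burden",
                           base)]
    rows += [_structure_row(r.label, r) for r in results]
    return pd.DataFrame(rows, columns=STRUCTURE_COLUMNS)


def impact_table(market: Market,
                 results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Consumption, deaths and revenue per scenario with changes vs base."""
    base = base_result(market)
    rows = [{
        "scenario": f"base scenario, {100 * base.burden:.1f}% tax burden",
        "quantity_units": base.total_q1,
        "quantity_change_pct": 0.0,
        "deaths_averted": 0.0,
        "revenue_usd": base.revenue,
        "revenue_change_pct": 0.0,
        "retail_price_usd": base.weighted_price,
        "price_change_pct": 0.0,
    }]
    for r in results:
        rows.append({
            "scenario": r.label,
            "quantity_units": r.total_q1,
            "quantity_change_pct": r.consumption_change_pct,
            "deaths_averted": r.deaths_averted,
            "revenue_usd": r.revenue,
            "revenue_change_pct": r.revenue_change_pct,
            "retail_price_usd": r.weighted_price,
            "price_change_pct": r.price_change_pct,
        })
    return pd.DataFrame(rows, columns=IMPACT_COLUMNS)


@dataclass(frozen=True)
class ReportBundle:
    """The four scenario tables for both approaches, plus run metadata."""

    table2_simple: pd.DataFrame
    table2_mixed: pd.DataFrame
    table3_simple: pd.DataFrame
    table3_mixed: pd.DataFrame
    results_simple: tuple[ScenarioResult, ...] = ()
    results_mixed: tuple[ScenarioResult, ...] = ()
    metadata: dict = field(default_factory=dict)

    def write_csv(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [("table2_simple", self.table2_simple),
                         ("table2_mixed", self.table2_mixed),
                         ("table3_simple", self.table3_simple),
                         ("table3_mixed", self.table3_mixed)]:
            path = out / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.6f")
            written.append(path)
        return written


def build_report_bundle(market: Market, mort: MortalityAssumptions,
                        ) -> ReportBundle:
    """Run the full ten-scenario battery (five burdens x two approaches)."""
    results = {
        approach: run_scenario_battery(market, paper_scenarios(approach), mort)
        for approach in (APPROACH_SIMPLE, APPROACH_MIXED)
    }
    return ReportBundle(
        table2_simple=tax_structure_table(market, results[APPROACH_SIMPLE]),
        table2_mixed=tax_structure_table(market, results[APPROACH_MIXED]),
        table3_simple=impact_table(market, results[APPROACH_SIMPLE]),
        table3_mixed=impact_table(market, results[APPROACH_MIXED]),
        results_simple=tuple(results[APPROACH_SIMPLE]),
        results_mixed=tuple(results[APPROACH_MIXED]),
        metadata={"market": market.name, "version": __version__,
                  "burden_tolerance": BURDEN_TOL},
    )


def run_secondary_who(market: Market | None = None, target_burden: float = 0.75,
                      mort: MortalityAssumptions | None = None,
                      approach: str = APPROACH_SIMPLE) -> ScenarioResult:
    """The single-share analysis on the WHO-style tax-structure data.

    Runs one scenario on a one-segment market (default: the packaged
    "premium home" share, which carries the home-flavoured elasticity).  The
    default mortality assumptions scale deaths by the smoker base implied by
    the World Bank population count; see the methods note.
    """
    if market is None:
        market = who_single_share_market()
    if mort is None:
        mort = who_secondary_mortality()
    if len(market.segments) != 1:
        raise ValueError("the single-share analysis requires exactly one segment")
    spec = ScenarioSpec(target_burden=target_burden, approach=approach)
    return run_scenario(market, spec, mort)


def plot_outcomes(results: Sequence[ScenarioResult], path,
                  title: str = "Outcomes by specific excise") -> Path:
    """Line plot of consumption, deaths averted and revenue vs the excise.

    A convenience visualisation of a battery; the numeric tables are the
    canonical output.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = sorted(results, key=lambda r: r.specific)
    S = [r.specific for r in results]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax2 = ax.twinx()
    ax.plot(S, [r.total_q1 / 1e9 for r in results], "o-", color="tab:blue",
            label="consumption (billion units)")
    ax.plot(S, [r.revenue / 1e9 for r in results], "s-", color="tab:gray",
            label="revenue (billion USD)")
    ax2.plot(S, [r.deaths_averted / 1e6 for r in results], "^-",
             color="tab:red", label="deaths averted (millions)")
    ax.set_xlabel("specific excise, USD per 20 g unit")
    ax.set_ylabel("consumption / revenue (billions)")
    ax2.set_ylabel("premature deaths averted (millions)")
    ax.set_title(title)
    lines = ax.get_lines() + ax2.get_lines()
    ax.legend(lines, [ln.get_label() for ln in lines], loc="center right",
              fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
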