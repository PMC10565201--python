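"""One-at-a-time sensitivity of the 75% scenario.

Perturbs elasticities (to illustrative +/-20% bounds), the CIF/ex-factory
cost (+/-50%) and the industry margin (+/-10% over/undershift), holding the
solved statutory excise fixed, and reports the relative percent change in
each outcome.
"""

import wptaxsim as w

market = w.egypt_market()
mort = w.egypt_mortality()
specs = w.paper_sensitivity_specs(market)
report = w.sensitivity_report(market, w.ScenarioSpec(0.75, "simple"),
                              specs, mort)

pivot = report.pivot_table(index=["dimension", "segment_scope"],
                           columns="outcome", values="percent_difference")
print(pivot.round(2).to_string())

cost_side = report[report.dimension.str.contains("cif|shift")]
print(f"\nCost-side uncertainty (CIF, margin shift) moves outcomes by at "
      f"most {cost_side.percent_difference.abs().max():.1f}% — the scenario "
      "conclusions are robust to it.  Elasticity uncertainty in the "
      "large-share unflavoured segments matters far more.")
print("Note: the elasticity bounds here are illustrative +/-20% placeholders, "
      "not published confidence intervals.")
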