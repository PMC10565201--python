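"""The single-share analysis on WHO-style tax-structure data.

Global tobacco-control reports describe a country's waterpipe tax structure
from a single representative brand.  Re-running the model on that one-share
description (retail 0.47 USD, tax already 70%) shows how much it
understates the excise needed for a 75% burden compared with the
four-segment market (~0.4 vs ~2.1 USD per 20 g unit).
"""

import wptaxsim as w

who = w.who_single_share_market()
seg = who.segments[0]
d = w.decompose_baseline(seg)
print(f"single share: retail {d.retail:.2f}, duty {d.duty_amount:.2f}, "
      f"ad valorem {d.advalorem_amount:.2f}, margin {d.margin:.2f}")
print(f"baseline tax burden: {w.tax_burden([d], [1.0]):.1%}")

result = w.run_secondary_who(target_burden=0.75)
print(f"\nsimple approach, 75% target burden:")
print(f"  solved specific excise: {result.specific:.2f} USD per 20 g unit")
print(f"  retail price: {d.retail:.2f} -> {result.weighted_price:.2f} USD")
print(f"  consumption change: {result.consumption_change_pct:.1f}%")
print(f"  premature deaths averted: {result.deaths_averted:,.0f}")
print(f"  revenue change: {result.revenue_change_pct:+.0f}%")
print("\nA ~0.4 USD excise suffices here only because the single share "
      "ignores the cheap, lightly taxed home segments that dominate actual "
      "consumption.")
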