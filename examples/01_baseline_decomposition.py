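"""Decompose the Egyptian market's baseline retail prices.

Builds the packaged four-segment market and splits each segment's observed
retail price into CIF/ex-factory cost, import duty, ad valorem excise and
industry margin, then aggregates with baseline consumption weights.
"""

import wptaxsim as w

market = w.egypt_market()
print(f"{'segment':18} {'price':>6} {'cif':>6} {'duty':>6} "
      f"{'advalorem':>9} {'margin':>7} {'tax share':>9}")
decomps = [w.decompose_baseline(s) for s in market.segments]
for seg, d in zip(market.segments, decomps):
    print(f"{seg.name:18} {d.retail:6.2f} {d.cif:6.2f} {d.duty_amount:6.3f} "
          f"{d.advalorem_amount:9.3f} {d.margin:7.3f} {d.burden:8.1%}")

shares = [s.share for s in market.segments]
avg = w.weighted_average(decomps, shares)
burden = w.tax_burden(decomps, shares)
print(f"\nweighted retail price: {avg.retail:.2f} USD per 20 g unit")
print(f"market-weighted tax burden: {burden:.1%}")
print("\nOnly ~39% of the average price is tax; the premium cafe segments "
      "carry a ~50% industry margin, the cheap home segment almost none.")
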