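"""Transfer waterpipe elasticities from neighbouring countries.

Where no local waterpipe price-elasticity estimates exist, per-segment
estimates can be borrowed: form the waterpipe/cigarette elasticity ratio in
each neighbour, average the ratios per segment, and apply the mean ratio to
the local cigarette elasticity.  The table below is a toy illustration.
"""

import wptaxsim as w
from wptaxsim.elasticity import ElasticityTable

table = ElasticityTable.from_records([
    # country, segment,        waterpipe, cigarette
    ("neighbour_A", "cafe_flavoured",   -0.55, -0.45),
    ("neighbour_A", "home_unflavoured", -0.70, -0.45),
    ("neighbour_B", "cafe_flavoured",   -0.50, -0.42),
    ("neighbour_B", "home_unflavoured", -0.58, -0.42),
    ("neighbour_C", "cafe_flavoured",   -0.48, -0.40),
    ("neighbour_C", "home_unflavoured", -0.65, -0.40),
])

local_cigarette = -0.397  # the only locally estimated elasticity
out = w.transfer(table, local_cigarette)
print(f"local cigarette elasticity: {local_cigarette}")
for seg, e in out.items():
    print(f"  transferred waterpipe elasticity, {seg}: {e:.3f}")
print("\nEach value is (mean waterpipe/cigarette ratio across neighbours) x "
      "the local cigarette elasticity; ratios > 1 mean waterpipe demand is "
      "more price-responsive than cigarette demand in that segment.")
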