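# Single-share market matching the WHO global-report tax-structure data for
# Egyptian waterpipe tobacco: one "premium home" share with CIF 0.09, import
# duty 0.01, ad valorem 0.32, industry margin 0.05, retail 0.47 (USD per 20 g).
# The elasticity is the home-flavoured (premium home) estimate.
name: who_single_share
base_quantity: 3670117434
segments:
  - name: premium_home
    share: 1.0
    base_price: 0.47
    elasticity: -0.321
    cif: 0.09
    duty_rate: 0.1111111111111111   # 0.01 USD duty on a 0.09 USD CIF
    advalorem_rate: 3.2             # 0.32 USD on CIF + duty = 0.10 USD
    specific: 0.0
mortality:
  quit_fraction: 0.5
  mortality_fraction: 0.35
  prevalence_current: 0.045
  population: 60409575
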