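# Four-segment Egyptian waterpipe tobacco market, 2022 tax rules.
# Prices are USD per 20 g unit; shares are fractions of baseline consumption.
# base_quantity is the calibrated annual consumption in 20 g units.
name: egypt_2022
base_quantity: 3670117434
segments:
  - name: cafe_flavoured
    share: 0.189
    base_price: 2.09
    elasticity: -0.489
    cif: 0.30
    duty_rate: 0.167
    advalorem_rate: 2.00
    specific: 0.0
  - name: cafe_unflavoured
    share: 0.277
    base_price: 0.20
    elasticity: -0.445
    cif: 0.07
    duty_rate: 0.0
    advalorem_rate: 1.65
    specific: 0.0
  - name: home_flavoured
    share: 0.021
    base_price: 2.11
    elasticity: -0.321
    cif: 0.30
    duty_rate: 0.167
    advalorem_rate: 2.00
    specific: 0.0
  - name: home_unflavoured
    share: 0.513
    base_price: 0.07
    elasticity: -0.592
    cif: 0.02
    duty_rate: 0.0
    advalorem_rate: 1.65
    specific: 0.0
population_15plus: 67589102
consumption:
  prevalence_daily: 0.03
  units_per_session: 2.8
  sessions_per_day: 3.6
  population: 60409575        # World Bank count matched to the survey age range
  illicit_fraction: 0.035
  days_per_year: 365.25
mortality:
  quit_fraction: 0.5
  mortality_fraction: 0.35
  prevalence_current: 0.045   # daily + non-daily use; base = 0.045 * population_15plus
adjustment:
  exchange_rate: 0.0531892    # USD per EGP, mid-year 2022
  inflation_rates:
    2017: 0.298
    2018: 0.144
    2019: 0.094
    2020: 0.056
    2021: 0.049
    2022: 0.132
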