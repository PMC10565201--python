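"""Market domain types, config loading/validation and adjustment utilities."""

import dataclasses
import math

import pytest

import wptaxsim as w
from wptaxsim.markets import MarketValidationError
from wptaxsim.synth import SynthSpec, generate_market


def egypt_doc():
    return {
        "name": "egypt",
        "base_quantity": 3_670_117_434,
        "segments": [
            {"name": "cafe_flavoured", "share": 0.189, "base_price": 2.09,
             "elasticity": -0.489, "cif": 0.30, "duty_rate": 0.167,
             "advalorem_rate": 2.00},
            {"name": "cafe_unflavoured", "share": 0.277, "base_price": 0.20,
             "elasticity": -0.445, "cif": 0.07, "advalorem_rate": 1.65},
            {"name": "home_flavoured", "share": 0.021, "base_price": 2.11,
             "elasticity": -0.321, "cif": 0.30, "duty_rate": 0.167,
             "advalorem_rate": 2.00},
            {"name": "home_unflavoured", "share": 0.513, "base_price": 0.07,
             "elasticity": -0.592, "cif": 0.02, "advalorem_rate": 1.65},
        ],
    }


class TestLoadMarket:
    def test_four_segment_market_loads(self):
        market = w.load_market(egypt_doc())
        assert market.segment_names == ("cafe_flavoured", "cafe_unflavoured",
                                        "home_flavoured", "home_unflavoured")
        assert market.segments[0].share == pytest.approx(0.189)
        assert [s.base_price for s in market.segments] == [2.09, 0.20, 2.11, 0.07]

    def test_single_segment_share_one_is_valid(self):
        doc = {"base_quantity": 100.0, "segments": [
            {"name": "only", "share": 1.0, "base_price": 1.0,
             "elasticity": -0.5, "cif": 0.1}]}
        market = w.load_market(doc)
        assert market.segments[0].share == 1.0

    def test_shares_not_summing_to_one_rejected(self):
        doc = egypt_doc()
        doc["segments"][0]["share"] = 0.089  # sums to 0.9
        with pytest.raises(MarketValidationError, match="sum to 1"):
            w.load_market(doc)

    def test_missing_field_names_field_and_segment(self):
        doc = egypt_doc()
        del doc["segments"][1]["elasticity"]
        with pytest.raises(MarketValidationError,
                           match="cafe_unflavoured.*elasticity"):
            w.load_market(doc)

    def test_negative_margin_rejected_with_segment_name(self):
        doc = egypt_doc()
        doc["segments"][3]["cif"] = 0.05  # taxes + cif exceed the 0.07 price
        with pytest.raises(MarketValidationError, match="home_unflavoured"):
            w.load_market(doc)

    def test_positive_elasticity_requires_magnitude_flag(self):
        doc = egypt_doc()
        for seg in doc["segments"]:
            seg["elasticity"] = abs(seg["elasticity"])
        with pytest.raises(MarketValidationError, match="magnitude"):
            w.load_market(doc)
        market = w.load_market(doc, elasticities_are_magnitudes=True)
        assert market.segments[0].elasticity == pytest.approx(-0.489)

    def test_duplicate_segment_names_rejected(self):
        doc = egypt_doc()
        doc["segments"][1]["name"] = "cafe_flavoured"
        with pytest.raises(MarketValidationError, match="unique"):
            w.load_market(doc)

    def test_packaged_fixtures_load(self):
        egypt = w.egypt_market()
        assert len(egypt.segments) == 4
        who = w.who_single_share_market()
        assert len(who.segments) == 1
        assert who.segments[0].base_price == pytest.approx(0.47)

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_preserves_all_numeric_fields(self, tmp_path, seed):
        market = generate_market(SynthSpec(n_segments=3, seed=seed))
        path = tmp_path / "market.yaml"
        w.write_market(market, path)
        back = w.load_market(path)
        assert back.base_quantity == pytest.approx(market.base_quantity, abs=1e-12)
        for a, b in zip(market.segments, back.segments):
            for f in dataclasses.fields(a):
                va, vb = getattr(a, f.name), getattr(b, f.name)
                if isinstance(va, float):
                    assert vb == pytest.approx(va, abs=1e-12)
                else:
                    assert va == vb


class TestAdjustments:
    def test_single_year_inflation(self):
        factors = w.AdjustmentFactors(exchange_rate=0.0531892,
                                      inflation_rates={2022: 0.132})
        assert w.inflation_factor(factors, 2021, 2022) == pytest.approx(1.132)

    def test_same_year_is_identity(self):
        factors = w.egypt_adjustment()
        assert w.inflation_factor(factors, 2022, 2022) == 1.0

    def test_multi_year_product(self):
        factors = w.egypt_adjustment()
        expected = 1.144 * 1.094 * 1.056 * 1.049 * 1.132
        assert w.inflation_factor(factors, 2017, 2022) == pytest.approx(expected)

    def test_missing_year_raises(self):
        factors = w.AdjustmentFactors(exchange_rate=1.0,
                                      inflation_rates={2022: 0.1})
        with pytest.raises(KeyError, match="2021"):
            w.inflation_factor(factors, 2020, 2022)

    @pytest.mark.parametrize("egp, usd", [
        (100.0, 5.31892),
        (0.0, 0.0),
        (18.8, 0.99995696),
    ])
    def test_currency_conversion(self, egp, usd):
        assert w.convert_currency(egp, w.egypt_adjustment()) == pytest.approx(usd)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            w.convert_currency(-1.0, w.egypt_adjustment())


def test_mortality_base_computed_from_prevalence():
    mort = w.egypt_mortality()
    assert mort.smoker_base == pytest.approx(0.045 * 67_589_102)
    assert mort.quit_fraction == 0.5
    assert mort.mortality_fraction == 0.35


def test_consumption_inputs_validate_fractions():
    with pytest.raises(MarketValidationError):
        w.ConsumptionInputs(prevalence_daily=1.5, units_per_session=1,
                            sessions_per_day=1, population=1)


def test_validated_market_satisfies_type_invariants():
    """Any market passing validation has consistent shares, prices, margins."""
    for seed in range(50):
        market = generate_market(SynthSpec(n_segments=1 + seed % 6, seed=seed))
        assert math.isclose(sum(s.share for s in market.segments), 1.0,
                            abs_tol=1e-9)
        for s in market.segments:
            assert s.base_price > 0 and s.elasticity < 0 and s.cif >= 0
            duty = s.duty_rate * s.cif
            assert (s.cif + duty + s.advalorem_rate * (s.cif + duty)
                    <= s.base_price + 1e-9)
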