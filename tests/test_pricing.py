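"""Price decomposition, policy application and weighted aggregates."""

import pytest
from hypothesis import given, strategies as st

import wptaxsim as w
from wptaxsim.pricing import APPROACH_MIXED, APPROACH_SIMPLE
from wptaxsim.synth import SynthSpec, generate_market


@pytest.fixture(scope="module")
def egypt_segments():
    return {s.name: s for s in w.egypt_market().segments}


class TestDecomposeBaseline:
    def test_home_unflavoured_hand_arithmetic(self, egypt_segments):
        d = w.decompose_baseline(egypt_segments["home_unflavoured"])
        assert d.duty_amount == pytest.approx(0.0)
        assert d.advalorem_amount == pytest.approx(0.033)  # 1.65 * 0.02
        assert d.margin == pytest.approx(0.017)
        assert d.retail == pytest.approx(0.07)

    def test_cafe_flavoured_hand_arithmetic(self, egypt_segments):
        d = w.decompose_baseline(egypt_segments["cafe_flavoured"])
        assert d.duty_amount == pytest.approx(0.0501)       # 16.7% of 0.30
        assert d.advalorem_amount == pytest.approx(0.70020)  # 200% of 0.3501
        assert d.margin == pytest.approx(1.0397, abs=1e-4)

    def test_zero_margin_boundary(self):
        seg = w.MarketSegment(name="tight", share=1.0, base_price=0.4,
                              elasticity=-0.5, cif=0.2, advalorem_rate=1.0)
        d = w.decompose_baseline(seg)
        assert d.margin == pytest.approx(0.0, abs=1e-12)


class TestApplyPolicy:
    def test_simple_policy_on_home_unflavoured(self, egypt_segments):
        base = w.decompose_baseline(egypt_segments["home_unflavoured"])
        new = w.apply_policy(base, w.TaxPolicy(APPROACH_SIMPLE, specific=2.08))
        # 0.02 cif + 2.08 specific + 0.017 margin, ad valorem removed
        assert new.retail == pytest.approx(2.117)
        assert new.advalorem_amount == 0.0

    def test_identity_policy_leaves_decomposition_unchanged(self, egypt_segments):
        base = w.decompose_baseline(egypt_segments["cafe_unflavoured"])
        new = w.apply_policy(base, w.TaxPolicy(APPROACH_MIXED, specific=0.0))
        assert new == base

    def test_mixed_policy_on_cafe_flavoured(self, egypt_segments):
        base = w.decompose_baseline(egypt_segments["cafe_flavoured"])
        new = w.apply_policy(base, w.TaxPolicy(APPROACH_MIXED, specific=1.58))
        # 0.30 + 0.0501 + 1.58 + 0.7002 + 1.0397
        assert new.retail == pytest.approx(3.670, abs=1e-3)

    def test_zero_shift_leaves_margin_exactly_unchanged(self, egypt_segments):
        for seg in egypt_segments.values():
            base = w.decompose_baseline(seg)
            new = w.apply_policy(base, w.TaxPolicy(APPROACH_SIMPLE, specific=1.3))
            assert new.margin == base.margin

    def test_overshift_adds_fraction_of_tax_change_to_margin(self, egypt_segments):
        base = w.decompose_baseline(egypt_segments["cafe_flavoured"])
        policy = w.TaxPolicy(APPROACH_MIXED, specific=1.0, shift_rate=0.10)
        new = w.apply_policy(base, policy)
        assert new.margin == pytest.approx(base.margin + 0.10 * 1.0)

    def test_undershift_floors_margin_at_zero_with_warning(self, egypt_segments):
        base = w.decompose_baseline(egypt_segments["home_unflavoured"])
        policy = w.TaxPolicy(APPROACH_SIMPLE, specific=2.0, shift_rate=-0.5)
        with pytest.warns(UserWarning, match="flooring"):
            new = w.apply_policy(base, policy)
        assert new.margin == 0.0

    def test_component_sum_identity_preserved(self, egypt_segments):
        for seg in egypt_segments.values():
            for policy in (w.TaxPolicy(APPROACH_SIMPLE, 0.5),
                           w.TaxPolicy(APPROACH_MIXED, 2.0, shift_rate=0.1)):
                d = w.apply_policy(w.decompose_baseline(seg), policy)
                total = (d.cif + d.duty_amount + d.specific
                         + d.advalorem_amount + d.margin)
                assert d.retail == pytest.approx(total, abs=1e-9)


class TestWeightedAggregates:
    def test_baseline_weighted_retail_price(self, egypt):
        decomps = [w.decompose_baseline(s) for s in egypt.segments]
        avg = w.weighted_average(decomps, [s.share for s in egypt.segments])
        assert avg.retail == pytest.approx(0.53, abs=0.01)

    def test_identical_decomps_any_weights(self, egypt_segments):
        d = w.decompose_baseline(egypt_segments["cafe_flavoured"])
        avg = w.weighted_average([d, d, d], [1.0, 5.0, 0.2])
        for f in ("cif", "duty_amount", "specific", "advalorem_amount",
                  "margin", "retail"):
            assert getattr(avg, f) == pytest.approx(getattr(d, f), abs=1e-12)

    def test_all_zero_weights_rejected(self, egypt_segments):
        d = w.decompose_baseline(egypt_segments["cafe_flavoured"])
        with pytest.raises(ValueError, match="zero"):
            w.weighted_average([d, d], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            w.tax_burden([d, d], [0.0, 0.0])

    def test_egypt_baseline_burden(self, egypt):
        decomps = [w.decompose_baseline(s) for s in egypt.segments]
        burden = w.tax_burden(decomps, [s.share for s in egypt.segments])
        assert burden == pytest.approx(0.391, abs=0.005)

    def test_zero_tax_decomps_have_zero_burden(self):
        d = w.PriceDecomposition(cif=0.5, duty_amount=0, specific=0,
                                 advalorem_amount=0, margin=0.5, retail=1.0)
        assert w.tax_burden([d], [1.0]) == 0.0

    def test_who_single_share_burden(self):
        who = w.who_single_share_market().segments[0]
        d = w.decompose_baseline(who)
        # 0.01 duty + 0.32 ad valorem over a 0.47 retail price
        assert w.tax_burden([d], [1.0]) == pytest.approx(0.704, abs=0.003)


@given(st.integers(0, 500), st.floats(0.0, 5.0), st.floats(0.01, 3.0))
def test_burden_strictly_increasing_in_specific(seed, s_low, gap):
    """With fixed weights and margins, a higher specific excise always raises
    the tax share of the retail price."""
    market = generate_market(SynthSpec(n_segments=1 + seed % 5, seed=seed))
    decomps = [w.decompose_baseline(s) for s in market.segments]
    weights = [s.share for s in market.segments]
    for approach in (APPROACH_SIMPLE, APPROACH_MIXED):
        b_low = w.tax_burden(
            [w.apply_policy(d, w.TaxPolicy(approach, s_low)) for d in decomps],
            weights)
        b_high = w.tax_burden(
            [w.apply_policy(d, w.TaxPolicy(approach, s_low + gap)) for d in decomps],
            weights)
        assert b_high > b_low
        assert 0.0 <= b_low < 1.0
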