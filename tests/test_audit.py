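"""Stock-flow RA estimation, exclusion rules, aggregation, accounting."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slsagree.audit import (
    PairedEstimate,
    SurveyRecord,
    aggregate_outlets,
    build_pairs,
    ra_estimate,
    response_accounting,
    screen_ra,
)
from slsagree.products import Category

from conftest import make_record


class TestRaEstimate:
    @pytest.mark.parametrize(
        "s1,dlv,dsp,s2,expected",
        [(10, 5, 1, 8, 6), (7, 0, 0, 7, 0), (2, 0, 0, 5, -3)],
    )
    def test_stock_flow_arithmetic(self, s1, dlv, dsp, s2, expected):
        assert ra_estimate(s1, dlv, dsp, s2) == expected

    @pytest.mark.parametrize("value,status", [
        (6, "valid"),
        (0, "valid"),            # zero sales are legitimate
        (-3, "negative_excluded"),
    ])
    def test_negative_screen(self, value, status):
        assert screen_ra(value) == status


class TestBuildPairs:
    def specs(self, am_spec, rdt_spec, incomputable_spec):
        return {s.product_id: s for s in (am_spec, rdt_spec, incomputable_spec)}

    def test_clean_record_pairs(self, am_spec, rdt_spec, incomputable_spec):
        # stock flow 10 + 0 - 0 - 4 = 6 tablets -> 0.25 AETD; rc 5 -> 5/24
        recs = [make_record(stock1=10, stock2=4, rc_sold=5)]
        pairs, excl = build_pairs(recs, self.specs(am_spec, rdt_spec, incomputable_spec))
        assert excl == []
        (p,) = pairs
        assert p.included
        assert p.ra_volume == pytest.approx(6 / 24)
        assert p.rc_volume == pytest.approx(5 / 24)

    def test_status_in_any_ra_component_voids_ra(self, am_spec, rdt_spec, incomputable_spec):
        specs = self.specs(am_spec, rdt_spec, incomputable_spec)
        for field in ("stock1", "stock2", "delivered", "disposed"):
            recs = [make_record(**{field: "refused"})]
            pairs, excl = build_pairs(recs, specs)
            assert pairs[0].ra_status == "unavailable"
            assert not pairs[0].included
            assert excl[0].reason == "ra_unavailable"
            assert field.replace("stock1", "stock_sls1").replace("stock2", "stock_sls2") \
                in excl[0].detail

    def test_rc_not_remembered_keeps_ra_side_accounting(self, am_spec, rdt_spec, incomputable_spec):
        recs = [make_record(rc_sold="not_remembered")]
        pairs, excl = build_pairs(recs, self.specs(am_spec, rdt_spec, incomputable_spec))
        (p,) = pairs
        assert p.ra_status == "valid" and p.rc_status == "unavailable"
        assert not p.included
        assert excl[0].reason == "rc_unavailable"

    def test_negative_ra_excluded_but_value_logged(self, am_spec, rdt_spec, incomputable_spec):
        recs = [make_record(stock1=2, stock2=5)]
        pairs, excl = build_pairs(recs, self.specs(am_spec, rdt_spec, incomputable_spec))
        (p,) = pairs
        assert p.ra_status == "negative_excluded"
        assert excl[0].reason == "negative_ra"
        # 2 + 0 - 0 - 5 = -3 tablets = -0.125 AETD, retained in the log
        assert excl[0].detail == "ra=-0.125"

    def test_incomputable_product_logged_exactly_once(self, am_spec, rdt_spec, incomputable_spec):
        recs = [make_record(product_id="AM-X")]
        pairs, excl = build_pairs(recs, self.specs(am_spec, rdt_spec, incomputable_spec))
        assert pairs == []
        assert len(excl) == 1 and excl[0].reason == "aetd_incomputable"

    def test_unknown_product_hard_error(self, am_spec):
        with pytest.raises(KeyError, match="NOPE"):
            build_pairs([make_record(product_id="NOPE")], {"AM-T": am_spec})

    def test_duplicate_outlet_product_hard_error(self, am_spec):
        recs = [make_record(), make_record()]
        with pytest.raises(ValueError, match="duplicate"):
            build_pairs(recs, {"AM-T": am_spec})

    def test_every_record_accounted_once(self, am_spec, rdt_spec, incomputable_spec):
        specs = self.specs(am_spec, rdt_spec, incomputable_spec)
        recs = [
            make_record(outlet_id="O1"),
            make_record(outlet_id="O2", stock1=2, stock2=5),
            make_record(outlet_id="O3", rc_sold="refused"),
            make_record(outlet_id="O4", product_id="AM-X"),
            make_record(outlet_id="O5", stock1="refused", rc_sold="not_remembered"),
        ]
        pairs, excl = build_pairs(recs, specs)
        n_included = sum(1 for p in pairs if p.included)
        assert n_included + len(excl) == len(recs)


class TestAggregateOutlets:
    def _pair(self, outlet, ra, rc, cat=Category.ANTIMALARIAL, status="valid"):
        from slsagree.audit import ProductPair
        return ProductPair(
            outlet_id=outlet, product_id=f"p{ra}{rc}", category=cat,
            ra_volume=ra, rc_volume=rc, ra_status=status, rc_status="valid",
        )

    def test_sums_within_category(self):
        pairs = [self._pair("O1", 2, 1), self._pair("O1", 3, 3)]
        (est,) = aggregate_outlets(pairs)
        assert (est.ra_total, est.rc_total, est.n_products) == (5, 4, 2)

    def test_categories_never_pooled(self):
        pairs = [self._pair("O1", 2, 1), self._pair("O1", 3, 3, cat=Category.RDT)]
        ests = aggregate_outlets(pairs)
        assert len(ests) == 2
        assert {e.category for e in ests} == {Category.ANTIMALARIAL, Category.RDT}

    def test_outlet_with_only_excluded_pair_absent(self):
        pairs = [self._pair("O1", -3, 1, status="negative_excluded")]
        assert aggregate_outlets(pairs) == []

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, derandomize=True)
    def test_permutation_invariant(self, rnd):
        pairs = [self._pair(f"O{i % 5}", i, i + 1) for i in range(12)]
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        assert aggregate_outlets(pairs) == aggregate_outlets(shuffled)


class TestResponseAccounting:
    def test_wholesale_fixture_percentages(self, am_spec):
        """104 surveyed, 76 collected, 17 not remembered, 11 refused."""
        recs = []
        statuses = [5] * 76 + ["not_remembered"] * 17 + ["refused"] * 11
        for i, rc in enumerate(statuses):
            recs.append(make_record(outlet_id=f"W{i}", rc_sold=rc, level="wholesale"))
        pairs, _ = build_pairs(recs, {"AM-T": am_spec})
        acc = response_accounting(recs, pairs, {"AM-T": am_spec})
        s = acc.get("wholesale", Category.ANTIMALARIAL)
        assert s.n_surveyed == 104
        assert (s.rc.n_collected, s.rc.n_not_remembered, s.rc.n_refused) == (76, 17, 11)
        pcts = [round(100 * n / 104, 1) for n in (76, 17, 11)]
        assert pcts == [73.1, 16.3, 10.6]
        assert s.rc.closed

    def test_no_missingness_means_all_collected(self, am_spec):
        recs = [make_record(outlet_id=f"O{i}") for i in range(20)]
        pairs, _ = build_pairs(recs, {"AM-T": am_spec})
        acc = response_accounting(recs, pairs, {"AM-T": am_spec})
        s = acc.get("retail", Category.ANTIMALARIAL)
        for comp in (s.rc, s.stock, s.received, s.disposed):
            assert comp.n_collected == s.n_surveyed == 20

    def test_ra_rows_including_vs_excluding_negatives(self, am_spec):
        recs = [
            make_record(outlet_id="O1"),                      # RA = 6
            make_record(outlet_id="O2", stock1=2, stock2=5),  # RA = -3
            make_record(outlet_id="O3", stock1="refused"),    # RA unavailable
        ]
        pairs, _ = build_pairs(recs, {"AM-T": am_spec})
        acc = response_accounting(recs, pairs, {"AM-T": am_spec})
        s = acc.get("retail", Category.ANTIMALARIAL)
        assert s.n_ra_including_negative == 2
        assert s.n_ra_nonnegative == 1
        assert s.n_ra_including_negative >= s.n_ra_nonnegative
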