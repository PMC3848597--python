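import logging

import pytest

from slsagree.products import Category, Form, ProductSpec, QuantityObservation
from slsagree.audit import SurveyRecord

logging.getLogger("slsagree").setLevel(logging.ERROR)


@pytest.fixture
def am_spec():
    """Anti-malarial tablet product: pack of 12, 24 tablets per adult course."""
    return ProductSpec(
        product_id="AM-T", category=Category.ANTIMALARIAL, drug_name="chloroquine",
        form=Form.TABLET, pack_size=12, strength_mg=150.0, units_per_aetd=24.0,
    )


@pytest.fixture
def rdt_spec():
    return ProductSpec(
        product_id="RDT-T", category=Category.RDT, drug_name="malaria pf rdt",
        form=Form.TEST, pack_size=25,
    )


@pytest.fixture
def incomputable_spec():
    """Anti-malarial with unknown conversion: AETD-incomputable."""
    return ProductSpec(
        product_id="AM-X", category=Category.ANTIMALARIAL, drug_name="quinine",
        form=Form.TABLET, pack_size=10,
    )


def loose(units, flag="counted"):
    return QuantityObservation(full_packs=0, loose_units=units, counted_flag=flag)


def make_record(
    outlet_id="O1",
    product_id="AM-T",
    stock1=10,
    stock2=4,
    delivered=0,
    disposed=0,
    rc_sold=5,
    level="retail",
    outlet_type="pharmacy",
):
    """Record with unit counts; pass a status string to any field instead."""
    def stock_field(v):
        return v if isinstance(v, str) else loose(v)

    return SurveyRecord(
        outlet_id=outlet_id, outlet_level=level, outlet_type=outlet_type,
        product_id=product_id,
        stock_sls1=stock_field(stock1), stock_sls2=stock_field(stock2),
        delivered=delivered, disposed=disposed, rc_sold=rc_sold,
    )
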