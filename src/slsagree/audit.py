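"""Retail-audit (RA) estimation, pairing with recall (RC), and accounting.

The RA estimate for one outlet x product over the two-week inter-visit
interval is the stock-flow identity

    RA = stock(SLS1) + delivered - disposed - stock(SLS2)

computed on exact base units (tablets, ampoules, tests) and then expressed
in AETDs (test units for RDTs) — the conversion is linear, so the order
does not change the estimate but keeps the arithmetic exact.  Strictly
negative RA values indicate data-collection errors and are screened out;
zero is a legitimate estimate.  A pair enters the agreement analysis only
when both the RA and the RC estimate exist.  Valid pairs are summed per
outlet within each product category (anti-malarials and RDTs are never
pooled), yielding one paired total per outlet x category.

Every record is accounted for exactly once: it either contributes a valid
pair or appears in the exclusion log with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .products import (
    AetdIncomputableError,
    Category,
    ProductSpec,
    QuantityObservation,
    to_aetd,
    total_units,
)

__all__ = [
    "STATUS_CODES",
    "SurveyRecord",
    "ProductPair",
    "PairedEstimate",
    "ExclusionRecord",
    "ComponentCounts",
    "StratumAccounting",
    "ResponseAccounting",
    "ra_estimate",
    "screen_ra",
    "build_pairs",
    "aggregate_outlets",
    "response_accounting",
]

#: Codes a measurement field may carry instead of a quantity.
STATUS_CODES = ("refused", "not_remembered", "missing")

# A measurement field: either a resolved quantity/observation or a status code.
StockField = Union[QuantityObservation, str]
CountField = Union[float, int, str]


def _is_status(value) -> bool:
    return isinstance(value, str)


def _check_field(name: str, value, allow_negative: bool = True) -> None:
    if _is_status(value):
        if value not in STATUS_CODES:
            raise ValueError(f"{name}: unknown status code {value!r}")
    elif not allow_negative and value < 0:
        raise ValueError(f"{name}: quantity must be >= 0, got {value}")


@dataclass(frozen=True)
class SurveyRecord:
    """One outlet x product observation carrying both methods' raw fields.

    Each of the five measurement fields is either a quantity (a
    :class:`QuantityObservation` for the two stock fields, a unit count for
    the rest) or exactly one status code from :data:`STATUS_CODES`.
    """

    outlet_id: str
    outlet_level: str  # "wholesale" | "retail"
    outlet_type: str
    product_id: str
    stock_sls1: StockField
    stock_sls2: StockField
    delivered: CountField
    disposed: CountField
    rc_sold: CountField

    def __post_init__(self) -> None:
        if self.outlet_level not in ("wholesale", "retail"):
            raise ValueError(f"outlet_level must be wholesale|retail, got {self.outlet_level!r}")
        for name in ("stock_sls1", "stock_sls2"):
            value = getattr(self, name)
            if _is_status(value) and value not in STATUS_CODES:
                raise ValueError(f"{name}: unknown status code {value!r}")
        _check_field("delivered", self.delivered)
        _check_field("disposed", self.disposed)
        _check_field("rc_sold", self.rc_sold, allow_negative=False)


@dataclass(frozen=True)
class ProductPair:
    outlet_id: str
    product_id: str
    category: Category
    ra_volume: Optional[float]  # signed; retained even when negative_excluded
    rc_volume: Optional[float]
    ra_status: str  # "valid" | "negative_excluded" | "unavailable"
    rc_status: str  # "valid" | "unavailable"
    outlet_level: str = "retail"

    @property
    def included(self) -> bool:
        return self.ra_status == "valid" and self.rc_status == "valid"


@dataclass(frozen=True)
class PairedEstimate:
    outlet_id: str
    category: Category
    ra_total: float
    rc_total: float
    n_products: int
    outlet_level: str = "retail"


@dataclass(frozen=True)
class ExclusionRecord:
    outlet_id: str
    product_id: str
    reason: str
    detail: str = ""


def ra_estimate(stock1: float, delivered: float, disposed: float, stock2: float) -> float:
    """Stock-flow sales estimate; may be negative (screened separately)."""
    return stock1 + delivered - disposed - stock2


def screen_ra(value: float) -> str:
    """Classify an RA estimate: >= 0 is ``valid``, < 0 is ``negative_excluded``."""
    return "valid" if value >= 0 else "negative_excluded"


def _resolve_stock(field_value: StockField, spec: ProductSpec) -> Tuple[Optional[float], Optional[str]]:
    """Return (base-unit count, None) or (None, status code)."""
    if _is_status(field_value):
        return None, field_value
    return total_units(field_value, spec), None


def _resolve_count(field_value: CountField, spec: ProductSpec) -> Tuple[Optional[float], Optional[str]]:
    if _is_status(field_value):
        return None, field_value
    return float(field_value), None


def build_pairs(
    records: Sequence[SurveyRecord],
    specs: Mapping[str, ProductSpec],
) -> Tuple[List[ProductPair], List[ExclusionRecord]]:
    """Standardize, compute RA, screen, and pair with RC for every record.

    Returns one :class:`ProductPair` per outlet x product plus the exclusion
    log.  A status code in any of the four RA components voids the whole RA
    estimate (the formula needs all four terms).  AETD-incomputable products
    leave the analysis entirely and are logged once.

    Raises on unknown ``product_id`` and on duplicate outlet x product.
    """
    pairs: List[ProductPair] = []
    exclusions: List[ExclusionRecord] = []
    seen: set = set()

    for rec in records:
        if rec.product_id not in specs:
            raise KeyError(f"unknown product_id {rec.product_id!r} in survey records")
        key = (rec.outlet_id, rec.product_id)
        if key in seen:
            raise ValueError(f"duplicate outlet x product record: {key}")
        seen.add(key)
        spec = specs[rec.product_id]

        if spec.aetd_incomputable:
            exclusions.append(
                ExclusionRecord(rec.outlet_id, rec.product_id, "aetd_incomputable")
            )
            continue

        ra_components = {}
        ra_missing = []
        for name, resolver, value in (
            ("stock_sls1", _resolve_stock, rec.stock_sls1),
            ("stock_sls2", _resolve_stock, rec.stock_sls2),
            ("delivered", _resolve_count, rec.delivered),
            ("disposed", _resolve_count, rec.disposed),
        ):
            vol, status = resolver(value, spec)
            if status is not None:
                ra_missing.append(f"{name}={status}")
            else:
                ra_components[name] = vol

        rc_units, rc_code = _resolve_count(rec.rc_sold, spec)
        rc_status = "valid" if rc_code is None else "unavailable"
        rc_volume = to_aetd(rc_units, spec) if rc_units is not None else None

        if ra_missing:
            ra_status, ra_volume = "unavailable", None
        else:
            # stock-flow difference on exact base units, AETD-converted after;
            # identical by linearity of the conversion, and float-safe (no
            # spurious negative residue from per-component division)
            ra_units = ra_estimate(
                ra_components["stock_sls1"],
                ra_components["delivered"],
                ra_components["disposed"],
                ra_components["stock_sls2"],
            )
            ra_status = screen_ra(ra_units)
            ra_volume = to_aetd(ra_units, spec)

        pair = ProductPair(
            outlet_id=rec.outlet_id,
            product_id=rec.product_id,
            category=spec.category,
            ra_volume=ra_volume,
            rc_volume=rc_volume,
            ra_status=ra_status,
            rc_status=rc_status,
            outlet_level=rec.outlet_level,
        )
        pairs.append(pair)

        if not pair.included:
            if ra_status == "negative_excluded":
                reason, detail = "negative_ra", f"ra={ra_volume:g}"
                if rc_status == "unavailable":
                    detail += f"; rc={rc_code}"
            elif ra_status == "unavailable" and rc_status == "unavailable":
                reason, detail = "ra_and_rc_unavailable", f"{'; '.join(ra_missing)}; rc={rc_code}"
            elif ra_status == "unavailable":
                reason, detail = "ra_unavailable", "; ".join(ra_missing)
            else:
                reason, detail = "rc_unavailable", f"rc={rc_code}"
            exclusions.append(ExclusionRecord(rec.outlet_id, rec.product_id, reason, detail))

    return pairs, exclusions


def aggregate_outlets(pairs: Iterable[ProductPair]) -> List[PairedEstimate]:
    """Sum valid pairs to one total per outlet x category.

    Only (valid, valid) pairs contribute; anti-malarials and RDTs are never
    pooled.  Output order is deterministic (sorted by outlet then category)
    so the result is invariant to input permutation.
    """
    acc: Dict[Tuple[str, Category], List[ProductPair]] = {}
    for p in pairs:
        if p.included:
            acc.setdefault((p.outlet_id, p.category), []).append(p)

    out: List[PairedEstimate] = []
    for (outlet_id, category) in sorted(acc, key=lambda k: (k[0], k[1].value)):
        members = acc[(outlet_id, category)]
        ra_total = sum(p.ra_volume for p in members)
        rc_total = sum(p.rc_volume for p in members)
        assert ra_total >= 0 and rc_total >= 0  # each included pair is >= 0
        out.append(
            PairedEstimate(
                outlet_id=outlet_id,
                category=category,
                ra_total=ra_total,
                rc_total=rc_total,
                n_products=len(members),
                outlet_level=members[0].outlet_level,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Response accounting (Table-1-style)
# ---------------------------------------------------------------------------

@dataclass
class ComponentCounts:
    """Nonresponse breakdown for one measurement component in one stratum."""

    n_surveyed: int = 0
    n_collected: int = 0
    n_not_remembered: int = 0
    n_refused: int = 0
    n_missing: int = 0

    def add(self, status: Optional[str]) -> None:
        self.n_surveyed += 1
        if status is None:
            self.n_collected += 1
        elif status == "not_remembered":
            self.n_not_remembered += 1
        elif status == "refused":
            self.n_refused += 1
        elif status == "missing":
            self.n_missing += 1
        else:  # pragma: no cover
            raise ValueError(f"unknown status {status!r}")

    @property
    def closed(self) -> bool:
        return (
            self.n_collected + self.n_not_remembered + self.n_refused + self.n_missing
            == self.n_surveyed
        )


@dataclass
class StratumAccounting:
    """Counts for one outlet_level x category stratum."""

    outlet_level: str
    category: Category
    n_surveyed: int = 0
    rc: ComponentCounts = field(default_factory=ComponentCounts)
    stock: ComponentCounts = field(default_factory=ComponentCounts)
    received: ComponentCounts = field(default_factory=ComponentCounts)
    disposed: ComponentCounts = field(default_factory=ComponentCounts)
    n_ra_nonnegative: int = 0
    n_ra_including_negative: int = 0


@dataclass
class ResponseAccounting:
    strata: Dict[Tuple[str, str], StratumAccounting]

    def get(self, outlet_level: str, category: Category) -> StratumAccounting:
        return self.strata[(outlet_level, category.value)]


def _stock_status(field_value: StockField) -> Optional[str]:
    return field_value if _is_status(field_value) else None


def _count_status(field_value: CountField) -> Optional[str]:
    return field_value if _is_status(field_value) else None


def response_accounting(
    records: Sequence[SurveyRecord],
    pairs: Sequence[ProductPair],
    specs: Mapping[str, ProductSpec],
) -> ResponseAccounting:
    """Tabulate collection/nonresponse counts per stratum and component.

    The stock row counts a product as collected only when both visits'
    stocks were obtained; when not, the SLS1 status (or else the SLS2
    status) is reported.  The two RA rows count products with a computed RA
    estimate, excluding vs including strictly negative values; both require
    all four stock-flow components and an AETD-computable product.
    """
    strata: Dict[Tuple[str, str], StratumAccounting] = {}

    def stratum_for(level: str, category: Category) -> StratumAccounting:
        key = (level, category.value)
        if key not in strata:
            strata[key] = StratumAccounting(outlet_level=level, category=category)
        return strata[key]

    for rec in records:
        spec = specs[rec.product_id]
        s = stratum_for(rec.outlet_level, spec.category)
        s.n_surveyed += 1
        s.rc.add(_count_status(rec.rc_sold))
        st1 = _stock_status(rec.stock_sls1)
        st2 = _stock_status(rec.stock_sls2)
        s.stock.add(st1 if st1 is not None else st2)
        s.received.add(_count_status(rec.delivered))
        s.disposed.add(_count_status(rec.disposed))

    for pair in pairs:
        s = stratum_for(pair.outlet_level, pair.category)
        if pair.ra_volume is not None:
            s.n_ra_including_negative += 1
            if pair.ra_status == "valid":
                s.n_ra_nonnegative += 1

    acc = ResponseAccounting(strata=strata)
    for s in strata.values():
        for comp in (s.rc, s.stock, s.received, s.disposed):
            assert comp.closed, "nonresponse categories must partition surveyed products"
        assert s.n_ra_including_negative >= s.n_ra_nonnegative
    return acc
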