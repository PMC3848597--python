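"""Synthetic sales-level-survey (SLS) generator.

Emulates a two-visit outlet survey of anti-malarials and RDTs in a
low-volume market: two outlet strata (wholesale, retail), a small product
catalogue, sales drawn from a zero-inflated negative binomial (heavy zero
mass, long right tail), rare very-large outlier outlets, and the
stock-flow bookkeeping the retail-audit estimator presumes, which holds
exactly in the truth ledger:

    stock_sls2 = stock_sls1 + delivered - disposed - true_sales   (>= 0)

Measurement error is layered on separately: recall (RC) gets additive,
multiplicative and volume-dependent bias plus noise, truncated at zero
(providers cannot recall negative sales) and optionally heaped to whole
units; stocks are physically counted or stated from memory with distinct
noise scales; item nonresponse (refused / not remembered / missing) is
injected at configurable per-stratum rates.  A single master seed feeds
named substreams so individual error channels can be toggled without
perturbing the draws of the others (common random numbers).

The truth ledger is test-only and is never read by the analysis path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .products import Category, Form, ProductSpec, QuantityObservation
from .audit import SurveyRecord

__all__ = [
    "SalesDist",
    "MarketConfig",
    "MeasurementConfig",
    "make_catalogue",
    "simulate_truth",
    "apply_measurement",
    "generate_survey",
    "NOISE_FREE",
]

LEVELS = ("wholesale", "retail")

# Catalogue templates: (drug_name, strength_mg, form, pack_size, units_per_aetd).
# units_per_aetd values are illustrative adult-course sizes for the synthetic
# market, not an authoritative dosing reference.
_AM_TEMPLATES = [
    ("artesunate-mefloquine", 50.0, Form.TABLET, 12, 12.0),
    ("chloroquine", 150.0, Form.TABLET, 10, 10.0),
    ("quinine", 300.0, Form.TABLET, 30, 21.0),
    ("dihydroartemisinin-piperaquine", 40.0, Form.TABLET, 9, 9.0),
    ("mefloquine", 250.0, Form.TABLET, 8, 8.0),
    ("artemether", 80.0, Form.INJECTABLE, 6, 6.0),
    ("primaquine", 15.0, Form.TABLET, 14, 14.0),
    ("quinine", 300.0, Form.INJECTABLE, 10, 6.0),
]
_RDT_TEMPLATES = [
    ("malaria pf rdt", None, Form.TEST, 25, None),
    ("malaria pf/pv combo rdt", None, Form.TEST, 25, None),
    ("malaria pan rdt", None, Form.TEST, 20, None),
]

_RETAIL_TYPE_MIX = {
    "pharmacy": 0.13, "drug_shop": 0.21, "mobile": 0.20,
    "grocery": 0.26, "village_shop": 0.20,
}
_WHOLESALE_TYPE_MIX = {"other": 1.0}


@dataclass(frozen=True)
class SalesDist:
    """Zero-inflated negative binomial for two-week sales, on the AETD/test scale."""

    pi0: float  # extra zero-inflation probability
    mu: float   # NB mean (AETD for anti-malarials, tests for RDTs)
    k: float    # NB dispersion (smaller = heavier tail)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError(f"pi0 must be in [0,1], got {self.pi0}")
        if self.mu <= 0 or self.k <= 0:
            raise ValueError("mu and k must be > 0")


def _default_sales() -> Dict[Tuple[str, str], SalesDist]:
    # Low-volume market: wholesale medians near zero with a long tail,
    # retail outlet totals mostly 0-20 AETDs.
    return {
        ("wholesale", "antimalarial"): SalesDist(pi0=0.50, mu=8.0, k=0.6),
        ("wholesale", "rdt"): SalesDist(pi0=0.40, mu=8.0, k=0.8),
        ("retail", "antimalarial"): SalesDist(pi0=0.40, mu=2.0, k=0.8),
        ("retail", "rdt"): SalesDist(pi0=0.30, mu=6.0, k=1.0),
    }


@dataclass(frozen=True)
class MarketConfig:
    """The market and stock-flow data-generating process."""

    n_outlets: Dict[str, int] = field(
        default_factory=lambda: {"wholesale": 39, "retail": 66}
    )
    outlet_type_mix: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {"wholesale": dict(_WHOLESALE_TYPE_MIX),
                                 "retail": dict(_RETAIL_TYPE_MIX)}
    )
    n_products_antimalarial: int = 8
    n_products_rdt: int = 3
    # probability an outlet stocks each catalogue product
    stocking_prob: Dict[str, float] = field(
        default_factory=lambda: {"antimalarial": 0.35, "rdt": 0.45}
    )
    sales: Dict[Tuple[str, str], SalesDist] = field(default_factory=_default_sales)
    # deliveries between visits: probability and mean size (AETD/test scale)
    p_delivery: float = 0.25
    delivery_mu: float = 4.0
    # providers essentially never throw products away
    p_disposal: float = 0.01
    disposal_mu: float = 0.5
    # buffer stock beyond what the interval's flows require (AETD/test scale)
    buffer_mu: float = 6.0
    # rare outlets selling an order of magnitude more than the rest
    outlier_prob: float = 0.015
    outlier_multiplier: float = 12.0
    seed: int = 0


#: Measurement layer with every error channel switched off: observed survey
#: records reproduce the truth ledger exactly.
@dataclass(frozen=True)
class MeasurementConfig:
    """Recall and audit error mechanisms, per outlet stratum.

    Recall for true two-week sales t (AETD/test scale) is generated as

        rc = max(0, delta + beta * t * (1 - gamma * t) + eps),   eps ~ N(0, sigma_rc^2)

    then optionally rounded to whole units (heaping).  ``beta < 1`` gives
    uniform under-recall; ``gamma > 0`` makes under-recall grow with volume,
    the mechanism behind proportional bias.  Stocks are physically counted
    with probability ``p_counted`` (relative noise ``sigma_count``),
    otherwise stated from memory (``sigma_stated`` > ``sigma_count``).
    """

    rc_additive_bias: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": -2.0, "retail": 0.0}
    )
    rc_multiplicative_bias: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 1.0, "retail": 1.0}
    )
    rc_volume_dependent_bias: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.0, "retail": 0.01}
    )
    rc_noise: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 2.0, "retail": 1.0}
    )
    rc_heaping: bool = True
    p_not_remembered: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.17, "retail": 0.028}
    )
    p_refused: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.106, "retail": 0.0}
    )
    # whole-record item missingness (all five fields), seen at retail only
    p_record_missing: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.0, "retail": 0.07}
    )
    p_counted: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.51, "retail": 0.97}
    )
    sigma_count: float = 0.02   # relative SD of counted stocks
    sigma_stated: float = 0.15  # relative SD of stated stocks
    p_stock_refused: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.077, "retail": 0.014}
    )
    p_received_refused: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.010, "retail": 0.0}
    )
    p_disposed_refused: Dict[str, float] = field(
        default_factory=lambda: {"wholesale": 0.029, "retail": 0.0}
    )
    sigma_flow: float = 0.0  # relative recall noise on delivered/disposed
    # retail tablets occasionally live in opened tins measured by ruler
    p_tin: float = 0.05
    tin_units_full: int = 100


def _zeroed(d: Dict[str, float]) -> Dict[str, float]:
    return {k: 0.0 for k in d}


def noise_free_measurement() -> MeasurementConfig:
    """Measurement layer with every bias, noise and nonresponse channel off."""
    base = MeasurementConfig()
    return MeasurementConfig(
        rc_additive_bias=_zeroed(base.rc_additive_bias),
        rc_multiplicative_bias={k: 1.0 for k in base.rc_multiplicative_bias},
        rc_volume_dependent_bias=_zeroed(base.rc_volume_dependent_bias),
        rc_noise=_zeroed(base.rc_noise),
        rc_heaping=False,
        p_not_remembered=_zeroed(base.p_not_remembered),
        p_refused=_zeroed(base.p_refused),
        p_record_missing=_zeroed(base.p_record_missing),
        p_counted={k: 1.0 for k in base.p_counted},
        sigma_count=0.0,
        sigma_stated=0.0,
        p_stock_refused=_zeroed(base.p_stock_refused),
        p_received_refused=_zeroed(base.p_received_refused),
        p_disposed_refused=_zeroed(base.p_disposed_refused),
        sigma_flow=0.0,
        p_tin=0.0,
    )


NOISE_FREE = noise_free_measurement()


def _streams(seed: int, names: Sequence[str]) -> Dict[str, np.random.Generator]:
    """Independent named substreams derived from one master seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


_STREAM_NAMES = (
    "market", "sales", "flows", "outlier",
    "rc_noise", "rc_status", "stock_noise", "stock_status", "flow_status", "tin",
)


def make_catalogue(market: MarketConfig) -> List[ProductSpec]:
    """Fixed product catalogue: anti-malarials (AM01..) and RDTs (RDT01..)."""
    specs: List[ProductSpec] = []
    for i in range(market.n_products_antimalarial):
        name, strength, form, pack, upa = _AM_TEMPLATES[i % len(_AM_TEMPLATES)]
        specs.append(ProductSpec(
            product_id=f"AM{i + 1:02d}", category=Category.ANTIMALARIAL,
            drug_name=name, form=form, pack_size=pack,
            strength_mg=strength, units_per_aetd=upa,
        ))
    for i in range(market.n_products_rdt):
        name, strength, form, pack, upa = _RDT_TEMPLATES[i % len(_RDT_TEMPLATES)]
        specs.append(ProductSpec(
            product_id=f"RDT{i + 1:02d}", category=Category.RDT,
            drug_name=name, form=form, pack_size=pack,
            strength_mg=strength, units_per_aetd=upa,
        ))
    return specs


def _units_per_volume(spec: ProductSpec) -> float:
    """Base units per AETD (anti-malarials) or per test (RDTs)."""
    return 1.0 if spec.category == Category.RDT else float(spec.units_per_aetd)


def _draw_zinb(rng: np.random.Generator, dist: SalesDist, size: int) -> np.ndarray:
    zeros = rng.random(size) < dist.pi0
    p = dist.k / (dist.k + dist.mu)
    draws = rng.negative_binomial(dist.k, p, size=size)
    return np.where(zeros, 0, draws)


def simulate_truth(
    market: MarketConfig, catalogue: Optional[List[ProductSpec]] = None
) -> pd.DataFrame:
    """Generate the ground-truth stock-flow ledger.

    One row per outlet x stocked product with integer unit counts
    ``stock1_units, delivered_units, disposed_units, sales_units,
    stock2_units`` obeying the conservation identity exactly, plus outlet
    metadata.  Nonnegativity of closing stock is guaranteed by construction:
    opening stock is set to cover the interval's net outflow plus a random
    buffer.
    """
    catalogue = catalogue if catalogue is not None else make_catalogue(market)
    rng = _streams(market.seed, _STREAM_NAMES)
    r_market, r_sales, r_flows, r_out = (
        rng["market"], rng["sales"], rng["flows"], rng["outlier"]
    )

    rows = []
    for level in LEVELS:
        n = market.n_outlets.get(level, 0)
        types, probs = zip(*market.outlet_type_mix[level].items())
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        for j in range(n):
            outlet_id = f"{'W' if level == 'wholesale' else 'R'}{j + 1:03d}"
            outlet_type = str(r_market.choice(types, p=probs))
            is_outlier = (level == "retail") and (r_out.random() < market.outlier_prob)
            stocked = []
            for spec in catalogue:
                if r_market.random() < market.stocking_prob[spec.category.value]:
                    stocked.append(spec)
            if not any(s.category == Category.ANTIMALARIAL for s in stocked):
                ams = [s for s in catalogue if s.category == Category.ANTIMALARIAL]
                if ams:
                    stocked.append(ams[int(r_market.integers(len(ams)))])
            for spec in stocked:
                upv = _units_per_volume(spec)
                dist = market.sales[(level, spec.category.value)]
                if is_outlier and spec.category == Category.ANTIMALARIAL:
                    # outlier outlets are unusually big sellers: no zero mass,
                    # mean scaled up by the outlier multiplier
                    big = SalesDist(pi0=0.0, mu=dist.mu * market.outlier_multiplier,
                                    k=dist.k)
                    sales_vol = float(_draw_zinb(r_sales, big, 1)[0])
                else:
                    sales_vol = float(_draw_zinb(r_sales, dist, 1)[0])
                sales_units = int(round(sales_vol * upv))

                delivered_units = 0
                if r_flows.random() < market.p_delivery:
                    delivered_units = int(round(
                        r_flows.exponential(market.delivery_mu) * upv))
                disposed_units = 0
                if r_flows.random() < market.p_disposal:
                    disposed_units = int(round(
                        r_flows.exponential(market.disposal_mu) * upv))

                buffer_units = int(round(r_flows.exponential(market.buffer_mu) * upv))
                stock1 = max(0, sales_units + disposed_units - delivered_units) + buffer_units
                stock2 = stock1 + delivered_units - disposed_units - sales_units
                assert stock2 >= 0

                rows.append({
                    "outlet_id": outlet_id, "outlet_level": level,
                    "outlet_type": outlet_type, "product_id": spec.product_id,
                    "category": spec.category.value,
                    "stock1_units": stock1, "delivered_units": delivered_units,
                    "disposed_units": disposed_units, "sales_units": sales_units,
                    "stock2_units": stock2,
                    "is_outlier_outlet": is_outlier,
                })
    return pd.DataFrame(rows)


def _measure_stock(
    units: int, counted: bool, meas: MeasurementConfig, z: float
) -> int:
    sigma = meas.sigma_count if counted else meas.sigma_stated
    return max(0, int(round(units * (1.0 + sigma * z))))


def _decompose(
    units: int, spec: ProductSpec, counted: bool,
    use_tin: bool, tin_units_full: int,
) -> QuantityObservation:
    packs, loose = divmod(int(units), spec.pack_size)
    flag = "counted" if counted else "stated"
    if use_tin and 0 < loose <= tin_units_full and spec.form == Form.TABLET:
        height_full = 10.0
        height = loose / tin_units_full * height_full
        return QuantityObservation(
            full_packs=packs, loose_units=0,
            tin_height_measured=height, tin_height_full=height_full,
            tin_units_full=tin_units_full, counted_flag=flag,
        )
    return QuantityObservation(full_packs=packs, loose_units=loose, counted_flag=flag)


def apply_measurement(
    truth: pd.DataFrame,
    meas: MeasurementConfig,
    catalogue: List[ProductSpec],
    seed: int,
) -> Tuple[List[SurveyRecord], pd.DataFrame]:
    """Overlay recall bias, counting error and nonresponse on a truth ledger.

    Returns the observed :class:`SurveyRecord` list plus a log aligned with
    the truth rows (observed values, injected statuses, counted flags) for
    oracle tests.  Stream separation: toggling one error channel leaves the
    draws of the others unchanged.
    """
    specs = {s.product_id: s for s in catalogue}
    rng = _streams(seed, _STREAM_NAMES)
    n = len(truth)
    z_stock1 = rng["stock_noise"].standard_normal(n)
    z_stock2 = rng["stock_noise"].standard_normal(n)
    u_counted = rng["stock_noise"].random(n)
    z_rc = rng["rc_noise"].standard_normal(n)
    u_rc_status = rng["rc_status"].random(n)
    u_record_missing = rng["rc_status"].random(n)
    u_stock_refused = rng["stock_status"].random(n)
    which_visit = rng["stock_status"].integers(0, 2, size=n)
    u_recv = rng["flow_status"].random(n)
    u_disp = rng["flow_status"].random(n)
    z_recv = rng["flow_status"].standard_normal(n)
    z_disp = rng["flow_status"].standard_normal(n)
    u_tin1 = rng["tin"].random(n)
    u_tin2 = rng["tin"].random(n)

    records: List[SurveyRecord] = []
    log_rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        spec = specs[row.product_id]
        level = row.outlet_level
        upv = _units_per_volume(spec)
        true_vol = row.sales_units / upv

        record_missing = u_record_missing[i] < meas.p_record_missing[level]

        # --- recall channel ---
        if record_missing:
            rc_field: object = "missing"
        else:
            p_nr = meas.p_not_remembered[level]
            p_rf = meas.p_refused[level]
            if u_rc_status[i] < p_nr:
                rc_field = "not_remembered"
            elif u_rc_status[i] < p_nr + p_rf:
                rc_field = "refused"
            else:
                delta = meas.rc_additive_bias[level]
                beta = meas.rc_multiplicative_bias[level]
                gamma = meas.rc_volume_dependent_bias[level]
                sigma = meas.rc_noise[level]
                rc_vol = delta + beta * true_vol * (1.0 - gamma * true_vol) \
                    + sigma * z_rc[i]
                rc_units = max(0.0, rc_vol * upv)
                if meas.rc_heaping:
                    rc_units = float(round(rc_units))
                rc_field = rc_units

        # --- stock channel ---
        counted = u_counted[i] < meas.p_counted[level]
        stock_refused = u_stock_refused[i] < meas.p_stock_refused[level]
        stock_fields: List[object] = []
        for visit, (true_units, z, u_tin) in enumerate((
            (row.stock1_units, z_stock1[i], u_tin1[i]),
            (row.stock2_units, z_stock2[i], u_tin2[i]),
        )):
            if record_missing:
                stock_fields.append("missing")
            elif stock_refused and which_visit[i] == visit:
                stock_fields.append("refused")
            else:
                measured = _measure_stock(true_units, counted, meas, z)
                use_tin = (level == "retail") and counted and (u_tin < meas.p_tin)
                stock_fields.append(
                    _decompose(measured, spec, counted, use_tin, meas.tin_units_full)
                )

        # --- delivered / disposed recall ---
        def flow_field(true_units: int, u: float, p_ref: float, z: float) -> object:
            if record_missing:
                return "missing"
            if u < p_ref:
                return "refused"
            return max(0, int(round(true_units * (1.0 + meas.sigma_flow * z))))

        delivered = flow_field(row.delivered_units, u_recv[i],
                               meas.p_received_refused[level], z_recv[i])
        disposed = flow_field(row.disposed_units, u_disp[i],
                              meas.p_disposed_refused[level], z_disp[i])

        records.append(SurveyRecord(
            outlet_id=row.outlet_id, outlet_level=level,
            outlet_type=row.outlet_type, product_id=row.product_id,
            stock_sls1=stock_fields[0], stock_sls2=stock_fields[1],
            delivered=delivered, disposed=disposed, rc_sold=rc_field,
        ))
        log_rows.append({
            "outlet_id": row.outlet_id, "product_id": row.product_id,
            "true_sales_units": row.sales_units,
            "rc_status": rc_field if isinstance(rc_field, str) else "ok",
            "rc_units": rc_field if not isinstance(rc_field, str) else np.nan,
            "counted": counted,
            "record_missing": record_missing,
        })
    return records, pd.DataFrame(log_rows)


def _config_hash(market: MarketConfig, meas: MeasurementConfig) -> str:
    def encode(obj):
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        return obj
    payload = json.dumps(
        {"market": encode(asdict(market)), "measurement": encode(asdict(meas))},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_survey(
    market: MarketConfig,
    meas: MeasurementConfig,
    out_dir: str,
) -> dict:
    """Write products.csv, survey.csv and truth.csv; return a manifest.

    truth.csv is test-only ground truth and is never read by the analysis
    path.  Two runs with the same configs produce identical files.
    """
    from . import io as slsio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalogue = make_catalogue(market)
    truth = simulate_truth(market, catalogue)
    records, _log = apply_measurement(truth, meas, catalogue, seed=market.seed + 1)

    slsio.write_products_csv(catalogue, out / "products.csv")
    slsio.write_survey_csv(records, out / "survey.csv")
    truth.to_csv(out / "truth.csv", index=False)

    manifest = {
        "seed": market.seed,
        "config_hash": _config_hash(market, meas),
        "n_records": len(records),
        "n_products": len(catalogue),
        "files": ["products.csv", "survey.csv", "truth.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
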