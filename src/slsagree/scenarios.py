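"""Reference simulation scenarios for validating the pipeline.

Each scenario fixes a (market, measurement) configuration pair in which the
quantity of interest has a known closed form, so pipeline output can be
checked against truth:

* ``additive_bias_scenario`` — recall under-reports every outlet's sales by
  a constant ``delta`` with Gaussian noise ``sigma``; everything else is
  exact.  One anti-malarial product per outlet and a large mean volume keep
  the zero-truncation of recall negligible, so the per-outlet difference is
  d = delta - eps and the Bland-Altman bias estimates delta with nominal CI
  coverage.

* ``proportional_bias_scenario`` — recall attenuation grows with the true
  volume (gamma > 0), the mechanism that makes the difference correlate
  positively with the pair mean at retail outlets.

* ``constant_bias_scenario`` — the comparator: a fixed additive
  under-recall at volumes large enough that truncation never binds, so the
  difference is independent of volume and the correlation is null.
"""

from __future__ import annotations

from typing import Tuple

from .synthetic import MarketConfig, MeasurementConfig, SalesDist, noise_free_measurement

__all__ = [
    "additive_bias_scenario",
    "proportional_bias_scenario",
    "constant_bias_scenario",
    "run_scenario",
]


def run_scenario(market: MarketConfig, meas: MeasurementConfig):
    """Run one scenario end to end; returns the retail anti-malarial result."""
    from .reporting import analyze_survey
    from .synthetic import apply_measurement, make_catalogue, simulate_truth

    catalogue = make_catalogue(market)
    truth = simulate_truth(market, catalogue)
    records, _ = apply_measurement(truth, meas, catalogue, seed=market.seed + 1)
    run = analyze_survey(records, {c.product_id: c for c in catalogue},
                         screen_outliers=False)
    return run.strata[("retail", "antimalarial")].results["all"]

_LEVEL = "retail"


def _single_product_market(
    seed: int, n_outlets: int, dist: SalesDist
) -> MarketConfig:
    return MarketConfig(
        n_outlets={"wholesale": 0, "retail": n_outlets},
        n_products_antimalarial=1,
        n_products_rdt=0,
        stocking_prob={"antimalarial": 1.0, "rdt": 0.0},
        sales={
            ("retail", "antimalarial"): dist,
            ("retail", "rdt"): SalesDist(pi0=0.0, mu=1.0, k=1.0),
            ("wholesale", "antimalarial"): dist,
            ("wholesale", "rdt"): SalesDist(pi0=0.0, mu=1.0, k=1.0),
        },
        outlier_prob=0.0,
        seed=seed,
    )


def _exact_measurement(**overrides) -> MeasurementConfig:
    base = noise_free_measurement()
    fields = {
        "rc_additive_bias": dict(base.rc_additive_bias),
        "rc_multiplicative_bias": dict(base.rc_multiplicative_bias),
        "rc_volume_dependent_bias": dict(base.rc_volume_dependent_bias),
        "rc_noise": dict(base.rc_noise),
    }
    for name, value in overrides.items():
        fields[name][_LEVEL] = value
    return MeasurementConfig(
        rc_heaping=False,
        p_not_remembered=base.p_not_remembered,
        p_refused=base.p_refused,
        p_record_missing=base.p_record_missing,
        p_counted=base.p_counted,
        sigma_count=0.0,
        sigma_stated=0.0,
        p_stock_refused=base.p_stock_refused,
        p_received_refused=base.p_received_refused,
        p_disposed_refused=base.p_disposed_refused,
        sigma_flow=0.0,
        p_tin=0.0,
        **fields,
    )


def additive_bias_scenario(
    seed: int, n_outlets: int = 100, delta: float = 4.0, sigma: float = 9.7
) -> Tuple[MarketConfig, MeasurementConfig]:
    """Pure additive recall bias: E[RA - RC] = delta, SD(d) = sigma.

    Mean sales are large (mu=100 AETD, k=30) relative to ``delta + 3*sigma``
    so the max(0, .) truncation of recall essentially never binds and the
    additive-bias model is well specified.
    """
    market = _single_product_market(
        seed, n_outlets, SalesDist(pi0=0.0, mu=100.0, k=30.0)
    )
    meas = _exact_measurement(rc_additive_bias=-delta, rc_noise=sigma)
    return market, meas


def proportional_bias_scenario(
    seed: int, n_outlets: int = 60, gamma: float = 0.03, sigma: float = 1.0
) -> Tuple[MarketConfig, MeasurementConfig]:
    """Volume-dependent under-recall: d grows with volume, so corr(d, m) > 0."""
    market = _single_product_market(
        seed, n_outlets, SalesDist(pi0=0.2, mu=6.0, k=1.5)
    )
    meas = _exact_measurement(rc_volume_dependent_bias=gamma, rc_noise=sigma)
    return market, meas


def constant_bias_scenario(
    seed: int, n_outlets: int = 60, delta: float = 2.0, sigma: float = 1.5
) -> Tuple[MarketConfig, MeasurementConfig]:
    """Constant under-recall at volumes where truncation never binds: corr(d, m) ~ 0."""
    market = _single_product_market(
        seed, n_outlets, SalesDist(pi0=0.0, mu=20.0, k=5.0)
    )
    meas = _exact_measurement(rc_additive_bias=-delta, rc_noise=sigma)
    return market, meas
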