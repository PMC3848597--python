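"""YAML/JSON configuration mirroring the generator dataclasses.

Layout::

    seed: 7
    market:
      n_outlets: {wholesale: 39, retail: 66}
      sales:
        wholesale: {antimalarial: {pi0: 0.5, mu: 8.0, k: 0.6}, ...}
      ...
    measurement:
      rc_multiplicative_bias: {wholesale: 0.8, retail: 1.0}
      ...

Any omitted key keeps its documented default.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .synthetic import MarketConfig, MeasurementConfig, SalesDist

__all__ = ["load_config", "market_from_dict", "measurement_from_dict"]


def _sales_from_dict(raw: dict) -> dict:
    out = {}
    for level, cats in raw.items():
        for cat, params in cats.items():
            out[(level, cat)] = SalesDist(**params)
    return out


def market_from_dict(raw: dict, seed: Optional[int] = None) -> MarketConfig:
    raw = dict(raw or {})
    if "sales" in raw:
        raw["sales"] = {**MarketConfig().sales, **_sales_from_dict(raw["sales"])}
    if seed is not None:
        raw["seed"] = seed
    known = {f.name for f in fields(MarketConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown market config keys: {sorted(unknown)}")
    base = MarketConfig()
    merged = {}
    for name in ("n_outlets", "outlet_type_mix", "stocking_prob"):
        if name in raw:
            merged[name] = {**getattr(base, name), **raw.pop(name)}
    return replace(base, **merged, **raw)


def measurement_from_dict(raw: dict) -> MeasurementConfig:
    raw = dict(raw or {})
    known = {f.name for f in fields(MeasurementConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown measurement config keys: {sorted(unknown)}")
    base = MeasurementConfig()
    merged = {}
    for name in list(raw):
        current = getattr(base, name)
        if isinstance(current, dict):
            merged[name] = {**current, **raw.pop(name)}
    return replace(base, **merged, **raw)


def load_config(
    path: Optional[Union[str, Path]], seed: Optional[int] = None
) -> Tuple[MarketConfig, MeasurementConfig]:
    """Load generator configs from YAML/JSON; missing file section = defaults."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is None:
        seed = raw.get("seed")
    market = market_from_dict(raw.get("market", {}), seed=seed)
    meas = measurement_from_dict(raw.get("measurement", {}))
    return market, meas
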