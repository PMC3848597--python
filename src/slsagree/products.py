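"""Product metadata and standardization of raw counts into analysis volumes.

Anti-malarial quantities are expressed in adult equivalent treatment doses
(AETDs): one AETD is the amount of drug making up a full adult treatment
course.  Rapid diagnostic tests (RDTs) are counted in single test units and
are never AETD-converted.  Anti-malarial products for which the units-per-AETD
conversion cannot be established (e.g. unknown strength) are flagged
*aetd-incomputable* and must be excluded from volume estimation by callers;
the structured :class:`AetdIncomputableError` carries what the exclusion log
needs.

Raw stock observations arrive through three channels: full packs, loose
units, and partially full tins whose content is estimated from the height of
the tablets relative to a full tin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

__all__ = [
    "Category",
    "Form",
    "ProductSpec",
    "QuantityObservation",
    "AetdIncomputableError",
    "estimate_tin_units",
    "total_units",
    "to_aetd",
    "resolve_units_per_aetd",
]


class Category(str, Enum):
    ANTIMALARIAL = "antimalarial"
    RDT = "rdt"


class Form(str, Enum):
    TABLET = "tablet"
    INJECTABLE = "injectable"
    TEST = "test"


class AetdIncomputableError(Exception):
    """Raised when an anti-malarial volume cannot be expressed in AETDs.

    Carries ``product_id`` and ``reason`` so callers can log the exclusion
    and drop the observation from the analysis.
    """

    def __init__(self, product_id: str, reason: str = "aetd_incomputable"):
        self.product_id = product_id
        self.reason = reason
        super().__init__(f"product {product_id!r}: {reason}")


@dataclass(frozen=True)
class ProductSpec:
    """Identity of a surveyed product plus its AETD conversion data.

    ``units_per_aetd`` is the number of base units (tablets, ampoules)
    constituting one adult course.  It is ignored for RDTs.  For
    anti-malarials a missing value flags the product as aetd-incomputable.
    """

    product_id: str
    category: Category
    drug_name: str
    form: Form
    pack_size: int
    strength_mg: Optional[float] = None
    units_per_aetd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pack_size < 1 or int(self.pack_size) != self.pack_size:
            raise ValueError(f"pack_size must be an integer >= 1, got {self.pack_size}")
        if self.units_per_aetd is not None and self.units_per_aetd <= 0:
            raise ValueError(f"units_per_aetd must be positive, got {self.units_per_aetd}")

    @property
    def aetd_incomputable(self) -> bool:
        return self.category == Category.ANTIMALARIAL and self.units_per_aetd is None


@dataclass(frozen=True)
class QuantityObservation:
    """One raw stock observation: packs + loose units + optional tin estimate.

    The three tin fields must be all present or all absent.  ``counted_flag``
    records whether the inventory was physically counted by fieldworkers or
    stated from memory by the provider (distinct error channels).
    """

    full_packs: float = 0
    loose_units: float = 0
    tin_height_measured: Optional[float] = None
    tin_height_full: Optional[float] = None
    tin_units_full: Optional[int] = None
    counted_flag: str = "counted"  # "counted" | "stated"

    def __post_init__(self) -> None:
        if self.full_packs < 0:
            raise ValueError(f"full_packs must be >= 0, got {self.full_packs}")
        if self.loose_units < 0:
            raise ValueError(f"loose_units must be >= 0, got {self.loose_units}")
        tin = (self.tin_height_measured, self.tin_height_full, self.tin_units_full)
        present = [v is not None for v in tin]
        if any(present) and not all(present):
            raise ValueError("tin fields must be all present or all absent")
        if all(present):
            # validation delegated so error messages name the offending field
            _validate_tin(self.tin_height_measured, self.tin_height_full, self.tin_units_full)
        if self.counted_flag not in ("counted", "stated"):
            raise ValueError(f"counted_flag must be 'counted' or 'stated', got {self.counted_flag!r}")

    @property
    def has_tin(self) -> bool:
        return self.tin_height_measured is not None


def _validate_tin(height_measured: float, height_full: float, units_full: int) -> None:
    if height_full <= 0:
        raise ValueError(f"tin_height_full must be > 0, got {height_full}")
    if height_measured < 0:
        raise ValueError(f"tin_height_measured must be >= 0, got {height_measured}")
    if height_measured > height_full:
        raise ValueError(
            f"tin_height_measured ({height_measured}) exceeds tin_height_full ({height_full})"
        )
    if units_full < 1:
        raise ValueError(f"tin_units_full must be >= 1, got {units_full}")


def estimate_tin_units(height_measured: float, height_full: float, units_full: int) -> int:
    """Estimate the units in a partially full tin from tablet-column height.

    The fill fraction ``height_measured / height_full`` is scaled by the
    capacity of a full tin and rounded half-up to an integer count (physical
    tablets are whole).  The result is clamped to ``[0, units_full]`` only by
    the input constraints, never by clipping.

    >>> estimate_tin_units(2.5, 5.0, 100)
    50
    """
    _validate_tin(height_measured, height_full, units_full)
    raw = (height_measured / height_full) * units_full
    return int(math.floor(raw + 0.5))


def total_units(obs: QuantityObservation, spec: ProductSpec) -> float:
    """Total base units in an observation: packs*pack_size + loose + tin estimate."""
    units = obs.full_packs * spec.pack_size + obs.loose_units
    if obs.has_tin:
        units += estimate_tin_units(
            obs.tin_height_measured, obs.tin_height_full, obs.tin_units_full
        )
    return units


def to_aetd(units: float, spec: ProductSpec) -> float:
    """Convert a base-unit count into the analysis volume.

    Anti-malarials: ``units / units_per_aetd`` (real-valued; sold quantities
    may be fractions of a course).  RDTs: unchanged, in test units.

    Raises
    ------
    AetdIncomputableError
        If the product is an anti-malarial without conversion data.  The
        caller logs the exclusion; the observation leaves the analysis.
    """
    if spec.category == Category.RDT:
        return float(units)
    if spec.aetd_incomputable:
        raise AetdIncomputableError(spec.product_id)
    return float(units) / spec.units_per_aetd


def resolve_units_per_aetd(
    spec: ProductSpec,
    lookup: Optional[Mapping[tuple, float]] = None,
) -> ProductSpec:
    """Fill ``units_per_aetd`` from a user-supplied lookup table.

    The table is keyed by ``(drug_name, strength_mg, form)``; an explicit
    per-product value on the spec always wins.  Dosing conversions come from
    user configuration (WHO guidelines or literature), never from data
    embedded in this package.
    """
    if spec.units_per_aetd is not None or lookup is None:
        return spec
    key = (spec.drug_name, spec.strength_mg, spec.form.value)
    if key in lookup:
        return ProductSpec(
            product_id=spec.product_id,
            category=spec.category,
            drug_name=spec.drug_name,
            form=spec.form,
            pack_size=spec.pack_size,
            strength_mg=spec.strength_mg,
            units_per_aetd=float(lookup[key]),
        )
    return spec
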