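"""Pipeline orchestration and report rendering.

Runs the full analysis sequence — standardize to AETD/tests, compute and
screen RA estimates, pair with RC, aggregate to outlet totals, screen
outliers, Bland-Altman per stratum — and renders the response-accounting
table (counts with one-decimal percentages) in the survey-report layout.
Strata (outlet level x product category) are always analyzed separately and
never pooled.  When the outlier screen flags anything, both the
with-outliers and the main (outliers-excluded) variants are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .agreement import (
    AgreementResult,
    DifferencePair,
    analyze_agreement,
    make_differences,
    outlier_screen,
)
from .audit import (
    ExclusionRecord,
    PairedEstimate,
    ProductPair,
    ResponseAccounting,
    StratumAccounting,
    SurveyRecord,
    aggregate_outlets,
    build_pairs,
    response_accounting,
)
from .products import Category, ProductSpec

__all__ = ["RunManifest", "StratumResult", "AnalysisRun", "analyze_survey", "render_table1"]

logger = logging.getLogger("slsagree")

STRATA = [
    ("wholesale", "antimalarial"), ("wholesale", "rdt"),
    ("retail", "antimalarial"), ("retail", "rdt"),
]


@dataclass
class RunManifest:
    """Bookkeeping for one analysis run; counts must reconcile exactly."""

    n_records_read: int
    n_records_analyzed: int
    n_records_excluded: int
    exclusions_by_reason: Dict[str, int]
    seed: Optional[int] = None
    config: Optional[dict] = None

    def reconciles(self) -> bool:
        return (
            self.n_records_read == self.n_records_analyzed + self.n_records_excluded
            and sum(self.exclusions_by_reason.values()) == self.n_records_excluded
        )


@dataclass
class StratumResult:
    outlet_level: str
    category: str
    unit: str  # "AETD" | "tests"
    estimates: List[PairedEstimate]
    flagged_outliers: List[PairedEstimate]
    # variant name -> result; "all" always present (when analyzable),
    # "main" added when outliers were flagged and excluded
    results: Dict[str, AgreementResult] = field(default_factory=dict)
    diffs: Dict[str, List[DifferencePair]] = field(default_factory=dict)
    skipped_reason: Optional[str] = None


@dataclass
class AnalysisRun:
    pairs: List[ProductPair]
    exclusions: List[ExclusionRecord]
    accounting: ResponseAccounting
    strata: Dict[Tuple[str, str], StratumResult]
    manifest: RunManifest

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for (level, cat), sr in sorted(self.strata.items()):
            for variant, res in sr.results.items():
                row = {"outlet_level": level, "category": cat,
                       "variant": variant, "unit": sr.unit}
                row.update(res.to_dict())
                row["excluded_outliers"] = ";".join(res.excluded_outliers)
                rows.append(row)
        return pd.DataFrame(rows)


def analyze_survey(
    records: Sequence[SurveyRecord],
    specs: Mapping[str, ProductSpec],
    outlier_k: float = 3.0,
    screen_outliers: bool = True,
    ci_level: float = 0.95,
    seed: Optional[int] = None,
) -> AnalysisRun:
    """Run the full method-comparison pipeline on survey records."""
    pairs, exclusions = build_pairs(records, specs)
    accounting = response_accounting(records, pairs, specs)
    estimates = aggregate_outlets(pairs)

    by_reason: Dict[str, int] = {}
    for e in exclusions:
        by_reason[e.reason] = by_reason.get(e.reason, 0) + 1
    for reason, count in sorted(by_reason.items()):
        logger.warning("excluded %d record(s): %s", count, reason)
    n_analyzed = sum(1 for p in pairs if p.included)
    manifest = RunManifest(
        n_records_read=len(records),
        n_records_analyzed=n_analyzed,
        n_records_excluded=len(exclusions),
        exclusions_by_reason=by_reason,
        seed=seed,
    )
    assert manifest.reconciles()

    strata: Dict[Tuple[str, str], StratumResult] = {}
    for level, cat in STRATA:
        members = [e for e in estimates
                   if e.outlet_level == level and e.category.value == cat]
        if not members:
            continue
        unit = "AETD" if cat == "antimalarial" else "tests"
        sr = StratumResult(outlet_level=level, category=cat, unit=unit,
                           estimates=members, flagged_outliers=[])
        if len(members) < 2:
            sr.skipped_reason = f"only {len(members)} paired outlet(s); need >= 2"
            logger.warning("stratum %s/%s skipped: %s", level, cat, sr.skipped_reason)
            strata[(level, cat)] = sr
            continue
        if screen_outliers:
            kept, flagged = outlier_screen(members, k=outlier_k)
        else:
            kept, flagged = list(members), []
        sr.flagged_outliers = flagged
        sr.results["all"] = analyze_agreement(members, ci_level=ci_level)
        sr.diffs["all"] = make_differences(members)
        if flagged and len(kept) >= 2:
            ids = [p.outlet_id for p in flagged]
            logger.warning("stratum %s/%s: outlier outlet(s) flagged: %s",
                           level, cat, ", ".join(ids))
            sr.results["main"] = analyze_agreement(
                kept, ci_level=ci_level, excluded_outliers=ids)
            sr.diffs["main"] = make_differences(kept)
        strata[(level, cat)] = sr

    return AnalysisRun(pairs=pairs, exclusions=exclusions, accounting=accounting,
                       strata=strata, manifest=manifest)


# ---------------------------------------------------------------------------
# Table-1-style rendering
# ---------------------------------------------------------------------------

def format_count_pct(n: int, denom: int) -> str:
    """Render ``n (p%)`` with a one-decimal percentage; dash when n = 0."""
    if n == 0:
        return "-"
    if denom <= 0:
        return str(n)
    return f"{n} ({100.0 * n / denom:.1f}%)"


_TABLE1_ROWS = [
    ("Total products surveyed", lambda s: (s.n_surveyed, s.n_surveyed)),
    ("Recall method (RC)", None),
    ("Sales volume data collected", lambda s: (s.rc.n_collected, s.n_surveyed)),
    ("- Not remembered", lambda s: (s.rc.n_not_remembered, s.n_surveyed)),
    ("- Refused", lambda s: (s.rc.n_refused, s.n_surveyed)),
    ("- Missing", lambda s: (s.rc.n_missing, s.n_surveyed)),
    ("Retail Audit method (RA)", None),
    ("Sales volumes data calculated (excluding negatives)",
     lambda s: (s.n_ra_nonnegative, s.n_surveyed)),
    ("Sales volumes data calculated (including negatives)",
     lambda s: (s.n_ra_including_negative, s.n_surveyed)),
    ("Stock data collected", lambda s: (s.stock.n_collected, s.n_surveyed)),
    ("- Stock refused", lambda s: (s.stock.n_refused, s.n_surveyed)),
    ("- Stock not remembered", lambda s: (s.stock.n_not_remembered, s.n_surveyed)),
    ("- Stock missing", lambda s: (s.stock.n_missing, s.n_surveyed)),
    ("Received quantities collected", lambda s: (s.received.n_collected, s.n_surveyed)),
    ("- Received refused", lambda s: (s.received.n_refused, s.n_surveyed)),
    ("- Received missing", lambda s: (s.received.n_missing, s.n_surveyed)),
    ("Disposed quantities collected", lambda s: (s.disposed.n_collected, s.n_surveyed)),
    ("- Disposed refused", lambda s: (s.disposed.n_refused, s.n_surveyed)),
    ("- Disposed missing", lambda s: (s.disposed.n_missing, s.n_surveyed)),
]

_STRATUM_LABELS = {
    ("wholesale", "antimalarial"): "Wholesale anti-malarials",
    ("wholesale", "rdt"): "Wholesale RDT",
    ("retail", "antimalarial"): "Retail anti-malarials",
    ("retail", "rdt"): "Retail RDT",
}


def render_table1(accounting: ResponseAccounting) -> pd.DataFrame:
    """Response accounting in the survey-report layout.

    One column per outlet-level x category stratum; counts with one-decimal
    percentages of total products surveyed in parentheses; dashes for empty
    cells and dash-filled columns for empty strata.
    """
    columns: Dict[str, List[str]] = {}
    for key, label in _STRATUM_LABELS.items():
        stratum = accounting.strata.get((key[0], key[1]))
        cells = []
        for name, getter in _TABLE1_ROWS:
            if getter is None:
                cells.append("")
            elif stratum is None or stratum.n_surveyed == 0:
                cells.append("-")
            else:
                n, denom = getter(stratum)
                cells.append(format_count_pct(n, denom))
        columns[label] = cells
    index = [name for name, _ in _TABLE1_ROWS]
    return pd.DataFrame(columns, index=index)
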