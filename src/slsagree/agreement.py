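"""Bland-Altman agreement analysis of paired outlet sales totals.

For each outlet the two methods give totals RA_i (retail audit) and RC_i
(recall).  The analysis works on the per-outlet difference d_i = RA_i - RC_i
and, since no gold standard exists, proxies the true volume by the pair mean
m_i = (RA_i + RC_i) / 2.  The bias of measurement is the mean of d, its
spread the sample SD (n-1 denominator), and the 95% limits of agreement are

    LoA = bias +/- 1.96 * SD

with 1.96 used literally.  Confidence intervals use the t distribution with
n-1 df: bias +/- t * SD/sqrt(n) for the bias and each limit +/- t *
SD*sqrt(3/n) (the classical variance approximation 3*SD^2/n) for the LoA.
Proportional bias -- dependence of d on the magnitude measured -- is
detected as the Pearson correlation of d against m with its two-sided
t-based p-value, the statistic the Stata ``baplot`` routine reports.

Degenerate inputs (fewer than two pairs, zero variance) raise or return
explicit structured statuses, never silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .audit import PairedEstimate

__all__ = [
    "DifferencePair",
    "AgreementResult",
    "NormalityDiagnostic",
    "make_differences",
    "bias_sd",
    "limits_of_agreement",
    "bias_ci",
    "loa_ci",
    "proportional_bias",
    "outlier_screen",
    "normality_check",
    "ba_plot",
    "analyze_agreement",
]


@dataclass(frozen=True)
class DifferencePair:
    outlet_id: str
    d: float  # RA - RC
    m: float  # (RA + RC) / 2

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"pair mean must be >= 0, got {self.m}")


@dataclass
class NormalityDiagnostic:
    """Advisory histogram + Shapiro-Wilk summary; never blocks the analysis."""

    status: str  # "ok" | "departure" | "degenerate"
    note: str
    bin_edges: Optional[np.ndarray] = None
    bin_counts: Optional[np.ndarray] = None
    shapiro_stat: Optional[float] = None
    shapiro_p: Optional[float] = None


@dataclass
class AgreementResult:
    n: int
    bias: float
    sd: float
    bias_ci: Tuple[float, float]
    loa: Tuple[float, float]  # (lower, upper)
    loa_ci_lower: Tuple[float, float]
    loa_ci_upper: Tuple[float, float]
    r: Optional[float]
    r_p: Optional[float]
    r_status: str  # "ok" | "degenerate"
    normality: Optional[NormalityDiagnostic] = None
    excluded_outliers: List[str] = field(default_factory=list)
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "bias_ci_lo": self.bias_ci[0],
            "bias_ci_hi": self.bias_ci[1],
            "loa_lower": self.loa[0],
            "loa_upper": self.loa[1],
            "loa_lower_ci_lo": self.loa_ci_lower[0],
            "loa_lower_ci_hi": self.loa_ci_lower[1],
            "loa_upper_ci_lo": self.loa_ci_upper[0],
            "loa_upper_ci_hi": self.loa_ci_upper[1],
            "r": self.r,
            "r_p": self.r_p,
            "r_status": self.r_status,
            "excluded_outliers": list(self.excluded_outliers),
            "ci_level": self.ci_level,
        }


class InsufficientPairsError(ValueError):
    pass


def make_differences(pairs: Sequence[PairedEstimate]) -> List[DifferencePair]:
    """One difference pair (d = RA-RC, m = (RA+RC)/2) per outlet, order-preserving."""
    return [
        DifferencePair(outlet_id=p.outlet_id, d=p.ra_total - p.rc_total,
                       m=(p.ra_total + p.rc_total) / 2.0)
        for p in pairs
    ]


def bias_sd(diffs: Sequence[DifferencePair]) -> Tuple[float, float, int]:
    """Mean of the differences (the bias of measurement) and its sample SD."""
    n = len(diffs)
    if n < 2:
        raise InsufficientPairsError(f"insufficient pairs: need >= 2, got {n}")
    d = np.array([p.d for p in diffs], dtype=float)
    return float(d.mean()), float(d.std(ddof=1)), n


def limits_of_agreement(bias: float, sd: float) -> Tuple[float, float]:
    """95% limits of agreement: bias -/+ 1.96*SD (1.96 literal)."""
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    return bias - 1.96 * sd, bias + 1.96 * sd


def _t_crit(n: int, level: float) -> float:
    return float(stats.t.ppf(0.5 + level / 2.0, df=n - 1))


def bias_ci(bias: float, sd: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """t-based CI for the bias: bias +/- t_{n-1} * SD/sqrt(n)."""
    if n < 2:
        raise InsufficientPairsError(f"insufficient pairs: need >= 2, got {n}")
    half = _t_crit(n, level) * sd / np.sqrt(n)
    return bias - half, bias + half


def loa_ci(
    bias: float, sd: float, n: int, level: float = 0.95
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """CIs for the two limits of agreement, each centred on its limit.

    Uses the classical large-sample variance approximation var(limit) ~=
    3*SD^2/n, i.e. half-width t_{n-1} * SD*sqrt(3/n).
    """
    if n < 2:
        raise InsufficientPairsError(f"insufficient pairs: need >= 2, got {n}")
    lower, upper = limits_of_agreement(bias, sd)
    half = _t_crit(n, level) * sd * np.sqrt(3.0 / n)
    return (lower - half, lower + half), (upper - half, upper + half)


def proportional_bias(diffs: Sequence[DifferencePair]) -> Tuple[Optional[float], Optional[float], str]:
    """Pearson correlation of differences against pair means, with p-value.

    Returns ``(r, p, "ok")`` or ``(None, None, "degenerate")`` when either
    series has zero variance (e.g. constant differences), instead of NaN.
    """
    n = len(diffs)
    if n < 3:
        raise InsufficientPairsError(f"insufficient pairs: need >= 3, got {n}")
    d = np.array([p.d for p in diffs], dtype=float)
    m = np.array([p.m for p in diffs], dtype=float)
    for x in (d, m):
        if np.ptp(x) <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
            return None, None, "degenerate"
    res = stats.pearsonr(d, m)
    return float(res.statistic), float(res.pvalue), "ok"


def outlier_screen(
    pairs: Sequence[PairedEstimate], k: float = 3.0
) -> Tuple[List[PairedEstimate], List[PairedEstimate]]:
    """Flag outlets whose mean volume dwarfs every other outlet's.

    An outlet is flagged when its pair mean m exceeds ``k`` times the
    largest m among the remaining outlets.  ``k = inf`` disables the screen.
    Flagged outlets are reported, and callers run the analysis both with and
    without them (sensitivity rerun).
    """
    if not np.isfinite(k) or len(pairs) < 2:
        return list(pairs), []
    m = np.array([(p.ra_total + p.rc_total) / 2.0 for p in pairs], dtype=float)
    kept, flagged = [], []
    for i, p in enumerate(pairs):
        others_max = np.max(np.delete(m, i))
        if m[i] > k * others_max:
            flagged.append(p)
        else:
            kept.append(p)
    return kept, flagged


def normality_check(
    diffs: Sequence[DifferencePair], alpha: float = 0.05, bins: int = 10
) -> NormalityDiagnostic:
    """Histogram of the differences plus an advisory Shapiro-Wilk test."""
    if len(diffs) < 3:
        return NormalityDiagnostic(status="degenerate", note="fewer than 3 differences")
    d = np.array([p.d for p in diffs], dtype=float)
    # numerically constant (spread below float resolution of the values)
    if np.ptp(d) <= 1e-12 * max(1.0, float(np.max(np.abs(d)))):
        return NormalityDiagnostic(status="degenerate", note="constant differences")
    counts, edges = np.histogram(d, bins=bins)
    stat, p = stats.shapiro(d)
    if p < alpha:
        status, note = "departure", f"departure from normality flagged (Shapiro-Wilk p={p:.3g})"
    else:
        status, note = "ok", f"no departure detected (Shapiro-Wilk p={p:.3g})"
    return NormalityDiagnostic(
        status=status, note=note, bin_edges=edges, bin_counts=counts,
        shapiro_stat=float(stat), shapiro_p=float(p),
    )


def analyze_agreement(
    pairs: Sequence[PairedEstimate],
    ci_level: float = 0.95,
    excluded_outliers: Sequence[str] = (),
) -> AgreementResult:
    """Full Bland-Altman summary for one set of paired outlet totals."""
    diffs = make_differences(pairs)
    bias, sd, n = bias_sd(diffs)
    loa = limits_of_agreement(bias, sd)
    b_ci = bias_ci(bias, sd, n, ci_level)
    l_ci, u_ci = loa_ci(bias, sd, n, ci_level)
    if n >= 3:
        r, r_p, r_status = proportional_bias(diffs)
        norm = normality_check(diffs)
    else:
        r, r_p, r_status, norm = None, None, "degenerate", None
    return AgreementResult(
        n=n, bias=bias, sd=sd, bias_ci=b_ci, loa=loa,
        loa_ci_lower=l_ci, loa_ci_upper=u_ci,
        r=r, r_p=r_p, r_status=r_status, normality=norm,
        excluded_outliers=list(excluded_outliers), ci_level=ci_level,
    )


def ba_plot(
    result: AgreementResult,
    diffs: Sequence[DifferencePair],
    out_path: str,
    unit: str = "AETD",
    title: str = "",
) -> str:
    """Mean-difference (Bland-Altman) plot written to an image file.

    Scatter of d against m, a dashed blue equality line at y=0, a solid red
    line at the bias, and dashed red lines at the limits of agreement.
    """
    if not diffs:
        raise ValueError("cannot plot an empty set of differences")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = [p.m for p in diffs]
    d = [p.d for p in diffs]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(m, d, s=25, color="black", zorder=3)
    ax.axhline(0.0, color="tab:blue", linestyle="--", label="equality")
    ax.axhline(result.bias, color="tab:red", linestyle="-", label="bias")
    ax.axhline(result.loa[0], color="tab:red", linestyle="--", label="limits of agreement")
    ax.axhline(result.loa[1], color="tab:red", linestyle="--")
    ax.set_xlabel(f"Mean of RA and RC estimates ({unit})")
    ax.set_ylabel(f"Difference RA - RC ({unit})")
    if title:
        ax.set_title(title)
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
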