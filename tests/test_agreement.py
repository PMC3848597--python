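"""Bland-Altman statistics: bias, SD, limits of agreement, CIs, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slsagree.agreement import (
    DifferencePair,
    InsufficientPairsError,
    analyze_agreement,
    ba_plot,
    bias_ci,
    bias_sd,
    limits_of_agreement,
    loa_ci,
    make_differences,
    normality_check,
    outlier_screen,
    proportional_bias,
)
from slsagree.audit import PairedEstimate
from slsagree.products import Category


def pe(outlet, ra, rc):
    return PairedEstimate(outlet_id=outlet, category=Category.ANTIMALARIAL,
                          ra_total=ra, rc_total=rc, n_products=1)


def dp(d, m, outlet="O"):
    return DifferencePair(outlet_id=outlet, d=d, m=m)


class TestDifferences:
    @pytest.mark.parametrize("ra,rc,d,m", [(4, 4, 0, 4), (6, 2, 4, 4), (0, 0, 0, 0)])
    def test_examples(self, ra, rc, d, m):
        (diff,) = make_differences([pe("O1", ra, rc)])
        assert (diff.d, diff.m) == (d, m)

    def test_empty_input(self):
        assert make_differences([]) == []


class TestBiasSd:
    def test_constant_differences(self):
        bias, sd, n = bias_sd([dp(2, 5), dp(2, 6), dp(2, 7)])
        assert (bias, sd, n) == (2, 0, 3)

    def test_symmetric_pair(self):
        bias, sd, n = bias_sd([dp(-1, 1), dp(1, 1)])
        assert bias == 0
        assert sd == pytest.approx(np.sqrt(2))

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientPairsError, match="insufficient"):
            bias_sd([dp(1, 1)])

    def test_sampling_distribution_bound(self):
        # 200 draws from N(4, 9.7^2): sample mean within 3 SE of 4
        rng = np.random.default_rng(42)
        d = rng.normal(4, 9.7, 200)
        bias, sd, n = bias_sd([dp(x, abs(x)) for x in d])
        assert abs(bias - 4) < 3 * 9.7 / np.sqrt(200)
        assert sd == pytest.approx(d.std(ddof=1))


class TestLimitsOfAgreement:
    def test_wholesale_antimalarial_pair(self):
        # sd back-derived from bias 4 and upper limit 23: sd = 19/1.96
        sd = (23.0 - 4.0) / 1.96
        lower, upper = limits_of_agreement(4.0, sd)
        assert round(upper, 1) == 23.0
        assert round(lower, 1) == -15.0

    def test_retail_with_outlier_pair(self):
        sd = (16.0 - 2.0) / 1.96
        lower, upper = limits_of_agreement(2.0, sd)
        assert round(lower, 1) == -12.0

    def test_degenerate_zero_sd(self):
        assert limits_of_agreement(0.0, 0.0) == (0.0, 0.0)

    @given(bias=st.floats(-100, 100), sd=st.floats(0, 100))
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_exact(self, bias, sd):
        lower, upper = limits_of_agreement(bias, sd)
        assert upper + lower == pytest.approx(2 * bias, abs=1e-9)
        assert upper >= lower


class TestConfidenceIntervals:
    def test_bias_ci_degenerate(self):
        assert bias_ci(0.0, 0.0, 10) == (0.0, 0.0)

    def test_bias_ci_closed_form(self):
        # t-based closed form at n=34, sd=9.694: half-width t_33 * sd/sqrt(34)
        lo, hi = bias_ci(4.0, 9.694, 34)
        assert (round(lo, 2), round(hi, 2)) == (0.62, 7.38)

    def test_width_shrinks_with_n(self):
        widths = [np.diff(bias_ci(0, 5, n))[0] for n in (10, 40, 160)]
        assert widths[0] > widths[1] > widths[2]
        # ~1/sqrt(n) for fixed sd (t quantile also shrinks slightly)
        assert widths[0] / widths[1] > 2.0

    def test_loa_ci_centred_on_limits(self):
        (llo, lhi), (ulo, uhi) = loa_ci(4.0, 9.694, 34)
        lower, upper = limits_of_agreement(4.0, 9.694)
        assert (llo + lhi) / 2 == pytest.approx(lower)
        assert (ulo + uhi) / 2 == pytest.approx(upper)
        # closed form with the 3*sd^2/n variance approximation
        assert (round(ulo, 1), round(uhi, 1)) == (17.1, 28.9)

    def test_loa_ci_degenerate_sd(self):
        (llo, lhi), (ulo, uhi) = loa_ci(1.0, 0.0, 10)
        assert llo == lhi == ulo == uhi == 1.0


class TestProportionalBias:
    def test_perfect_proportionality(self):
        diffs = [dp(2 * m, m) for m in (1.0, 2.0, 3.0, 4.0)]
        r, p, status = proportional_bias(diffs)
        assert status == "ok"
        assert r == pytest.approx(1.0)

    def test_constant_differences_degenerate(self):
        r, p, status = proportional_bias([dp(2, m) for m in (1.0, 2.0, 3.0)])
        assert (r, p, status) == (None, None, "degenerate")

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientPairsError):
            proportional_bias([dp(1, 1), dp(2, 2)])


class TestOutlierScreen:
    def test_flags_the_dominant_outlet(self):
        pairs = [pe(f"O{i}", m, m) for i, m in enumerate(range(21))]
        pairs.append(pe("BIG", 129, 129))
        kept, flagged = outlier_screen(pairs, k=3)
        assert [p.outlet_id for p in flagged] == ["BIG"]
        assert len(kept) == 21

    def test_all_equal_nothing_flagged(self):
        pairs = [pe(f"O{i}", 5, 5) for i in range(10)]
        kept, flagged = outlier_screen(pairs, k=3)
        assert flagged == []

    def test_infinite_k_disables_rule(self):
        pairs = [pe("O1", 1, 1), pe("O2", 1000, 1000)]
        kept, flagged = outlier_screen(pairs, k=np.inf)
        assert flagged == [] and len(kept) == 2


class TestNormalityCheck:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(7)
        diffs = [dp(x, abs(x)) for x in rng.normal(0, 1, 100)]
        diag = normality_check(diffs)
        assert diag.status == "ok"
        assert diag.bin_counts.sum() == 100

    def test_exponential_sample_flagged(self):
        rng = np.random.default_rng(7)
        diffs = [dp(x, x) for x in rng.exponential(1, 100)]
        assert normality_check(diffs).status == "departure"

    def test_constant_degenerate(self):
        assert normality_check([dp(1, 1)] * 5).status == "degenerate"


class TestInvariants:
    @given(
        ras=st.lists(st.floats(0, 100), min_size=3, max_size=20),
        rcs=st.lists(st.floats(0, 100), min_size=3, max_size=20),
        c=st.floats(0.1, 50),
    )
    @settings(max_examples=50, derandomize=True)
    def test_translation_equivariance(self, ras, rcs, c):
        n = min(len(ras), len(rcs))
        pairs = [pe(f"O{i}", ras[i], rcs[i]) for i in range(n)]
        shifted = [pe(f"O{i}", ras[i] + c, rcs[i]) for i in range(n)]
        r0 = analyze_agreement(pairs)
        r1 = analyze_agreement(shifted)
        assert r1.bias == pytest.approx(r0.bias + c, abs=1e-8)
        assert r1.sd == pytest.approx(r0.sd, abs=1e-8)
        assert r1.loa[0] == pytest.approx(r0.loa[0] + c, abs=1e-8)
        assert r1.loa[1] == pytest.approx(r0.loa[1] + c, abs=1e-8)

    @given(
        vals=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=3, max_size=20, unique_by=lambda t: t,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_method_swap_antisymmetry(self, vals):
        pairs = [pe(f"O{i}", ra, rc) for i, (ra, rc) in enumerate(vals)]
        swapped = [pe(f"O{i}", rc, ra) for i, (ra, rc) in enumerate(vals)]
        r0, r1 = analyze_agreement(pairs), analyze_agreement(swapped)
        assert r1.bias == pytest.approx(-r0.bias, abs=1e-8)
        assert r1.loa[0] == pytest.approx(-r0.loa[1], abs=1e-8)
        assert r1.loa[1] == pytest.approx(-r0.loa[0], abs=1e-8)
        if r0.r_status == "ok" and r1.r_status == "ok":
            assert r1.r == pytest.approx(-r0.r, abs=1e-8)

    def test_empirical_coverage_of_loa(self):
        rng = np.random.default_rng(123)
        d = rng.normal(4, 9.7, 10_000)
        bias, sd, _ = bias_sd([dp(x, abs(x)) for x in d])
        lower, upper = limits_of_agreement(bias, sd)
        frac = np.mean((d >= lower) & (d <= upper))
        assert frac == pytest.approx(0.95, abs=0.01)


class TestPlot:
    def test_plot_written_and_nonempty(self, tmp_path):
        pairs = [pe(f"O{i}", ra, rc) for i, (ra, rc) in
                 enumerate([(4, 4), (6, 2), (1, 3), (5, 5)])]
        res = analyze_agreement(pairs)
        path = tmp_path / "ba.png"
        ba_plot(res, make_differences(pairs), str(path), unit="AETD")
        assert path.exists() and path.stat().st_size > 0

    def test_empty_diffs_error(self):
        res = analyze_agreement([pe("O1", 1, 1), pe("O2", 2, 2)])
        with pytest.raises(ValueError, match="empty"):
            ba_plot(res, [], "/tmp/never.png")
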