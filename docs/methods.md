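# Methods

## The measurement problem

A sales-level survey (SLS) visits each medicine outlet twice, two weeks
apart. At the second visit the provider is asked to recall the quantities
sold in the interval (RC); independently, fieldworkers record quantities
stocked at both visits and quantities received and disposed of in between,
from which the retail-audit estimate follows by stock-flow accounting:

    RA = stock(SLS1) + delivered − disposed − stock(SLS2)

Neither method is a gold standard, so the question is *agreement*, not
accuracy, and the analysis is the classical Bland–Altman comparison of
paired per-outlet totals.

## Standardization

Anti-malarial quantities arrive as full packs, loose tablets, and
partially full tins; tin content is estimated from the height of the
tablet column relative to a full tin, scaled by the capacity of a full
tin, and rounded half-up to an integer tablet count (physical tablets are
whole; the rounding rule is this package's choice). All channels are summed
to base units and divided by the product's units-per-AETD to give volumes
in adult equivalent treatment doses; RDTs stay in single test units.
Units-per-AETD values come from a user-supplied catalogue or lookup table
keyed by (drug, strength, form) — adult-course definitions belong to WHO
guidance and the literature, not to this package, so no dosing database is
embedded. An anti-malarial without conversion data is AETD-incomputable:
it is excluded from volume estimation and logged exactly once.

The stock-flow difference is computed on exact base units and converted to
AETDs afterwards. The conversion is linear, so this is mathematically
identical to converting each component first, but it keeps the arithmetic
exact: dividing each component by units-per-AETD before differencing
leaves floating-point residue that can turn a true zero into a spurious
"negative" estimate.

## Exclusion rules

* Strictly negative RA estimates indicate data-collection error and are
  excluded; zero is a legitimate estimate of no sales. The negative value
  is retained in the exclusion log.
* A nonresponse status (refused / not remembered / missing) in *any* of
  the four stock-flow components voids the whole RA estimate; the formula
  needs all four terms. Component-level nonresponse is still tabulated
  separately in the accounting table.
* A pair enters the agreement analysis only when both RA and RC exist.
* No imputation anywhere; an excluded observation stays excluded.

Every record is accounted for exactly once across {analyzed,
excluded-with-reason}; the run manifest asserts this reconciliation.

## Agreement statistics

With per-outlet totals (summed over the products of one category; drug and
RDT strata are never pooled), the per-outlet difference is d = RA − RC and
the unobservable true volume is proxied by m = (RA + RC)/2. The bias is
the mean of d; spread is the sample SD (n−1). Limits of agreement use
1.96 literally: LoA = bias ± 1.96·SD, so upper + lower = 2·bias holds
exactly.

Confidence intervals: the bias uses the t distribution with n−1 df and
variance SD²/n; each limit uses the classical large-sample approximation
var ≈ 3·SD²/n. These are conventional small-sample choices; published
Bland–Altman reports differ between z- and t-based intervals, so printed
intervals from other analyses are expected to match only approximately.

Proportional bias — dependence of d on the magnitude measured — is tested
as the Pearson correlation of d on m with its two-sided t-based p-value
(the statistic the Stata `baplot` routine reports). A Shapiro–Wilk
statistic plus histogram of d is attached as an advisory normality note;
it never blocks the analysis. Degenerate inputs (n < 2, zero or
numerically-zero variance) raise explicit errors or return structured
"degenerate" statuses, never NaN.

### Outlier screen

Survey totals occasionally contain single outlets selling an order of
magnitude more than every other outlet, which dominates the statistics and
obscures interpretation. Rather than an ad-hoc exclusion, the rule is
explicit and configurable: an outlet is flagged when its pair mean exceeds
`k` times the largest mean among the remaining outlets (default k = 3;
k = ∞ disables). Whenever anything is flagged the analysis is reported
both with and without the flagged outlets.

## Synthetic survey generator

The generator emulates a low-volume anti-malarial/RDT market of the kind
these surveys encounter: two strata (default 39 wholesale, 66 retail
outlets, reflecting realistic participation in a ~67/107 sample), a small
catalogue (8 anti-malarials, 3 RDTs; illustrative pack sizes and
units-per-AETD), and two-week product-level sales drawn from a
zero-inflated negative binomial on the AETD/test scale. Defaults place
retail outlet totals mostly in 0–20 AETDs with a heavy zero mass, and
wholesale medians near zero with a long right tail. A rare outlier
mechanism (probability 0.015 per retail outlet) redraws an outlet's
anti-malarial sales from the non-zero-inflated tail with the mean scaled
×12, producing the ~10× dominant outlets the screen is designed for.

Truth ledger: sales, deliveries (probability 0.25, exponential sizes) and
disposals (probability 0.01 — providers essentially never discard stock)
are drawn first; opening stock is then set to the net outflow plus an
exponential buffer, so closing stock is nonnegative and the conservation
identity holds *exactly* by construction (no rejection sampling needed).
This ledger is the oracle for the RA estimator: with all error channels
off, the pipeline must recover bias = SD = 0 exactly.

Measurement layer, per stratum:

* Recall: `rc = max(0, δ + β·t·(1 − γ·t) + ε)`, ε ~ N(0, σ²), optionally
  heaped to whole units. δ < 0 gives constant under-recall, β < 1
  uniform proportional under-recall, γ > 0 volume-dependent attenuation —
  the mechanism that produces a positive correlation of differences with
  volume. Defaults: wholesale δ = −2 AETD, σ = 2 (wholesalers handle many
  products and under-recall, without a volume trend); retail γ = 0.01,
  σ = 1 (recall degrades with volume). Truncation at zero is deliberate —
  providers cannot recall negative sales — and induces a small upward
  distortion at near-zero volumes, documented below.
* Stocks: physically counted with probability 0.51 (wholesale) / 0.97
  (retail); relative noise 2% counted vs 15% stated. Retail tablet
  observations occasionally (5%) appear through the tin-measurement
  channel.
* Nonresponse: recall not-remembered 17% / 2.8%, recall refused 10.6% / 0,
  stock refused 7.7% / 1.4% per stratum; a 7% whole-record "missing"
  channel at retail mirrors the unexplained missing category such surveys
  carry. Rates are illustrative of the field pattern, not calibrated
  claims.

A single master seed spawns named substreams (sales, flows, recall noise,
statuses, …), so toggling one error channel leaves the others' draws
unchanged — common random numbers, used by the monotone-degradation test
(SD of differences non-decreasing in σ_rc).

What the generator does **not** model: supply-chain links between
wholesalers and retailers, spatial/cluster sampling, stock-outs, temporal
dynamics beyond one interval, prices. Passing tests therefore validate the
estimator and agreement machinery under the stated error mechanisms, not
the field accuracy of either survey method.

## Validation scenarios

* **CI calibration** (`additive_bias_scenario`): one anti-malarial product
  per outlet, sales NB(μ = 100 AETD, k = 30) without zero-inflation, recall
  = truth − 4 + ε with σ = 9.7, everything else exact. The large mean keeps
  the max(0,·) truncation inert, so d = 4 − ε exactly and the 95% bias CI
  should cover 4 at its nominal rate; with zero-heavy sales the truncation
  would bias the estimand itself and no CI could be calibrated against the
  nominal δ. 500 replicates of 100 outlets are required to cover in ≥ 93%.
* **Proportional bias** (`proportional_bias_scenario`): γ = 0.03 at n = 60
  outlets, ZINB(π₀ = 0.2, μ = 6, k = 1.5) — positive, significant Pearson
  correlation expected.
* **Constant bias** (`constant_bias_scenario`): δ = −2 at volumes where
  truncation never binds — correlation indistinguishable from zero.

## Numerical and design choices

* Round-half-up for tin estimates; volumes themselves are carried as reals
  (a sold quantity can be a fraction of a course) and never rounded.
* 1.96 literal in the LoA (not a t quantile), so the symmetry identity is
  exact.
* Categories are independent per outlet: an outlet can contribute an RDT
  pair while its anti-malarial side is wholly excluded.
* Problem sizes in the test and acceptance runs (e.g. ~1,100-record
  conservation ledger, 500 calibration replicates, 10,000-draw coverage
  check) were chosen to make the checked properties statistically sharp
  while keeping the full suite runnable in well under a minute of compute.

## Known limitations

* The recall-truncation asymmetry means the additive-bias parameter δ is
  only the estimand of the Bland–Altman bias when volumes are well above
  zero; in zero-heavy markets the generator's "true" bias differs from δ
  by the truncation mass — intentional, since the same is true in the
  field.
* The outlier rule compares against the single next-largest outlet; two
  simultaneous outliers of similar size mask each other. With ≤ 1 outlier
  per stratum (the regime the default rates produce) this does not arise.
* LoA CIs use the 3·SD²/n approximation; exact noncentral-t intervals are
  out of scope.
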