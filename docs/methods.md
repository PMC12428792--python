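# Methods

This note documents the statistical procedures exposurekit implements, the
choices made where the published analysis left the method open, what the
synthetic-data generator does and does not emulate, and the known limits of
reproducibility.

## The cohort model

The unit of analysis is a patient record with categorical attributes drawn
from fixed controlled vocabularies (sex, residence, smoking, comorbidity,
occupational exposure, diagnostic group G1a/G1b/G2/G3, TNM stage II/III/IV,
p63, PD-L1, EGFR exon status) plus optional age and Ki-67. Diagnostic group
and histology are a fixed bijection (G1a = adenocarcinoma, G1b = squamous
cell, G2 = small cell, G3 = pulmonary neuroendocrine tumor), so histology is
stored once (as the group) and derived, which makes contradictory records
unrepresentable. Age classes partition the age axis at 50 and 65 years
(under 50 / 50–64 / 65+); one published table header reads "64<" but the
accompanying text defines class 3 as ≥65, and the prose definition is
authoritative here. Category label order follows the published table order
so cross-tabulations reproduce printed tables cell-for-cell.

Two-way tables and record collections convert losslessly into one another:
`expand_table` enumerates a table's (row, col) observation pairs in
row-major order and `crosstab`/`table_from_pairs` invert it. This is the
mechanism that lets published aggregate tables be re-analysed without
patient-level data, and it is property-tested as an exact round trip on
randomized tables. Three printed panels (the comorbidity-by-sex,
comorbidity-by-residence and exposure-by-residence panels) do not sum to
the cohort size as published; they ship flagged `display_only` and are
excluded from every statistical reproduction.

## The composite score

One point per component present: PD-L1+, p63+, EGFR mutation (any tested
exon), TNM III/IV, any comorbidity, aggressive histology (G2 or G3). The
source description lists these six components while describing a "0–5"
scale and a high class of "4–5"; the component list is taken as the
operational definition, so the attainable maximum here is 6 and the high
class is defined as ≥4, which leaves the three-class recoding (low 0–1,
medium 2–3, high ≥4) unchanged for every attainable total. Any subset of
components can be scored (`include=`) for sensitivity analysis. PD-L1
positivity is the record's binary label; no TPS threshold is imposed
because none was published.

## Contingency-table inference

* **Chi-square.** Pearson statistic without continuity correction, on the
  table after dropping zero-margin rows/columns (with a warning).
  Diagnostics (minimum expected count, percentage of cells with expected
  < 5) are computed from the actual table.
* **Monte Carlo p.** When requested — and automatically inside the full
  analysis whenever any expected count is below 5 — B random tables are
  drawn with *both margins fixed* (Patefield's algorithm, i.e., the
  multivariate hypergeometric null, the convention of the mainstream
  commercial software this analysis style follows), and
  p̂ = (1 + #{χ²\* ≥ χ²obs})/(1 + B) so a simulated p is never zero. The
  default B = 10,000 matches the half-width of 99% intervals such as
  0.935 ± 0.0065. The accompanying CI is the normal-approximation binomial
  interval at the 99% level.
* **Effect size.** Cramér's V with the textbook denominator
  n·(min(r,c)−1), clipped to [0,1]. Its CI is a percentile bootstrap over
  records (B = 2000 default); resamples that lose a category are
  recomputed on the collapsed table, and resamples collapsing below 2×2
  contribute V = 0.
* **Proportions.** Exact Clopper–Pearson (beta-quantile) intervals, chosen
  because the exact method reproduces the printed lower rebiopsy bound
  (4.3%) and no other standard method does; see Reproducibility for the
  0.13-point discrepancy on the upper bound.
* **Means.** t-based CI (mean ± t₁₋α/2,n−1·sd/√n), 5% trimmed mean
  (⌊0.05n⌋ observations removed per tail), adjusted Fisher–Pearson
  skewness; a constant sample yields a degenerate CI and skewness reported
  as 0 with an explicit flag.
* **Kruskal–Wallis.** Midrank ties, tie-corrected H, chi-square reference
  distribution with k−1 df, per-group mean ranks reported; an all-tied
  sample reports H = 0 with a flag instead of failing.
* No multiple-testing correction is applied anywhere, matching the
  exploratory character of the analysis plan.

## ROC validation

AUC is computed from midranks as the Mann–Whitney concordance probability
(ties counted ½), verified in tests against an exhaustive O(n₁·n₀) pair
count and an independent library implementation. The ROC curve has one
point per distinct threshold (descending) and its trapezoidal area equals
the rank AUC exactly. The CI is a percentile bootstrap over paired
resamples (B = 1000 default; single-class resamples are redrawn and
logged); a DeLong variance interval is available as `ci_method="delong"`
since the original interval method was not stated. Optimism correction
follows the bootstrap recipe for a *prespecified* score: optimism_b =
AUC(resample b) − AUC(original), corrected = apparent − mean optimism.
With no refitting inside the loop the correction is close to zero by
construction — which is the property the validation battery asserts
(|corrected − apparent| < 0.01 at B = 1000).

## Power design

Power is P(X > c) with X noncentral chi-square(df, λ = n·w²) and c the
central 1−α quantile; the required n is found by integer bisection and is
minimal by construction (power(n) ≥ target, power(n−1) < target). The
published design point (w = 0.25, α = 0.05, power = 0.80 → n = 126) is
reproduced only at df = 1 (λ = 7.849 ⇒ n = 125.6 → 126), although the
accompanying text mentions four groups; a four-group association test at
df = 3 would require 175. df is therefore a mandatory explicit parameter
rather than a hidden default.

## The synthetic cohort generator

The generator emulates the *study conditions*: the published marginal
frequencies and the qualitative dependence structure, not every printed
cell (the printed tables are mutually inconsistent in places, so a joint
distribution consistent with all of them need not exist). Per patient:
occupational exposure ~ Bernoulli(75/131); latent severity
z ~ N(β·exposure, 1) with β = 1.0; each severity-linked trait (advanced
stage, PD-L1, p63, any comorbidity, aggressive histology) ~
Bernoulli(logistic(γ₀ + 0.7·z)); EGFR mutation ~ Bernoulli(19/131) with
the published exon split 9:5:3:2 over exons 19/21/20/18, and a −1.428
log-odds PD-L1 penalty when mutated (logit(0.598) − logit(0.263), which
reproduces the published 73.7% vs 40.2% PD-L1-negative contrast and the
55.0% PD-L1 marginal). Conditional splits complete the categories: stage
IV with probability 89/120 given advanced (else III; non-advanced is II),
small cell 30/57 given aggressive, adenocarcinoma 45/74 given
non-aggressive, comorbidity type 8:48:29:23. Age is truncated normal
(62.82, 12.67) on [40, 85]; Ki-67 is truncated normal (60, 25) on [1, 99]
and is only loosely constrained (the study published no patient-level
Ki-67, just a non-significant Kruskal–Wallis across age classes).

The intercepts γ₀ are version-pinned constants computed once by
Gauss–Hermite moment matching against the latent mixture so every marginal
hits its target at the default slope; `calibrate_intercept` reproduces
them deterministically and is tested to 1e−4, but they are not re-fit at
runtime. `independence_config()` zeroes the slopes, the exposure effect
and the EGFR coupling (resetting intercepts to logit(target)), giving a
fully independent joint for type-I-error calibration.

What the generator does *not* emulate: the exact joint distribution of the
six score components (only marginals and two qualitative links are
constrained, so the emergent score-class split — {low 7, medium 61, high
63} at n = 131, seed 1, frozen as a regression value — is more severe than
the published {14, 78, 39}); within-advanced stage detail (IV vs III is an
independent coin given advanced severity, so the stage-IV-vs-rest endpoint
discriminates weakly on synthetic data while stage III–IV vs II
discriminates strongly); and any survival or longitudinal structure.
Passing tests on synthetic data therefore demonstrate correctness of the
*procedures* under a realistic dependence structure, not agreement with
the original cohort's unpublished joint distribution.

## Numerical choices and problem sizes

Monte Carlo tests default to B = 10,000 (matching the printed interval
widths); bootstrap CIs to B = 1000–2000. The validation battery uses
deliberately modest problem sizes chosen to make its checks sharp but
cheap: 500 simulated cohorts of n = 131 for the type-I-error study, 500
null tables at B = 999 for the p-value uniformity check (95% Kolmogorov
band), n = 50,000 for marginal recovery (3 Monte Carlo SEs), n = 20,000
for slope recovery (±0.15), 2000 replicates (plus exact enumeration over
k) for Clopper–Pearson coverage. Every stochastic routine takes an
explicit integer seed and is reproducible bit-for-bit; per-battery seeds
inside the full analysis are derived deterministically from the run seed.
Floating-point ties in the Monte Carlo exceedance count are tolerated at
1e−9 so resampled statistics equal to the observed one always count as
extreme.

## Reproducibility of the published numbers

Reproduced exactly (and asserted in the test suite and acceptance script):
the chi-square statistics 22.797 (comorbidity × smoking), 1.886 (TNM ×
group), 2.384 (TNM × age class) and the six score batteries 22.605,
24.353, 19.706, 29.772, 14.352, 4.171 (all to the printed 3 decimals, from
the expanded 131-record tables); the asymptotic p = 0.826 for the
comorbidity × score battery; the age CI [60.63, 65.01]; the required
n = 126; Monte Carlo p̂ inside both printed 99% intervals (≈0.935 and
≈0.024); the diagnostic-yield point estimates 91.6%/8.4%.

Not reproducible from the published aggregates, by construction:

* the printed AUCs 0.743/0.740/0.657 — they were computed on the
  unpublished patient-level 0–5 totals; the shipped surrogate is the
  3-class AUC on the expanded stage table, 2691/3738 ≈ 0.720, fixed by an
  exhaustive pair-concordance count;
* the printed Cramér's V values (e.g., 0.470 where χ² = 22.797, n = 131,
  2×5 gives 0.417) — they match no standard formula; the textbook V is
  implemented;
* the printed χ² for the sex/residence/exposure panels and three of the
  group panels (0.892, 3.515, 33.92, 11.98, 31.56, 16.910) — these
  disagree with their own printed cell counts (the comorbidity × group
  recomputation ≈ 24.8 even yields the printed p of 0.016);
* the printed "minimum expected frequency" values (20.34, 8.12) and the
  Kruskal–Wallis mean ranks (raw Ki-67 unavailable);
* the upper rebiopsy CI bound (printed 14.4% vs exact 14.53%).

Each of these is covered instead by a property-based check (oracle
equality, calibration, coverage, round-trip) rather than by a comparison
against an unreproducible printed number.

## Known limitations

The package analyses a single cohort cross-sectionally: no survival or
treatment-response modelling, no multiple-testing adjustment, no
comparison of correlated AUCs between endpoints, and no calibration
curves. The fixture tables support exactly the published vocabularies
(e.g., TNM II–IV only), though the record schema validates any of the
declared categories and is extensible in code.
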