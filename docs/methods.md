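# Methods

## Data model and counting conventions

The unit of counting is the case/report. A database is the JADER-shaped
four-table layout: a case list with sex (women / men / unknown; anything
outside the recognized vocabulary maps to unknown with a warning), drug
mentions with an involvement level (suspect / concomitant / interaction)
and an administration start date, event mentions coded as MedDRA
preferred terms (PTs) with an onset date, and an optional primary-disease
table that is stored but consumed by no statistic. Only suspect-drug
mentions define exposure; restricting to them never changes the report
total N++, because a case whose mentions were all concomitant still
counts in the comparator. PTs roll up to high-level terms (HLTs) through
a user-supplied one-to-one PT→HLT map; a case belongs to an event group
if at least one of its PTs maps there, duplicates counting once.

Dates must be fully specified; partial dates (year–month, as occur in
real extracts) coerce to missing rather than to a guessed day. Missing
dates exclude a case from the time-to-onset sample but never from
counting.

## Disproportionality screen

For each (drug, HLT) pair the 2×2 table is built over the whole database
("all other reports" as comparator), each case falling in exactly one
cell. The information component is the shrunk log2 observed-to-expected
ratio IC = log2((O+0.5)/(E+0.5)) with E = N1+·N+1/N++. The +0.5
shrinkage is applied uniformly, with no special-casing of zero counts;
pairs with O = 0 are reported as `not_available` rather than classified.

Two 95% interval methods:

* **Closed form (default)**: IC025 = IC − 3.3(O+0.5)^(−1/2) −
  2.4(O+0.5)^(−1), IC975 = IC + 2.4(O+0.5)^(−1/2) − 0.5(O+0.5)^(−1).
  This O-dependent quantile approximation reproduces published
  large-count worked examples (O = 213 and O = 400) to two decimals.
  It is calibrated for the 95% level only and refuses other levels.
* **Monte Carlo**: empirical quantiles of log2(G/(E+0.5)) with
  G ~ Gamma(O+0.5, 1), i.e. the posterior of the shrunk ratio
  conditional on E.

The two methods deliberately answer slightly different questions: the
closed form approximates the full BCPNN posterior, which carries
uncertainty in the margins, while the gamma posterior conditions on the
expected count and is therefore a little narrower. The lower bounds
differ by 0.056 bits at O = 100, 0.037 at O = 213, 0.026 at O = 400 and
0.016 at O = 1000 (upper bounds less). This is a fixed property of the
formulas, not a convergence issue; tests assert agreement at the 0.05-bit
level only where it actually holds (O ≥ 213). For small counts the two
are materially different and neither reproduces published small-count
bounds exactly (e.g. a published lower bound of 1.53 at O = 15 against
1.41 closed-form); the interval method behind those printed values is
not identifiable from the publication, so the divergence is documented
rather than patched.

Classification: signal iff IC025 > 1 bit; inverse signal iff IC975 < 0;
`not_available` iff O = 0; otherwise none. The inverse threshold
defaults to 0 — published tables flag inverse signals only where the
upper bound is negative — and both thresholds are configurable.
Threshold comparisons always use unrounded values; display rounding is
two decimals.

## Sex-subgroup contrast

Each stratum's expected count uses only its own margins
(E_women = Nw1+·Nw+1/Nw++, likewise for men); nothing is pooled across
sexes except through E* = E_women·OE_men, the count women would show at
the men's observed-to-expected ratio. ICΔ = log2((O_women+0.5)/(E*+0.5))
gets the same interval machinery applied to (O_women, E*). Unknown-sex
cases enter neither stratum (they stay in the overall screen); their
count is carried so the partition is checkable. O_men = 0 or a
non-positive expected count makes OE_men degenerate and the result is
flagged not-computable rather than silently zero.

A women signal requires all of ICΔ025 > 0, O_women > 2 and the
women-stratum IC025 > 0. Note that under either interval method the two
interval criteria are unreachable at O_women ≤ 2, so the count criterion
is a guard rather than the binding constraint.

**Attenuation at high exposure margins.** ICΔ compares OE ratios, and
each stratum's E absorbs the association being tested: with exposure
fraction p and rate ratio r, the stratum's event margin is inflated by
roughly 1 + p(r−1). When p·r is not small this shrinks the contrast —
in the bundled miniature (planted exposure 5%, ratio 40, female excess
2×) the ICΔ comes out near 0 even though women's co-reports outnumber
men's two to one. At rare exposure (p·r ≪ 1, the regime of real
spontaneous-report databases, where a single drug is a fraction of a
percent of reports) ICΔ converges to log2 of the planted sex multiplier;
the recovery experiments therefore use exposure margins of 0.5%.

## Weibull time-to-onset

Latency is (earliest onset among the case's events in the HLT) −
(earliest administration start among its suspect mentions of the drug)
+ 1 day; the inclusive count makes same-day onset representable on
Weibull support. Onsets strictly before first administration are data
errors and are excluded, counted separately from missing-date
exclusions.

The fit is an uncensored two-parameter Weibull MLE (location fixed at 0:
spontaneous reports contain only realized events, and a free location is
not identifiable at these sample sizes). Optimization runs over
(log α, log β) — Nelder-Mead followed by BFGS polish from a
moment-flavoured start — and 95% Wald bounds come from the
central-difference observed information on the log scale, exponentiated
back, so bounds are always positive. An independent survival-analysis
implementation (lifelines' Weibull fitter) is used as a cross-check
oracle in the tests, never as the implementation. Samples below `min_n`
(default 5) are reported `not_available`; zero-spread samples are
refused outright because the shape diverges.

Pattern taxonomy from the shape CI: wear-out (increasing onset rate) iff
the lower bound exceeds 1; early failure iff the upper bound is below 1;
otherwise indeterminate. The quantile helper T_p = α(−ln(1−p))^(1/β)
supports onset narratives (median onset; 63.2% of onsets by T = α).

Coverage of the Wald CI was checked by simulation: at n = 200
exponential (β = 1) samples, the nominal-95% shape interval covers 1 in
≥ 90 of 100 seeded replicates; at n = 150, Weibull(100, 1.5) samples
refit with median relative error below 10% on both parameters.

## Synthetic-report generator

The generator emulates the statistical structure the screen assumes:
independent Bernoulli drug exposures, events drawn at margin ×
rate-ratio × women-multiplier for associated, exposed (and female)
cases, association-attributed onsets at administration start plus a
ceiling-rounded Weibull latency, uniform background onset dates, and
independent knockout of dates at a missingness rate. Defaults, chosen
once as plausible for a JADER-like extract: 49/49/2% women/men/unknown
sex; 35% missing dates (published onset analyses lose roughly 40% of
co-reports to undated records); reporting window 2004-01-01 to
2019-12-31. Identical seeds give identical databases.

What it does *not* emulate — and what passing tests therefore do not
establish about real data: reporting biases (launch-period waves,
notoriety effects, underreporting), confounding and co-medication,
duplicate or updated case versions, dose, and any correlation between
events within a case beyond the planted associations. Null behaviour is
exactly null by construction, which is what makes the false-positive
tests meaningful.

The bundled miniature fixture (≈2,000 cases by default) plants one
strong association (ratio 40) so that a signal is recoverable at small
n; as discussed above this puts it deliberately outside the rare-exposure
regime in which ICΔ is unbiased, and the subgroup recovery experiments
use their own rare-exposure configurations (exposure 0.5%, ratio 4,
multiplier 2, n = 100,000–150,000 reports; expected co-report counts of
roughly 64 for the detection study and 230 women / 115 men for the
contrast study).

## Problem sizes used in the checks

Simulation-based checks run at: 10 × 50,000 reports for the null
false-positive study and the planted-signal detection study; 10 ×
150,000 reports for the sex-multiplier recovery (median over seeds,
since a single seed's ICΔ has sampling SD ≈ 0.16 at these counts); 50 ×
150 latencies for Weibull recovery; 10^6 draws for Monte-Carlo interval
comparisons. Worked-example recomputations are closed-form and
deterministic.

## Known limitations

* The closed-form interval is 95%-only, and its constants are an
  approximation: small-count bounds differ from published small-count
  examples by up to ~0.1 bits.
* The ICΔ interval applies the same machinery to (O_women, E*); the
  interval construction behind published ICΔ bounds could not be
  identified and point estimates are the reliable comparison.
* No multiple-comparison adjustment, reporting-odds-ratio family
  statistics, or reporting-bias corrections are provided.
* Real-extract ingestion assumes upstream deduplication of follow-up
  case versions; the loader enforces case-id uniqueness but cannot merge
  versions.
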