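# srsignal

Signal detection and onset-pattern analysis for spontaneous adverse-event
reporting databases, built around three statistics used in
pharmacovigilance practice:

* the **BCPNN information component** (IC), a shrunk log2 observed-to-
  expected reporting ratio with 95% credible bounds, for screening
  drug–event pairs;
* the **IC-delta subgroup contrast**, which compares women's and men's
  observed-to-expected ratios to flag sex-disproportionate reporting;
* **Weibull time-to-onset profiling**, which classifies whether an adverse
  event's hazard rises (wear-out), falls (early failure) or stays flat
  with time on drug.

The package is organised around the JADER table layout (the Japanese
Adverse Drug Event Report database: `demo`/`drug`/`reac`/`hist` CSVs) and
was written to reproduce a published screen of pituitary-related adverse
events — anterior pituitary hypofunction and hyperfunction, posterior
pituitary disorder, pituitary neoplasm — under the six immune checkpoint
inhibitors (ipilimumab, nivolumab, pembrolizumab, atezolizumab, avelumab,
durvalumab). It is generic over drugs and MedDRA high-level-term groups:
users supply their own PT→HLT map (MedDRA is licensed and is not bundled)
and a declarative run configuration. A synthetic-report generator with
planted ground truth stands in for the licensed extract, so the full
pipeline is testable offline.

## The statistics

For a drug–event pair with co-report count *O* = N11 in a database of
N++ reports, the expected count under independence is
E = N1+·N+1/N++ and

IC = log2((O + 0.5)/(E + 0.5)).

A pair is a *signal* when the lower 95% credible bound IC025 exceeds 1
bit, and an *inverse signal* when the upper bound falls below 0. The
default interval is the closed-form quantile approximation
IC ∓ {3.3, −2.4}(O+0.5)^(−1/2) − {2.4, 0.5}(O+0.5)^(−1); a Monte-Carlo
gamma-posterior alternative is provided for cross-validation.

The sex contrast computes each stratum's own observed-to-expected ratio
(OE_women, OE_men), forms E* = E_women·OE_men — the women's expected
count if women reported at the men's rate — and shrinks:

ICΔ = log2((O_women + 0.5)/(E* + 0.5)).

A *women signal* requires ICΔ025 > 0, O_women > 2 and the women-stratum
IC025 > 0.

Onset latency T (days from first administration of the suspect drug to
event onset, counted inclusively) is fitted with a two-parameter Weibull,
hazard λ(T) = (β/α)(T/α)^(β−1), by uncensored maximum likelihood; the
onset pattern is read off the 95% CI of the shape β (wholly above 1 →
wear-out, wholly below → early failure, otherwise indeterminate).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
extract (all outputs land in `results/`):

```
python analysis/01_simulate.py        # 20,000-report database, one planted association
python analysis/02_screen_signals.py  # BCPNN screen of 24 (drug, HLT) pairs
python analysis/03_sex_subgroup.py    # women-vs-men IC-delta contrast
python analysis/04_weibull_onset.py   # Weibull fits for signal pairs
python analysis/05_worked_examples.py # recompute published worked examples
```

The generator plants one association — ipilimumab × anterior pituitary
hypofunction, reporting-rate ratio 40, 2× female excess, Weibull(120, 1.6)
onsets. The screen recovers exactly that pair:

```
screened 24 (drug, HLT) pairs over 20000 reports
signals detected: 1
      drug                              hlt  n11  expected    ic  ic025  ic975 classification
ipilimumab  anterior pituitary hypofunction  260     16.26  3.96   3.74   4.10         signal
```

and the Weibull step recovers the planted onset profile:

```
ipilimumab x anterior pituitary hypofunction: n_used=118 (missing-date exclusions: 142)
  alpha = 126.4 days (112.5-142.0), beta = 1.63 (1.41-1.88) -> wear_out
  median onset 101 days; 63% of onsets by T = alpha = 126 days
```

β's CI lies above 1, so the onset rate increases with time on drug; the
fitted scale says ~63% of onsets occur within the first 126 days.
Script 03 shows both regimes of the sex contrast: in the miniature the
planted drug reaches 5% of all reports and the contrast is attenuated
(−0.03 bits), while a rare-exposure experiment (0.5% of 100,000 reports)
returns `IC-delta = 0.94 bits (0.64-1.14)` for the planted 2× excess —
see `docs/methods.md` for why the margin matters.

A `srsignal` console command exposes the same steps
(`simulate` / `screen` / `subgroup` / `tto` / `full`) over YAML configs
for use on real JADER-layout extracts.

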