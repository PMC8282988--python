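# fertdecomp

Fertility and family-planning decomposition for DHS-style survey microdata.

Between its two most recent national surveys, Jordan recorded a fall in the
total fertility rate (3.5 → 2.7 births per woman) *together with* a fall in
contraceptive prevalence among married women (61.2% → 51.8%) — the opposite
of the usual TFR/CPR relationship. Explaining such a pattern requires
re-estimating every link in the chain: fertility rates from retrospective
birth histories, the conversion from an ever-married sample to all women,
the Bongaarts proximate determinants, wanted fertility and unmet need,
infecundity, the contraceptive calendar, and external checks against vital
registration and commodity-distribution statistics. `fertdecomp` implements
that full toolkit for demographers and family-planning analysts working
with DHS-style recode subsets, plus a synthetic-data generator that plants
known ground truth so every estimator is testable without restricted
microdata.

## The models

**Birth-history fertility.** Age-specific fertility rates follow the DHS
convention: with century month codes (CMC = 12·(year−1900)+month), a birth
is attributed to the mother's age group at the birth CMC, and exposure is
weighted woman-months in the age-group × period intersection, truncated at
the (incomplete) interview month. TFR = 5·Σₐ ASFR(a)/1000. Confidence
intervals use a delete-one-cluster jackknife over primary sampling units.
Because ever-married samples lack never-married exposure, all-women rates
inflate each group's denominator by (EM+NM)/EM using never-married counts
from the household roster (ages known only in completed years, taken as
age+0.5).

**Proximate determinants (Bongaarts).**

    TFR = Tf · Cm · Cc · Ci · Ca
    Cm = Σ m(a)·g(a) / Σ g(a)        Cc = 1 − 1.08·u·e
    Ci = 20 / (18.5 + i)             Ca = TFR / (TFR + 0.4·(1+u)·TAR)

with Tf total fecundity (default 15.3), m(a) the proportion married, g(a)
marital ASFRs, u contraceptive prevalence, e mean use-effectiveness, i mean
postpartum-insusceptible months, TAR the total abortion rate. When observed
fertility falls short of the no-abortion prediction, the implied TAR is
back-calculated as (predicted − observed)/(0.4·(1+u)).

**Other components.** Revised DHS unmet-need classification; wanted TFR
(births kept only when parity at conception was below the respondent's
ideal family size); monthly CPR reconstructed from calendar strings with
the standard exclusions (pre-marriage months, women 45+ in a past month);
CBR/GFR from end-year populations via exponential mid-year interpolation
P_mid = P₁·exp(r/2); and couple-years of protection / estimated modern use
(EMU) from commodity series.

## Worked example

```python
import fertdecomp as fd

params = fd.national_2017_schedule(n_women=5000, seed=1)
survey = fd.generate_survey(params)          # population, respondents, roster
fd.generate_calendars(survey)

period = fd.RatePeriod.years_before_interview(params.interview_cmc, years=3)
asfr = fd.compute_asfr(survey.population, period)
print(f"TFR (3-year window): {asfr.tfr:.2f}")
print(f"CPR  {fd.cpr(survey.women):.1f}%   mCPR {fd.cpr(survey.women, modern_only=True):.1f}%")
print(f"mean insusceptibility {fd.mean_insusceptibility(survey.women):.1f} months")

ca, tar = fd.implied_tar(tfr_observed=2.7, tfr_predicted_no_abortion=3.7, u=0.518)
print(f"implied TAR {tar:.1f} abortions/woman (Ca = {ca:.3f})")
```

Output:

```
TFR (3-year window): 2.73
CPR  51.6%   mCPR 37.0%
mean insusceptibility 3.1 months
implied TAR 1.6 abortions/woman (Ca = 0.730)
```

The generator was asked for the published 2017 national age-specific
fertility schedule (which sums to a TFR of 2.73) and a method mix totalling
51.8% prevalence; the estimators recover both from the simulated birth
histories and current-status reports. The last line reproduces the
abortion back-calculation: reconciling an observed TFR of 2.7 with a
predicted no-abortion TFR of 3.7 at 51.8% prevalence would require 1.6
abortions per woman.

A full round analysis — simulate (or load CSVs), estimate, decompose,
report — runs through the pipeline or the CLI:

```bash
fertdecomp run --config analysis.yaml --seed 1 --out results/
fertdecomp tfr --women women.csv --roster roster.csv --all-women
fertdecomp emu --service service_stats.csv --wra vitals.csv
```

## Layout

- `src/fertdecomp/synthetic_data.py` — survey/calendar/registry generator
- `src/fertdecomp/fertility_rates.py` — ASFR/TFR, jackknife, vital rates
- `src/fertdecomp/all_women.py` — ever-married → all-women adjustment
- `src/fertdecomp/proximate_determinants.py` — Bongaarts indices, TAR
- `src/fertdecomp/fp_indicators.py` — CPR, unmet need, WTFR, infecundity
- `src/fertdecomp/calendar_analysis.py` — monthly CPR, pregnancy outcomes
- `src/fertdecomp/service_statistics.py` — CYP and EMU
- `src/fertdecomp/pipeline.py`, `cli.py`, `io.py` — orchestration and I/O

`docs/methods.md` documents the models, generator design, parameter
defaults, and known limitations.
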