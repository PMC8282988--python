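# Methods

This note documents the models implemented in `fertdecomp`, the design of
the synthetic-data generator, the defaults that matter, and the limits of
what passing tests demonstrate.

## Estimation conventions

**Ages and periods.** All dates are century month codes,
CMC = 12·(year−1900)+month. A woman's exact age in months at any CMC is
`cmc − v011`. Age groups are the seven 5-year bands 15–19 … 45–49; group
k covers 60k ≤ age_months − 180 < 60(k+1). Reporting periods are half-open
CMC intervals `[start, end)`; the interview month is incomplete and is
excluded from both exposure and births.

**ASFR/TFR.** Numerators are weighted births at the mother's age group at
the birth CMC; denominators are weighted woman-months in the group×period
intersection divided by 12. A group with zero exposure has an *undefined*
rate — it is flagged (`ASFRTable.undefined_groups`), never reported as
zero. Since a zero-exposure group can carry no births, it contributes
nothing to the TFR sum. Rates are kept unrounded internally; the reporting
layer rounds rates to 1 decimal and indices to 3.

**Marital rates.** `compute_asfr(..., exposure="married")` clips each
woman's exposure at her first-marriage CMC, giving the marital schedule
g(a) used by the marriage index.

**Variance.** Delete-one-cluster jackknife:
se² = (k−1)/k · Σᵢ(θ₍ᵢ₎ − θ̄)² over the k leave-one-cluster-out
replicates; CIs are normal (z·se, level configurable). Between-survey
changes use an independent-samples z-test on combined jackknife SEs; the
choice of a plain z-test is ours — the source analyses report significance
without naming a test.

**All-women adjustment.** Never-married women (assumed childless, a good
approximation where non-marital childbearing is negligible) enter through
denominator inflation factors (EM+NM)/EM rather than fabricated person
records. The roster gives age only in completed years; a woman aged a is
treated as exactly a+0.5 years. Two factor modes:

- *snapshot*: weighted headcounts at the interview. Simple, but when
  marriage hazards are steep the interview-time headcount over-represents
  never-married women relative to the estimation window, inflating
  denominators: on the synthetic rounds this understates TFR by ≈0.2–0.3.
- *exposure* (default in the pipeline): never-married roster ages are
  back-projected over the period and the factor is a ratio of
  woman-months. Under the childlessness assumption this is an exact
  decomposition of all-women exposure — equivalent to appending the
  never-married women to the sample — and agrees with the direct all-women
  estimate to within 0.1 births per woman on synthetic data.

Household weights normalize the factors.

**Unmet need.** Revised DHS-style classification of currently married
women, in order: (1) contraceptive users → met need, limiting if they want
no more children or are sterilized; (2) pregnant or postpartum-amenorrheic
women by the wantedness of that pregnancy (then → no need, mistimed →
unmet spacing, unwanted → unmet limiting); (3) infecundity test; (4) the
fecund remainder by stated preference (want soon → no unmet need; want
later/undecided → unmet spacing; want no more → unmet limiting). The
infecundity rule is: *no birth in the past 5 years* AND (self-reported
"can't get pregnant" OR (first married ≥5 years ago AND never used
contraception)). Published descriptions conjoin all four criteria while
the full DHS algorithm disjoins several; this middle reading preserves the
invariant that a never-user with a recent birth — demonstrably fecund — is
never classified infecund. Categories partition married women exactly;
missing fields raise, never default silently.

**Wanted TFR.** A birth is wanted when the mother's parity at its
conception (births more than 9 months before it) was below her ideal
family size; non-numeric ideal responses count all births as wanted (the
standard convention, configurable). Denominators are untouched, so
WTFR ≤ TFR identically.

**Calendar reconstruction.** Calendars are strings with index 1 = the
interview month and increasing index = earlier months. Monthly prevalence
excludes a woman's pre-marriage months (marital status inside the calendar
is unobserved; remarriage gaps are indistinguishable — an inherited data
limitation) and any month in which she was 45 or older. The most recent
pregnancy outcome is the B/T cell closest to the interview; terminations
take the respondent's type report for the latest termination, and a
termination without a valid type is reported as `unclassified`.

**Vital rates.** Within-year growth is constant exponential:
r = ln(P_t/P_{t−1}), mid-year population P_{t−1}·exp(r/2), taken as the
person-years lived. CBR and GFR divide registered births by mid-year total
and WRA populations respectively.

**CYP and EMU.** Commodity units convert to couple-years of protection via
the standard factors (pill 15 cycles, condom 120 units, injectable 4
doses per CYP; IUD 4.6, implant 2.5, sterilization 10 years per
insertion/procedure) — configurable because source analyses rarely print
theirs. EMU spreads each long-acting insertion over a flat profile of
round(years-per-insertion) years (optionally with geometric
discontinuation decay), adds short-term CYP as current users, scales by a
private-sector inflation factor (default 1.0 — pharmacy supply is known to
be missing from public logistics data but unquantified), and divides by
women of reproductive age. Years before the series start contribute no
history, so early years understate long-acting use (warm-up); EMU is a
trend indicator, not a level estimate of survey prevalence.

## The synthetic-data generator

The generator simulates a female population aged 15–49 at a fixed
interview month. `n_women` is the size of that population (the sampling
frame); its ever-married members form the respondent file and everyone
enters the household roster.

**Marriage.** First marriage follows piecewise-constant annual hazards by
age group and nationality, sampled exactly on a monthly grid by inverse
CDF. Defaults give ever-married shares rising from ≈5% (15–19) to ≈75%
(45–49) for Jordanian women, with substantially earlier marriage for
Syrian women. Respondents are treated as currently married (no
dissolution by default); spousal separation enters only through the
`living_with_husband` report (default 95.5%).

**Fertility: cohort-calibrated thinning.** A naive per-month hazard of
rate/12,000 suppressed during pregnancy and postpartum insusceptibility
does *not* reproduce the target ASFRs: suppression and the renewal
transient after marriage bias realized fertility low by 0.1–0.4 births per
woman. Instead, each month t the expected number of births due at t+9 in
every nationality × age-group cell is pinned to
rate/12,000 × the realized all-women headcount of the cell, and that many
conceptions (stochastic rounding with signed carry, so cell totals are
unbiased at every horizon) are allocated uniformly at random among the
cell's currently married, fecund, non-pregnant, non-insusceptible women.
Realized ASFRs are therefore unbiased for the planted schedule at any
sample size and markedly less variable than a Poisson process —
TFR estimates on 5,000-woman populations have a Monte-Carlo sd of ≈0.005.
Pregnancy occupies 9 calendar cells (conception + 8) ending in B;
terminations (default 10.8% of pregnancies, type split ≈78/18/4
miscarriage/abortion/stillbirth, matching the 2017-like outcome
distribution) occupy 3 cells ending in T. Postpartum insusceptibility
after each birth is geometric (or fixed) with mean
`mean_insusceptibility_months` (default 3.1 months, the duration implied
by a postpartum index of 0.926). There is no parity feedback and no
contraception→fertility feedback: fertility and use are painted to their
respective targets independently, which is what makes every planted
parameter exactly recoverable.

**Contraceptive use.** A per-woman Markov chain runs over months that are
married, fecund and not pregnant/insusceptible: initialization at marriage
draws from the stationary distribution; adoption into method m occurs at
rate d_m·ũ_m/π₀ and discontinuation at the per-method monthly rate d_m, so
occupancy is stationary at ũ. The within-susceptible mix ũ is the planted
mix inflated by 1/(1 − β − φ), with β the realized pregnant/amenorrheic
share and φ the realized infecund share among married women at interview —
pregnant and infecund women report non-use, as in current-status survey
measures — so the measured CPR recovers the planted prevalence. Zero
discontinuation degenerates correctly: no adoption, initial users persist
in one unbroken episode.

**Infecundity.** A sterility onset at least 69 months before the
interview is assigned among longer-married women with an age ramp scaled
so the expected classified share among married women equals
`infecund_share` (2017-like default 14.5%, 2012-like 8.7%). Onset women
stop conceiving and using and report the "can't get pregnant" preference,
so the unmet-need classifier recovers the planted share.

**Reports.** Ideal family size is drawn from a planted distribution (mode
4, mean ≈3.8, 3% non-numeric). Wantedness of the current/last pregnancy
derives from parity at conception vs ideal (unwanted when parity ≥ ideal;
otherwise mistimed with probability 0.08). Preferences follow parity vs
ideal with fixed splits; recent sexual activity (90.6% within 4 weeks) and
cohabitation are independent draws. Weights are equal by default, with
optional cluster-level gamma noise to exercise the weighted estimators;
women are assigned uniformly to `n_clusters` clusters (default 150) in two
strata.

**Round presets.** `jpfhs_2017_like` uses the published per-nationality
2017 ASFR schedules, the 2017 method mix (totalling 51.8 = 37.4 modern +
14.4 traditional), infecund share 14.5%. `jpfhs_2012_like` scales the 2017
national schedule to a TFR of 3.5 (the 2012 round published only the
total), uses a 2012 mix totalling 61.2, infecund share 8.7%, and 2012-era
nationality shares. Method-mix presets reconstruct the published totals
and the individually-published method shares (condom, periodic abstinence,
withdrawal, IUD); the remaining shares are chosen to sum exactly to the
printed totals. Failure-rate defaults are standard 12-month typical-use
values; with the two preset mixes they give use-weighted average
effectiveness of 90.7% and 91.3%, reproducing the reported slight rise.

**What the generator does not emulate.** Full recode files (hundreds of
variables), interviewer and recall effects, nonresponse, marital
dissolution histories, parity-dependent fertility control, or a male
roster (the roster holds women 15–49 only). Unmet-need *levels* emerge
from the preference splits rather than being planted, so round presets
reproduce the direction of change but not the published level. The
marriage-index level similarly depends on the marriage-hazard defaults.
Passing tests therefore demonstrate estimator correctness and internal
consistency, not that the generator is a statistical twin of the surveys.

**Variance reduction and inference tests.** Balanced birth allocation
suppresses the cross-replication variance of fertility-linked statistics
(by design: it is what lets a 5,000-woman simulation pin the TFR to the
published confidence band). Within one realization, cluster-to-cluster
dispersion remains essentially iid, so jackknife SEs on fertility-linked
statistics *over*-state their true replication variance and design-based
tests on them are conservative (measured type-I ≈0.6% at the nominal 5%
level for CPR). The type-I calibration check therefore uses an
independent per-woman report (recent sexual activity), for which the
jackknife is exact; it lands at the nominal rate.

## Numerical choices and problem sizes

- Seeds: every stochastic component derives from `numpy`'s `SeedSequence`
  spawned off a single integer; identical parameters give byte-identical
  CSV output.
- Degenerate inputs raise typed errors (`ParameterError`,
  `EstimationError`, `ClassificationError`, `SchemaError`) rather than
  returning silent defaults; Cc < 0 raises rather than clamping.
- Test problem sizes: the shared fixture simulates 4,000 women; the
  TFR-recovery check runs 20 replicates of 5,000 women (≈5 s); the type-I
  calibration runs 500 null replicate pairs of 400 women in 30 clusters
  (≈80 s). These sizes were chosen so realized Monte-Carlo error is a
  small fraction of each tolerance while the whole suite stays about a
  minute of compute.
- The calendar length defaults to 72 months and is configurable (real
  instruments vary).

## Known limitations

- The infecundity classifier implements one defensible reading of the
  partially-specified published rule (see above); alternative readings
  shift the secondary-infecundity level by a few points.
- Bongaarts effectiveness weights default to the classic use-effectiveness
  table (sterilization 1.0, IUD 0.95, pill 0.90, others 0.70); the source
  analyses' exact weights are not public, so measured Cc levels are
  comparable in structure but not calibrated to the published index.
- EMU adjustment constants (long-acting continuation profiles,
  private-sector inflation) default to transparent assumptions; Bayesian
  prevalence modelling (FPET-style) is out of scope — this package
  produces the EMU inputs such tools consume.
- Remarriage gaps inside the calendar window cannot be represented, so
  pre-first-marriage exclusion is the only marital filter — the same
  limitation the source data has.
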