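# Methods

## The analysis

`chww_uptake` evaluates a household-outreach pilot in which Community
Health and Wellbeing Workers (CHWWs) — trained, paid lay workers modelled
on Brazil's Family Health Strategy agents — make proactive visits to
households registered at one GP practice. Households that received at
least one visit form the intervention arm; allocated-but-unvisited
households form the control arm. This is a natural experiment, not a
randomised allocation, and the package makes no causal claim: it computes
the descriptive comparisons such a service evaluation reports.

The primary outcome is the **Composite Referral Completion Indicator
(CRCI)**. For household *h*,

    CRCI_h = min(1, received_h / eligible_h),

where `eligible_h` counts eligible person-services over all members (a
member eligible for *k* services contributes *k*) and `received_h` counts
distinct in-window service receipts by members. Summaries are reported
per arm as mean ± SD over households with a defined ratio, for three
categories: immunisations, screenings + NHS Health Check, and overall.

Secondary outcomes: per-service 2×2 arm comparisons (Pearson chi-squared,
1 df, no continuity correction), household-occupancy comparisons, and a
difference-in-difference on GP consultation volume between the ten months
before the pilot (Sep 2020 – Jun 2021) and its first ten months
(Jul 2021 – Apr 2022).

## Eligibility rules

Twenty-one services are modelled: 16 immunisations (three COVID-19 dose
services, shingles, five infant-schedule rows, HPV, influenza, MMR ×2,
PCV ×2, PPV), four screening bands (bowel; breast; cervical 25–49 and
50–64) and the NHS Health Check. Each rule is a closed birth-date window
exactly as a GP audit prints it, optionally with:

* a sex restriction (breast and both cervical bands are female-only);
* a *recurrence cutoff* — "last screening before July 2019" read as
  strictly before 2019-07-01; a prior event on/after the cutoff removes
  eligibility. Prior-event dates are carried as `last_*` columns on the
  patient record, as an audit export provides them, rather than being
  reconstructed from events;
* exclusion flags (Health Check only: statins, diabetes, hypertension and
  related conditions collapsed to one `hc_exclusion` boolean — the export
  does not enumerate codes);
* the influenza rule, which carries two birth windows (school-age band
  and 65+) plus an any-age at-risk extension, and counts receipts only
  within the vaccination season (Sep 2021 – Mar 2022). All other services
  count receipts from the intervention start through a three-month lag
  (1 Jul 2021 – 30 Apr 2022).

Every analysed patient counts as eligible for all three COVID-19 dose
services: eligibility criteria changed repeatedly during the study
period, so the audit treats the register as universally eligible.
Multi-dose infant rows use dose-specific service codes, so numerator
matching by code counts exactly the qualifying dose.

Design choice: birth windows are applied verbatim as closed date
intervals, with no age-at-reference-date arithmetic — the printed bounds
are the rule, which avoids any ambiguity about reference dates.

## The numerator is not gated on computed eligibility

`count_received` counts one in-window receipt per (patient, service) for
any service in the rule registry, whether or not the patient's record
makes them look eligible. This mirrors how the audit is actually built —
an eligibility list merged with a receipts list — and it is what makes
raw ratios above 1 possible when eligibility evidence is missing from a
record. The CRCI caps such households at 1 and flags them (`capped`).
Gating the numerator on computed eligibility would make the cap
unreachable by construction.

## Cohorts and views

Households are formed by grouping identical normalised addresses
(case-fold, strip punctuation, collapse whitespace) and receive stable
alphanumeric codes assigned in sorted-address order. Two analysis views
are built: *immunisations* (every household — everyone is eligible for at
least the COVID services) and *screening_hc* (only households with at
least one screening/Health-Check-eligible member, since a household that
cannot receive screening cannot contribute to screening uptake). The
sensitivity analysis removes deducted patients — people taken off the
practice register ("ghost patients") whose deduction date the main
analysis cannot see — before any view is built.

The consultation cohort keeps non-deducted patients and resolves
membership per period (registered on or before the period's end), so the
before- and during-period denominators can differ through births and new
registrations. Consultations count when delivered by one of the thirteen
GP-type clinician roles and not flagged as a scheduled review.

## Display conventions

Published audit tables print integer percents and 2-dp proportions, and
their narrative ratios are computed *from the printed values*. The
package therefore distinguishes:

* `raw` mode — arithmetic on unrounded values;
* `displayed` mode — inputs first rounded half-up to their printed
  precision (2 dp for CRCI means, integers for percents), result rounded
  half-up to an integer percent (relative differences) or 2 dp (percent
  changes).

All rounding is half-up (away from zero), not banker's. SDs use the
sample (n−1) convention. P-values print at 2 dp, "<0.01" when they round
below 0.01, and "-" when a zero expected cell makes the test invalid.

## Synthetic-data generator

Because patient-level GP exports cannot be published, `simulate`
generates a register with the structure the analysis assumes. Defaults
are the pilot's study conditions:

| parameter | default | origin |
|---|---|---|
| `n_households` | 662 | pilot cohort size |
| `occupancy_probs` | (.248, .213, .139, .130, .270) | pooled occupancy table |
| `occupancy_tail_mean` | 1.62 | Poisson extra members in the 5+ bin, so mean occupancy ≈ 3.4 (2251 patients / 662 households) |
| `p_visited` | 160/662 | visited-household fraction |
| `baseline_uptake` | per-service control-arm uptake fractions | published service table |
| `intervention_multiplier` | 1.4 | the 40% headline lift |
| `icc` | 0.05 | upper planning scenario for household clustering |
| `consult_rate` | 4.3 /person/10 months | before-period totals over 733 patients |
| `consult_dispersion` | 0.8 | gamma shape; consultation counts are overdispersed in all primary-care data |
| `arm_period_effect` | 0.95 | intervention × during-period rate multiplier |
| `p_deducted` | 0.05 | ghost-patient fraction |
| `p_missing_eligibility` | 0 | off unless corruption is being studied |

Mechanisms, and what they do and do not emulate:

* **Household clustering**: for each (household, service) the uptake
  probability is drawn from a beta distribution with mean *p* and
  intra-class correlation `icc` (beta-Bernoulli mixture), then members'
  receipts are independent Bernoulli draws. This is the simplest
  exchangeable-within-household mechanism; the ICC is exact per service
  indicator. Verified by ANOVA ICC recovery on the booster indicator —
  the moment estimator on a rare indicator (prevalence ≈ 0.06) has
  seed-to-seed SD ≈ 0.013 even at 5000 households, so recovery is
  checked on the highest-prevalence universal service.
* **Demographics**: ages come from a piecewise-uniform band mixture
  (≈15% aged 65+, ≈5% under five, one band born during the pilot), sex is
  balanced, and screening histories give each in-band candidate a recent
  (post-cutoff) prior screen with probability 0.45 and an old one with
  probability 0.30. No demographic table was available to calibrate
  against, so eligible fractions are approximate by construction; tests
  treat them as order-of-magnitude, not targets.
* **Consultations**: per-person gamma frailty shared across periods,
  Poisson counts given the frailty (i.e. negative binomial), exposure
  pro-rated for mid-period birth or deduction. Excluded records
  (nurse-role and scheduled reviews, ~30% extra) are generated so the
  role/flag filter has something to do.
* **Ghost patients** keep their register row but accrue no events on or
  after a deduction date drawn uniformly over the calendar.
* **Missing eligibility evidence** (`p_missing_eligibility`): a kept
  receipt of a recurrence-based service overwrites the patient's
  `last_*` date with a post-cutoff date, so the record looks ineligible
  while the receipt remains — the route to raw ratios above 1.
  Immunisation eligibility is birth-date-driven and cannot be corrupted
  this way; at realistic uptake rates capping is correspondingly rare
  (as it was in the pilot: 6 of 662 households), so tests of the capping
  path plant near-complete uptake (0.95) to exercise it.
* **Not modelled**: CHWW visit dynamics or schedules, contamination
  between arms, multi-practice registration, or correlation between a
  household's uptake and its consultation rate. A green test suite shows
  the pipeline computes the right statistics on data with the assumed
  structure; it does not validate those assumptions against real
  households.

One root `default_rng(seed)` drives every draw in a fixed order
(households → demographics → histories → per-service uptake →
consultations), so a seed fixes the export byte-for-byte; each uptake
service burns its household-level draws even when unused so the stream
layout does not depend on parameter values.

## Power and design effect

A scaled study would allocate whole CHWW patches (~100 households), so
household outcomes cluster within patches and the two-sample requirement
inflates by `DEFF = 1 + (m − 1) · ICC`. `required_households` applies the
normal-approximation comparison of means, `n per arm = 2 (z_{1−α/2} +
z_{power})² σ² / Δ² · DEFF`, with Δ the relative effect times the
baseline CRCI, rounded up. Defaults (baseline 0.15, SD 0.17, 30% effect,
90% power, α 0.05) give requirements that increase in ICC exactly as the
cited planning scenarios do (ICC 0.01 < 0.02 < 0.05); the cited absolute
numbers rest on unpublished variance assumptions, so the package treats
ordering and magnitude — not the exact values — as the check.

`simulated_power` replays the full synthetic pipeline per replicate and
applies a Welch t-test to household CRCIs at α. At zero effect the
rejection rate is checked against α using 600-household replicates: on
much smaller cohorts the skewed, point-massed household ratios visibly
miscalibrate any t-based test (measured: 0.033 at 200 households with
ICC 0.05, 0.073 with ICC 0), which is a property of the t-test, not of
the generator.

## Numerical and edge-case choices

* Zero-denominator CRCI is undefined (`None`/NaN) and excluded from
  summaries, never treated as 0.
* Chi-squared tests are invalid (displayed "-") when an expected cell is
  exactly 0; negative counts raise.
* Duplicate same-service receipts count once; unknown service codes are
  logged and ignored; rows with unparseable required dates are rejected
  with their row number.
* Household codes, patient IDs and all CSV outputs are deterministic
  given input order-independent content.
* The exact asymptotic-vs-exact gap of the uncorrected chi-squared test
  is documented by a test comparing it with a full conditional
  enumeration on small tables: at totals ≤ 30 the two genuinely differ
  (by design of the asymptotic test), which is why the package reports
  the conventional asymptotic p that audit tables print rather than an
  exact p.

## Known limitations

* Arms are self-selected (visit acceptance); nothing here adjusts for
  that, matching the descriptive scope of a service evaluation.
* No multi-level regression on the CRCI; household-level means ± SD only.
* No inference (SEs/CIs) on the difference-in-difference.
* The demographic mixture is a plausible inner-city profile, not a fit
  to any register; per-service eligible fractions should not be read as
  predictions.
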