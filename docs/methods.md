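# Methods

This note documents the models, rules and defaults implemented in
`ohcm_burden`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not establish about real data.

## Study design emulated

A retrospective cohort of adults diagnosed with hypertrophic cardiomyopathy
in routine care, built from linked primary-care (CPRD GOLD/Aurum-like) and
secondary-care (HES-like) flat tables over a fixed study window
(1 April 2007 – 30 October 2020). The earliest admissible index date is
1 April 2009 so that a full 2-year baseline look-back fits inside the window.
Day convention: the index day is day 0 and all intervals are half-open
`[start, end)` on a day grid; person-years are exact day counts divided
by 365.25.

### Cohort rules

* **Index and cohort label.** Index = earliest in-window HCM diagnosis code.
  Any obstructive code forces the obstructive cohort with index at the
  earliest *obstructive* code, regardless of earlier non-obstructive codes;
  codes that do not specify obstruction pool with the non-obstructive cohort.
  Where several codes share a day, this rule also resolves the tie
  (obstructive > non-obstructive/unspecified).
* **Eligibility flags** (one per criterion; included iff all false): index
  before the admissible period; age <18 at index; <365 days of registration
  before index; research-quality and linkage-eligibility booleans (these are
  provider-determined in real extracts and therefore modelled as input
  columns, not computed); any exclusion-condition code *anywhere in the study
  period* (not just pre-index).
* **Attrition accounting** attributes each excluded patient to the first
  failing criterion in a fixed order, so counts partition the identified
  population exactly.
* **Baseline characterization.** Condition flags use a 730-day look-back
  inclusive of the index day; "active at baseline" prescriptions use a
  42-day look-back inclusive of the index day. The age-adjusted Charlson
  comorbidity index uses the classic weights restricted to the conditions the
  pipeline flags, plus one point per decade of age over 40 (capped at 4);
  the weight table is overridable.

## Proxy NYHA classification

Recorded NYHA codes are authoritative wherever they exist. Otherwise a
stepwise tree infers class from treatment and symptom coding. The published
description of this family of algorithms does not include the internal
branches, so the shipped default ruleset is this package's own, chosen to
reproduce the qualitative ordering (therapy intensity and symptom burden
increase with class) and validated by recovery tests rather than by claiming
any unpublished tree. Every parameter is config-overridable
(`NYHARuleset`, YAML-serialisable):

| parameter | default | meaning |
|---|---|---|
| medication window | day −2 … +28 from index | scripts that inform the baseline class |
| baseline symptom window | day −90 … +28 | symptoms that adjust the baseline class |
| daily grace period | 30 days | a product is active for days' supply + grace |
| daily symptom look-back | 90 days | rolling window for the adjustment |
| HF-hospitalization look-back | 90 days | secondary-care heart-failure code ⇒ class IV |
| symptom threshold | 2 distinct concepts | +1 class (capped at IV) |

Provisional class: heart-failure hospitalization in look-back → IV; ≥2
active agents, or disopyramide, or a loop diuretic → III; a single
β-blocker/CCB agent → II; otherwise I.

**Ratchet (asymptomatic correction).** Applied forward in time over the daily
series: a transition from class II+ to class I is blocked — the held class
persists — unless an intervention occurred strictly after the day the held
class was entered. The intervention set (configurable) is: coded septal
reduction therapy, ICD or pacemaker insertion, and the start of any new drug
exposure episode (therapy initiation, or within/between-class augmentation).
Improvement *within* the symptomatic range (e.g. III→II) is never blocked.
A recorded NYHA code during follow-up overrides the proxy from its date
until the raw rule-driven series next changes value. Day 0 of the corrected
trajectory carries the baseline classification.

## Treatment pathways

Exposure episodes per product: each prescription with positive days' supply
covers `[date, date+supply)`; episodes of the same product merge across gaps
of ≤30 days (grace, configurable — the source design fixes only the ≥90-day
no-treatment gap, so the grace value is this package's choice). Zero or
missing supplies are ignored; negative supplies are rejected with a warning.

The first treatment change is the earliest of (a) an exposure gap reaching
90 days, dated at the last exposure end (the earliest detectable point), and
(b) a regimen composition change, classified by set comparison of product
sets *F* → *T*:

1. *F* ⊂ *T* → **augment**; 2. *T* ⊂ *F* → **discontinuation**;
3. equal therapy-class multiset → **switch within class**;
4. |*T*| > |*F*| → **switch with addition**;
5. otherwise → **switch between classes**.

Rule 5 also absorbs cardinality-*decreasing* replacements
(e.g. {BB, CCB} → {disopyramide}), which no published category names; folding
them into between-class switching keeps the taxonomy total, which an
enumeration test over all product sets up to size 3 verifies. A ≥90-day gap
with the *same* regimen resumed is not a change. Cumulative risk of change is
1 − the Kaplan–Meier product-limit estimator (`lifelines`), cross-checked in
tests against a brute-force risk-set enumeration.

## Clinical outcomes

Event rules: chronic conditions are `first_only` (at most one event, the
earliest in-study code; with `incident_only`, patients with any pre-index
code contribute no event — the default, since in-study *incidence* is the
target); acute events are `repeatable` with a greedy 30-day deduplication:
a code is kept iff it is ≥30 days after the last *kept* code. The greedy
reading is a deliberate disambiguation of "codes ≥30 days apart count as
unique": it is deterministic, order-stable and idempotent.

Person-time splits along the time-varying NYHA trajectory; an event belongs
to the half-open interval containing its date. Rates are 100·*k*/PY per
stratum. The default interval estimate is the exact Poisson (Garwood) CI,
`[χ²(α/2, 2k)/2, χ²(1−α/2, 2k+2)/2]·100/PY`; an optional negative-binomial
intercept model with patient-level robust variance is provided. A
generalized-estimating-equation estimator with AR(1) working correlation is
intentionally *not* re-implemented: for unadjusted rates the point estimate
is identical and the difference is purely one of variance approximation,
which the method tag on every estimate makes explicit.

## Costing

Components: primary care (GP, nurse, telephone consultations; out-of-hours
visits are counted but excluded from costs), secondary care (outpatient, A&E
and critical-care activity at unit costs; elective/non-elective/day-case
episodes priced by HRG code), and tests/procedures (coded diagnostics at
unit costs). Non-inpatient costs are `count × unit cost × inflation factor`,
with a single multiplicative inflation uplift per run standing in for the
PSSRU index. Multi-day stays that span a NYHA change attribute their full
cost to the class at admission (the alternative — per-day slicing — is not
offered because no published analysis specifies it; the attribution point is
a config hook). Unknown HRG codes are dropped at £0 with a warning or raise,
per policy. All internals are unrounded; reported £/PY rounds half-up to the
nearest pound, percentages to 1 dp (2 dp for attrition).

## Disclosure control

Counts of 1–4 are primary-suppressed. If a row or column whose total is
shown retains exactly one suppressed cell, that cell is recoverable by
subtraction, so the smallest remaining shown cell is secondary-suppressed;
the rule iterates to a fixpoint. The exact secondary rule used for the
published tables is not stated anywhere public; this fixpoint rule is the
package's documented choice, property-tested for one-step
non-recoverability.

## Synthetic EHR generator

Each patient carries a latent NYHA path: a monthly (30-day-step) Markov
chain over classes I–IV. Monthly latent steps are a deliberate economy —
observations still carry exact dates, so the *daily* classifier is fully
exercised. Defaults are fixed once as the study conditions:

* demographics: age ~ N(61.0, 15.6²) years at diagnosis, 61.9% male,
  ethnicity mix ~79% white; 57.9% of patients obstructive;
* initial class distribution (0.259, 0.339, 0.377, 0.025) — the published
  baseline mix; the chain is progression-dominant (monthly stay
  probabilities ≈0.975–0.98, recovery to class I rare), so the class mix at
  index is shifted upward relative to the initial distribution, and the
  cohort drifts further toward II/III over follow-up;
* class-dependent monthly symptom-coding rates (0.02–0.45), therapy-set
  policies per class (none → BB → BB+CCB → combinations with disopyramide),
  clinical-event rates per 100 PY rising with class (e.g. stroke 2/4/8/20),
  activity rates per PY rising with class, and synthetic unit-cost/HRG
  tables;
* one global seed spawns per-patient `SeedSequence` children, so datasets
  are byte-reproducible and any patient can be regenerated alone;
* a class-dependent death hazard is available but off by default, keeping
  person-time accounting simple.

The generator also emits attrition fodder (short registrations, quality and
linkage failures, exclusion-condition codes, dual-coded non-obstructive→
obstructive patients) so the cohort stage has realistic work to do.

`rule_consistent_config()` defines the classifier-recovery conditions:
therapy deterministically encodes the latent class (I: none, II: BB,
III: BB+CCB, IV: BB+CCB plus a monthly secondary-care heart-failure code),
symptoms and background prescribing are off, and the chain never returns to
class I. Transitions are rare (monthly stay ≈0.99), leaving the
supply-plus-grace tail after a regimen step-down and the HF look-back tail
as the only disagreement sources — which is what the ≥95% person-day
agreement tolerance absorbs.

**What the synthetic data does not show.** The generator emulates the
*statistical shape* of a linked EHR extract, not UK coding practice: no real
code dictionaries, no coding inconsistency or missingness, no
under-ascertainment of mild disease, no GOLD/Aurum structural differences,
and prescriptions always carry clean days'-supply values. Passing recovery
tests therefore demonstrates that the pipeline's logic is faithful to its
stated rules and can recover known truths from rule-consistent data — not
that the proxy NYHA algorithm is clinically valid on real records.

## Problem sizes and test design

Property suites run on small randomized inputs against brute-force oracles
(risk-set enumeration for product-limit estimates, day-set unions for
exposure merging, forward replay for the ratchet, exhaustive enumeration for
the change taxonomy). Recovery experiments use cohorts of 2,000 patients
across three fixed seeds for rate recovery (checking the configured
class-I/class-IV rates of 2 and 20 per 100 PY fall inside the 95% CIs, with
estimates strictly ordered in class) and 300 patients for trajectory
recovery; these sizes give comfortably narrow CIs while keeping the whole
suite under a minute. Incidence recovery is evaluated against the latent
truth trajectory so that estimator error is not confounded with classifier
window-edge lag; classifier fidelity is tested separately.

## Known limitations

* The proxy NYHA tree is a configurable stand-in validated by recovery, not
  a clinically validated instrument.
* Dose changes are invisible (no dose field is modelled), so within-product
  titration never registers as a treatment change.
* The no-treatment gap is assessed across all HCM-specific classes jointly
  (a per-class reading is possible but not implemented).
* No competing-risks estimators, covariate adjustment, cause-of-death
  decomposition, or discounting/currency conversion.
* CSV is the only on-disk format; tables are small enough that columnar
  formats add nothing here.
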