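# Methods

## Scope and unit of analysis

`ichd3kit` classifies *single headache attacks*, not patients. ICHD-3 was
written to diagnose disorders, which requires attack counts over time
(criterion A) and exclusion of other diagnoses (criterion E); neither is
observable in one diary entry. The package therefore operationalizes the
attack-level core (criteria B–D for migraine 1.1 and tension-type headache
2.x, definite and probable) and replaces A and E by explicit stand-ins:

* **Criterion A** — two boolean history flags (`has_migraine_history`,
  `has_tth_history`) that gate the *probable* diagnoses in the cascade.
  Both default to true, the setting of a diary population already under
  care. Definite diagnoses are not gated.
* **Criterion E** — a short-duration rule: attacks shorter than
  `short_duration_h` (default 0.5 h) are marked NOT_CLASSIFIABLE with a
  dedicated flag, because the differential for very short attacks
  (trigeminal autonomic cephalalgias, other primary headaches) cannot be
  resolved from diary data. TACs and secondary headaches are out of scope by
  design.

## The decision cascade

The cascade order is the unique order consistent with the clinical rules it
encodes: (1) triptan response ⇒ migraine, checked first so a successfully
aborted short attack is still counted as migraine (the 4–72 h window applies
only to untreated or unsuccessfully treated attacks, which is also why a
positive triptan flag waives migraine criterion B); (2) the short-duration
rule; (3) definite migraine before (4) definite TTH (hierarchy: migraine
before TTH; definite trumps probable); (5) probable migraine with a migraine
history before (6) probable TTH with a TTH history; (7) otherwise
NOT_CLASSIFIABLE. With neither history, a merely probable attack is
NOT_CLASSIFIABLE.

Probable status means *exactly one* of B/C/D fails, independent of the
margin of failure: in particular an attack whose C count is 0 but whose B
and D hold is probable. Getting this wrong (requiring at least one C item)
is a known failure mode of strict rule coding and is covered by a regression
property test.

MA semantics: the aura flag selects MA over MO only when the event
classifies as migraine through the cascade; aura alongside a TTH or
not-classifiable outcome does not force MA. The diary records aura as a
single yes/no answer, so no aura sub-characteristics are modelled.

Non-triptan medication has no effect on any criterion; the triptan flag is
three-valued and an absent value is treated as "no positive evidence", so
the triptan rule fires only on an explicit true.

## Pain intensity

The diary collects pain on the 0–10 numeric rating scale; ICHD-3 speaks in
verbal categories. The mapping 0 → none, 1–3 → mild, 4–6 → moderate,
7–10 → severe is total and monotone. Note one deliberate asymmetry it
induces: migraine's "moderate or severe" C item is monotone non-decreasing
in NRS over the whole scale, while TTH's "mild or moderate" item is
non-monotone at the none→mild boundary (0 has no item, 1 does). Monotonicity
properties are therefore asserted over the observed pain range 1–10.

## Agreement statistics

Two raters' labels over the four categories (MO, MA, TTH, NOT_CLASSIFIABLE)
are cross-tabulated and summarized by unweighted Cohen's kappa. The standard
error is the large-sample asymptotic variance *not* assuming chance
agreement (Fleiss, Cohen & Everitt 1969) — the variant standard statistical
packages print — computed via `statsmodels`; the interval is the two-sided
Wald interval κ ± z·SE truncated to [−1, 1]. The H0-based SE is not
computed. Descriptive bands are half-open and gap-free ([0.40, 0.60)
moderate, [0.60, 0.80) substantial, [0.80, 1] excellent): the conventional
printed ranges (0.40–0.59, 0.6–0.79, > 0.80) leave (0.59, 0.60) and
(0.79, 0.80] undefined, and left-closed bands are the only total,
order-consistent completion. Weighted and multi-rater kappas are non-goals.

The bundled fixture `data/validation_confusion.csv` holds the reference
validation cross-tabulation (n = 102 attacks, specialist rows × algorithm
columns); it reproduces κ = 0.742, SE = 0.058, 95 % CI [0.628, 0.856].

## Synthetic diary generator

The generator exists so the whole pipeline is testable without access to any
clinical database. It emulates the *marginal* structure of a real diary
sample: symptom-flag frequencies (pulsating 0.46, pressing 0.54, one-sided
0.56, both-sided 0.44, aggravation 0.38, aura 0.18, vomiting 0.02, nausea
0.25, phonophobia 0.33, photophobia 0.44, medication 0.41), mean pain 4.8/10
(sampled as 1 + Binomial(9, p) on 1–10; 0 is reserved for "no pain"), and a
log-normal duration model truncated to [0.2 h, 102.5 h] — 12 minutes to
4 d 6.5 h — whose *truncated* mean is calibrated to 13.5 h by solving for μ
at fixed log-σ = 1.1 (the shape of the true duration distribution is
unknown; log-normal is this package's choice and is configurable).

Independent flag draws at those marginals almost never assemble a definite
diagnosis, so label structure is driven by **archetypes**
(definite_MO/MA/TTH, probable_MO, probable_TTH, short_duration, ambiguous).
Each targeted archetype proposes an event biased toward its diagnosis
(e.g. duration drawn from the criterion-B window conditioned on the base
duration model, C items topped up to two, D forced or suppressed; probable
archetypes pick one criterion to fail, including the C-count-0 route) and
then *verifies* it against the actual rule engine, resampling until the
event classifies to the archetype's target label with the right certainty
and provenance — the construct-then-verify contract. The `ambiguous`
background archetype draws everything independently at the configured
marginals (quality and laterality pairs are sampled as complements, which is
how the paired frequencies behave) and adopts the classifier's own label as
its truth.

Default archetype weights (0.22 / 0.08 / 0.15 / 0.20 / 0.10 / 0.05 / 0.20)
were chosen once to echo the validation sample's composition — an
algorithm-side label mix near 59 MO : 15 MA : 27 TTH : 1 NC per 102 and a
probable-based share near 38 % — and are not tuned thereafter. The triptan
flag is assigned (rate 0.5 among medicated events) only in the
definite-migraine and ambiguous archetypes: in TTH, probable or
short-duration archetypes a positive triptan flag would flip the target
label or its provenance and defeat the archetype contract.

The noisy-rater simulator replaces each true label independently with
probability `error_rate` by a uniform draw over the three other categories —
a deliberately memoryless error model for inadvertent rater mistakes.

What passing tests on synthetic data do **not** show: the generator models
no within-patient correlation, circadian timing, trigger factors, missing
answers, or the systematic (non-uniform) confusion patterns of human raters,
so agreement levels measured on synthetic diaries characterize the
machinery, not expected field performance on real diaries.

## Numerical and interface choices

* Timestamps are naive local clock times; duration = end − start in
  fractional hours. Generated durations are rounded to whole minutes.
* Duration windows are closed intervals; the short-duration rule uses a
  strict `<` so a 30-minute attack is a valid TTH candidate. The
  configuration validator enforces `short_duration_h ≤` the lower TTH bound.
* Boolean CSV encoding is "1"/"0" on write, with "true"/"false"/"yes"/"no"
  accepted case-insensitively on read; the unknown triptan state is an empty
  cell. Validation is total: malformed fields are rejected with row number
  and field name, never coerced.
* The degenerate kappa case p_e = 1 raises instead of returning NaN; the
  asymptotic variance is clipped at 0 before the square root to absorb
  round-off at κ = 1.
* Resampling in the generator is capped (`max_resample`, default 1000
  proposals per event) and raises if an archetype cannot be satisfied under
  a custom rule configuration.

## Problem sizes

Property suites use an exhaustive grid of all 576 valid symptom-flag
combinations × 9 durations × 4 NRS values (~21k events) against an
independently written brute-force oracle; generator/classifier consistency
is checked on 5 000 seeded events; marginal calibration on 10 000; the
asymptotic SE is validated against a 10 000-replicate nonparametric
bootstrap on a seeded 102-pair sample, and chance-level kappa on 10 000
random label pairs.

## Known limitations

* The classifier inherits the diary's limits: a yes/no aura question (no
  aura characteristics), no medication type beyond the triptan flag, no
  patient-level context. It classifies attacks; it does not diagnose
  patients.
* All-flags-required schema: the package defines no missing-data policy
  beyond the triptan flag.
* The history gating of probable diagnoses is a modelling choice for
  criterion A, not a clinical validation of it.
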