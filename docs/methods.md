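# Methods

This note documents the models, rules, and design choices behind
`smokereg`, in the spirit of a statistical software vignette. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Smoking behaviors live in two places in an EHR: coded ("semi-structured")
fields — status drop-downs and occasional pack-year entries — and free-text
clinical notes. A smokers' registry merges both into one record per patient
so that cessation services and lung-cancer-screening outreach can be driven
from data rather than chart review. The package implements the extraction,
merging, and eligibility layers, plus the agreement statistics used to
validate such a registry against an external questionnaire treated as the
reference standard.

## Status classification

A note is classified at the document level. Tokens whose prefix matches a
hotspot root (`smok`, `cig`, `tobac`, `nicoti`) anchor windows of up to
five tokens each side; all windows are concatenated and the result is
classified by a one-vs-rest linear SVM over binary unigram presence
(bigrams behind a flag). Four labels are learnable — current, former,
smoker-temporality-unknown, never; *unknown* is never a model output. It is
assigned by rule when a note has no hotspot, because such a note contains
no smoking information to classify. This makes the no-information rate of a
corpus a deterministic function of the text, independent of training.

Choices the underlying approach leaves open, and what we chose:

* **Prefix vs. substring root matching.** Prefix, so `cig` cannot fire
  inside unrelated words and `nonsmoker` is not a hotspot; substring is a
  config switch.
* **Window units.** Tokens after punctuation-splitting tokenization (the
  window is word-based, not character-based).
* **Vectorization and multi-class scheme.** Unstated upstream; binary
  unigrams and one-vs-rest are the minimal standard choices. Ties in the
  decision scores break toward the higher-risk label.
* **Regularization** C = 1.0; seed default 20160401. Training is
  deterministic given seed and input order.

## Pack-year extraction

Sentences are split on `.!?` and newlines with guards for decimals, single
letters (dotted abbreviations like `b.i.d.`), and common clinical
abbreviations (`pt.`, `hx.`, ...). A sentence is a pack-year candidate iff
it contains a stem from `cig, smok, pack, pak, pkyr` (token-prefix) or
`pk, ppd` (exact token — short stems are high-risk substrings). Numbers are
parsed as numerals, decimals, simple fractions (`1/2`, "half"), and spelled
numbers up to one hundred; values above 200 are discarded as dates or lab
values.

Interpretation: two usable numbers ⇒ frequency × duration product, with
cigarette frequencies divided by 20 (one pack = 20 cigarettes); where unit
cues are absent, frequency is assumed to precede duration, and cues win
when present. One number ⇒ routed by its adjacent cue to a stated pack-year
total, frequency-only, or duration-only; the latter two carry no pack-year
value (reporting a bare "1 ppd" as 1 pack year is precisely the error the
low-value filter exists for). An explicit stated total outranks other cued
numbers in the same sentence. Unparseable sentences yield nothing rather
than a guess.

The **low-value filter** drops stated totals below a cutoff (default 5,
the lower end of the plausible 5–15 range for this heuristic; config
exposes it). Computed products are exempt: when both components were
observed, a small product is evidence, not misclassification. The
document-level value is the maximum over surviving full findings,
mirroring the cross-source keep-the-highest rule; whether the original
upstream implementation used maximum, first, or last is unknown, and
maximum is our documented choice.

## Cessation dates

Quit sentences are those with a `quit`/`stop` token prefix or an exact
`qd`, additionally required to contain a smoking hotspot root. The gate is
our addition (toggleable): without it, medication text ("stop aspirin",
"metoprolol 25 mg qd") dominates the findings. Dates are normalized at
their native resolution — full dates to the day, month + year to the first
of the month, bare four-digit years to January 1. Relative phrases ("quit N
years/months ago") resolve against the note date. Two-digit years are
rejected (ambiguous century), as is any date after the note date. When a
note carries several quit dates, the most recent is kept, since the latest
cessation governs screening windows.

## Merging and eligibility

Status merging is the maximum under the total order current > former >
smoker-temporality-unknown > never > unknown (hence commutative,
associative, idempotent); pack-year merging is the maximum of present
values. Screening eligibility requires a smoker status and ≥ 30 pack years
(the threshold is inclusive; both "greater than 30" and "30 or more"
readings circulate, and the screening guideline itself is inclusive —
config allows strict). Former smokers must have quit within 15 years of the
reference date; when no cessation date exists, `assume_recent_quit`
(default on) treats them as recently quit, which is the stance forced on
any validation against a questionnaire that records no quit dates. A
documented smoker of unknown temporality is treated as a smoker and handled
like a former smoker with no quit date. Unknown status and missing pack
years produce explicit missing-data verdicts with machine-readable reasons.

## Agreement statistics

Implemented directly from the definitions (and cross-checked in the tests
against a brute-force double summation and against scikit-learn): weighted
kappa with w_ij = 1 − (|i−j|/(k−1))^q, q = 1 linear, q = 2 quadratic
(Fleiss–Cohen), identity weights for the unweighted case. On any 2×2 table
the three schemes coincide. Confidence intervals use the large-sample
standard error of weighted kappa (Fleiss–Cohen–Everitt) with normal
quantiles, clipped to [−1, 1]; other CI constructions exist and printed
intervals from other software may differ in the second decimal.

### Shipped validation tables and reconstructions

`smokereg/data/validation_tables.json` carries the published
cross-tabulations from an external-questionnaire validation of a registry
built this way (n = 1,504). Three analysis restrictions are reconstructions
— the published report states the results but not the exact analysis sets —
and each is pinned by arithmetic:

* the multi-class analysis drops the unknown EHR column (1,101 records) and
  the three smoker-temporality-unknown records, since 1,504 − 1,101 − 3 =
  400 and only this set reproduces the printed 67.8% concordance; on it,
  **quadratic** weights (ordering current < former < never) reproduce the
  printed weighted kappa 0.62, while linear weights give 0.56;
* the ever/never analysis drops only the unknown column (n = 403), folding
  smoker-temporality-unknown into *ever*; this reproduces 83.6% concordance
  and unweighted kappa 0.59;
* the 74-record current-smoker comparison is reported as 52 concordant and
  71.2%, but 52/74 = 70.3%; setting aside its single
  smoker-temporality-unknown record — the same exclusion as the n = 400
  analysis — gives 52/73 = 71.2%, which is the computation implemented.

## Synthetic data

The generator's defaults are the validation study's observed conditions:
status mix 247/614/643 (current/former/never out of 1,504), 27% of notes
informative, semi-structured status for 222/1,504 visits with pack years on
67/222, and 96/861 smokers declining the questionnaire's quantity
questions. Smokers draw 0.5–3 packs/day (half-pack steps) and 10–50 years
smoked — realistic for a 50–80-year-old screening cohort and implying at
least 5 pack years, so gold values are never artifacts of the low-value
filter. Former smokers quit 1–30 years before the note date. The
questionnaire is error-free ground truth by default (the validation
design's assumption; a noise parameter exists for sensitivity analyses),
and semi-structured status disagrees with gold at rate 0.05 to exercise the
worst-label merge.

Three template sets control difficulty: *unambiguous* (one clear cue per
class; quantities round-trip exactly), *varied* (hedged clinical
shorthand), *adversarial* (trap-adjacent wording). Distractor injection
appends the classic false-positive sentences — "if you currently smoke...",
"stop aspirin...", "metoprolol qd", "packed red blood cells" — which must
never change gold labels. Everything derives from one `numpy` generator, so
equal seeds give byte-identical corpora.

**What passing tests show, and what they do not.** The generator emulates
surface variety, missingness, and the trap phrases, but not real clinical
notes: no negation chains, templated grammar, no OCR noise, no contradictory
longitudinal history. Recovery rates ≥ 0.95–0.99 on unambiguous synthetic
corpora demonstrate that the rules implement their specification exactly;
they do not predict real-note performance, where agreement with an external
questionnaire has been observed in the 0.56–0.62 kappa range.

## Problem sizes and numerics

The acceptance script uses 2,000-patient corpora and a 480-example training
set (120 per class), sizes at which every rate of interest is estimated to
within ~1% and the whole run takes seconds. Pack-year "exact" recovery uses
an absolute tolerance of 1e-9 (values are products of half-steps and
integers, exact in binary floating point). The kappa oracle comparison runs
at 1e-12. Degenerate inputs — empty tables, single-class training sets,
zero-variance correlations, zero denominators in screening metrics — raise
or flag explicitly rather than returning silent NaNs.

## Known limitations

* Single-note scope: no reconciliation of contradictory histories across a
  patient's notes (cross-sectional design).
* No temporal scoping of pack-year statements (past vs. present rates).
* The single-number interpretation rules and the quit-sentence smoking
  gate are documented reconstructions of under-specified behavior, exposed
  in config rather than asserted as ground truth.
* Age-band gating for screening eligibility is out of scope (cohorts are
  assumed pre-restricted); `qd` as once-daily collides with the quit cue by
  design and is handled only by the smoking-root gate.
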