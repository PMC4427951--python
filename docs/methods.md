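# Methods

This note documents the models, rules and parameter choices behind
`medrec`, the assumptions they encode, and what the synthetic experiments
do and do not demonstrate.

## Problem setting

One hospital encounter yields (a) free-text clinical notes — problem
overview notes and a discharge summary — and (b) a structured discharge
prescription list with name, generic name, instruction, route, frequency,
strength, form and order/start/end dates.  The task is note→list
reconciliation: every medication *mentioned in the notes* must either be
matched to a prescription (name and attributes consistent) or flagged
discrepant.  The reverse direction is deliberately not attempted:
prescription lists legitimately contain medications ordered by providers
whose notes are not in the collection, so list→note comparison would
manufacture false discrepancies.

## Process 1 — entity detection

**Tokenizer.**  A rule tokenizer splits on whitespace and at
letter/digit/punctuation boundaries; decimal numbers (`2.5`) stay intact;
each punctuation character is its own token.  Offsets always index the
original note, so predicted spans can be compared to gold annotations
character-for-character.

**Labels.**  BIO tags over the eight categories (17 labels).  A token
belongs to a span when its midpoint lies inside the span, so spans that
cut a token still cover it.

**Model.**  A first-order linear-chain CRF implemented in the package:
binary indicator features feed an emission weight matrix, plus dense
transition and start-weight vectors.  Training minimizes the
L2-penalized negative log-likelihood with L-BFGS; gradients come from a
scaled (normalized) forward–backward pass that is batched across all
training sequences per iteration, which keeps ten-fold cross-validation
on the default corpus under a minute per fold.  Decoding is Viterbi with
hard BIO masks (`I-x` reachable only from `B-x`/`I-x`), so every decode
is structurally valid whatever the weights.  Training starts from zero
weights and L-BFGS is deterministic, so a fixed corpus always yields the
same model; the recorded seed is bookkeeping, not a randomness source.

Defaults: L2 penalty `c2 = 0.1`, at most 100 L-BFGS iterations, minimum
feature count 1.  These are mild, generic settings for small indicator
CRFs; the synthetic task is not sensitive to them, and they are exposed
via `CRFParams` for larger corpora.

**Features** per token: lowercased form, shape class
(digit/upper/capitalized/lower/mixed), digit flags, punctuation class,
2–3 character prefixes/suffixes, an optional POS tag (a null `UNK`
tagger is supported so the pipeline carries no heavyweight parser
dependency), lowercased context tokens at offsets −2…+2 with boundary
sentinels, and gazetteer flags: membership of the token in the drug
lexicon's description terms or in small unit/route/form/frequency
tables.  The gazetteer flags play the role that concept-extractor output
(dictionary evidence) plays in a full clinical deployment; here the drug
lexicon is the only dictionary, which keeps the package self-contained.

## Process 2 — attribute linkage

Each attribute span is linked to the medication-name span with the
smallest **interval gap** (`max(0, max(starts) − min(ends))`; overlap =
0), whether the name precedes or follows the attribute.  "Absolute
character distance" admits several readings (midpoints, start offsets);
the interval gap is the most literal and is the stated contract here.
An attribute exactly equidistant between two names goes to the
**preceding** name — dosing attributes conventionally follow the drug
they modify.  Attributes in a note with no medication name at all are
retained in a diagnostic `unlinked` list rather than dropped.

Linkage never creates or destroys medication names, so medication-name
recall is passed through this stage unchanged — a structural identity
that the evaluation asserts rather than measures.

## Process 3 — medication matching

The cascade tries four steps strictly in order, stopping at the first
success; disabling steps 2–4 can therefore only reduce the matched count
(monotonicity, asserted in tests).

1. **Substring.**  The lowercased, whitespace-collapsed mention is equal
   to or a substring of the prescription name (or vice versa), then the
   same against the generic name.  Only the name span is compared —
   attributes are not appended.  This is intentionally naive
   bag-of-string matching: `prednisolone` does match
   `methylprednisolone 4 mg tab`, a documented failure mode that is kept
   reproducible rather than patched.
2. **Pair memory.**  Term sets are extracted from mention and
   prescription name (lowercase alphabetic tokens minus numbers, units,
   form/route/frequency stop words and hyphen/dash/slash delimiters; the
   stop table ships as `data/stop_tokens.txt`).  If the pair of term sets
   was observed as a gold match in the *training folds*, the pair
   matches.  The memory is built per fold from training data only; a
   leakage audit asserts test-fold-only pairs never appear.
3. **Description co-occurrence.**  A mention term and a prescription
   term occurring in one lexicon description are treated as probable
   synonyms.  All entry types are searched.  This inherits the known
   false positive that two *ingredients* of one combination product
   (e.g. glycerin / polyethylene glycol in an artificial-tears entry)
   also "co-occur"; the behavior is kept and unit-tested.
4. **Trade name.**  Mention and prescription are mapped to lexicon codes
   by bag-of-words containment between term sets and entry terms; a
   trade-name/generic relation between any mapped code pair matches.

When several prescriptions match at the same step, the one with the
longest common substring with the mention wins; remaining ties keep
prescription-list order.

**Attribute comparison.**  Attributes of a matched medication are
compared to the prescription field of the same category (route,
frequency, strength, form), after normalization: lowercase, punctuation
stripped (decimal points preserved), digit/letter boundaries split
(`5mg` → `5 mg`), unit synonyms collapsed via
`data/unit_normalization.tsv`.  A comparison succeeds on equality or
contiguous token containment in either direction.  Amount and dosage
have no structured field and are compared against the instruction text;
duration is compared against a string synthesized from start/end dates
(`for N days`) when both are present, else the instruction.  No semantic
inference is performed — `AM` never matches `twice a day`, and
dose-per-administration is never converted to dose-per-day; these are
deliberate fidelity limits, not oversights.  An attribute whose
counterpart field is blank is labeled discrepant (and is the main
divergence risk of the string-comparison design).  A route mismatch does
*not* void the name match by default; the stricter rule is available as
`MatchConfig(route_must_match=True)`.

A medication lands on the discrepant list when the cascade failed **or**
any linked attribute is discrepant.

## Evaluation protocol

* Token-level P/R/F for detection and linkage (B/I collapsed to the
  category; O excluded), span-level exact-boundary matching elsewhere —
  partial credit is undefined in the protocol, so exact is used.
* Matched-medication true positives require the system's prescription to
  equal the annotators'.  Matched-attribute true positives additionally
  require that prescription agreement.  Discrepant-side true positives
  require both sides to say discrepant.
* Zero-denominator convention: a precision or recall with denominator 0
  is reported as 1 (nothing predicted/expected, nothing wrong).  Real
  corpora never hit this; synthetic edge cases do.
* Ten-fold cross-validation splits at the encounter level, stratified by
  quartiles of each patient's total note count and dealt round-robin
  within quartile bins, deterministically for a fixed seed.  The tagger
  and the pair memory are rebuilt per fold from the nine training folds.
* Recall propagation reports, per note type, the recall of
  gold-discrepant medications after each stage: exact name-span
  detection, survival through linkage (equal to detection by
  construction), and final discrepant-bucket placement.

## Synthetic corpus

The generator emulates the *structure* the algorithm depends on, not
clinical prose.  Notes are templated ("Continue <name> <strength> <form>
<route> <frequency>, take <amount> <dosage> <duration>." and bulleted
discharge-medication lists) with distractor sentences between mentions,
so gold offsets are exact by construction and the nearest-name rule
provably reproduces gold attribute groupings on clean text (the
inter-mention separators are longer than the largest possible
name-to-attribute gap).  Drug names are pseudo-names built from
syllables and filtered to be substring-free, so substring matching is
unambiguous by design; a handful of real entries (diastat/diazepam, the
ipratropium–albuterol combination, artificial tears,
methylprednisolone/prednisolone, amoxicillin clavulanate) is embedded in
the lexicon to exercise the cascade's documented behaviors in unit
tests.

Default conditions: 30 patients × 1–3 encounters, 1–2 overview notes and
one discharge summary per encounter, 4–8 medications per encounter (all
on the discharge summary, 1–3 per overview note), attribute inclusion
probabilities proportional to the reference corpus's category
frequencies (frequency 0.73 … duration 0.09), and a **7.5% per-medication
discrepancy rate** split evenly between missing-prescription and
attribute-mismatch injections.  Missing-prescription deletes the
prescription and relabels all of the medication's mentions (and their
attributes) discrepant; attribute-mismatch perturbs exactly one
structured field (route, frequency, strength or form) to a different
catalog value.  Brand names are used as the mention surface 15% of the
time, exercising cascade steps 3–4 even on clean text.  Abbreviation
(5%) and misspelling (3%) noise is applied to overview notes only,
mirroring the observation that discharge summaries written through
structured medication pickers use a more controlled vocabulary; the
abbreviation of a drug is stable across the corpus, so pair memory can
learn it from training folds.

What passing synthetic tests shows: the implementation of all three
processes and the evaluation machinery is internally correct (the
noise-free oracle recovers injected discrepancies with P = R = 1), and
the pipeline degrades in the qualitatively expected way under noise
(discrepant precision falls first; overview-note recall trails
discharge-summary recall).  What it does not show: performance on real
clinical language — real notes have abbreviations, misspellings and
formulation variants far beyond the template vocabulary, and published
results on real corpora are correspondingly lower.

Problem sizes used by the shipped experiments: the oracle run generates
≈500 encounters (250 patients, noise-free); cross-validated parameter
recovery uses the 30-patient default corpus (≈140 notes, ≈480 mentions).
These sizes were chosen so the whole suite runs comfortably on a
single CPU while keeping every fold statistically non-trivial.

## Numerical and degenerate-input choices

* Character offsets are 0-based, half-open everywhere.
* Empty notes tokenize to empty sequences and decode to no spans; empty
  prescription lists make every mention discrepant (not an error).
* The forward–backward pass shifts per-token score rows and the
  transition matrix by their maxima before exponentiation, so training
  is stable for arbitrarily confident weights.
* `F = 0` when `P + R = 0`; `fvalue` rejects inputs outside [0, 1] to
  catch accidental percent-scale arguments.
* Serialized tagger models embed a feature-template version string and
  refuse to decode under a mismatched template.

## Known limitations

* Bag-of-words matching cannot separate combination products from their
  components (albuterol vs ipratropium–albuterol) or near-identical
  names (prednisolone vs methylprednisolone); both failure modes are
  reproduced and tested rather than fixed.
* Attribute comparison is purely lexical; semantically equivalent doses
  and schedules are labeled discrepant.
* The lexicon dialects cover descriptions, term sets and trade
  relations only — no ingredient hierarchies or license-encumbered
  vocabularies.
* The synthetic generator's template grammar makes entity detection
  easier than on real text; token-level F on the default corpus
  (≈0.95) should be read as an implementation check, not a clinical
  performance claim.
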