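# Methods

## The extraction model

`rdocnlp` implements dictionary-anchored sentence classification. Two
curated artifacts define the label space:

* a **keyword dictionary** mapping each of the six RDoC domains
  (negative valence, positive valence, cognitive, arousal/regulatory,
  social processes, sensorimotor) to a set of lowercase keyword phrases of
  one to six tokens; a phrase may appear under several domains ("stress"
  is both negative-valence and arousal/regulatory in the demo dictionary);
* a **sentence dictionary** of exemplar sentences, each labeled with one
  domain and guaranteed (enforced at load) to contain at least one
  keyword.

A note sentence is annotated in two stages. The *keyword gate* restricts
the comparison set to exemplars sharing at least one keyword phrase with
the sentence; sharing is decided by token-boundary, case-insensitive
phrase matching (tokens are maximal alphanumeric runs, so "art" never
matches inside "heart"; matching is greedy left-to-right with the longest
phrase preferred, so "panic attacks" shadows "panic"). The *semantic
stage* embeds the sentence and all gated exemplars with a pluggable
backend and selects the exemplar with maximal cosine similarity; ties go
to the smallest exemplar id for determinism. The match is accepted as an
RDoC instance iff its score reaches the threshold θ; the sentence then
carries the matched exemplar's domain. One annotation is produced per
sentence regardless of how many keywords it contains — the best match,
not one match per keyword. Because the argmax does not depend on θ, the
matched exemplar is recorded even for rejected sentences, which makes
threshold sweeps exact replays rather than re-computations.

Domain assignment flows through the matched *sentence*, never the keyword
itself; this is what lets ambiguous keywords live in several domains
without a disambiguation rule.

### Assumptions and known limitations

* **No negation or uncertainty handling**: "denies panic attacks" matches
  exactly like "reports panic attacks". This mirrors the gate-and-match
  design itself, which has no linguistic analysis beyond tokenization;
  on real notes this inflates instance counts for frequently-negated
  symptoms.
* Single-label per sentence: a sentence mentioning fear and poor sleep
  contributes one instance (its best match), not two. The per-exemplar
  score table is exposed (`DictionarySentenceMatcher.gated_scores`) for
  debugging multi-domain sentences.
* The shipped demo dictionaries (~50 keywords, 60 exemplars) are synthetic
  illustrations assembled from construct vocabulary common in the PTSD
  literature (acute/potential threat, anhedonia, craving, hyperarousal,
  psychomotor change, ...). They are not clinically validated; any real
  deployment must supply its own dictionaries, which the loaders validate
  (all six domains present, every exemplar keyword-bearing, ids strictly
  increasing).

## Embedding backends

The backend contract is minimal: a name, a fixed output dimension, and an
order-preserving, neighbor-independent `embed_batch`. The matcher touches
backends only through pairwise cosine similarity, so they are freely
substitutable.

* **Hashing embedder (default, offline).** Character n-grams (n = 3..5) of
  the lowercased, whitespace-collapsed, space-padded sentence are hashed
  with BLAKE2 into 256 signed buckets (signed hashing trick) and the
  result is L2-normalized. It is deterministic across processes and
  platforms (no environment-dependent hash salting) and needs no model
  files. Character n-grams make near-paraphrases (word dropout, inflection
  changes) score high while lexically disjoint sentences score low — the
  separation the matcher needs.
* **Pretrained backend (optional).** A wrapper around a
  sentence-transformers model, default the 768-dimensional
  `all-mpnet-base-v2`, used as published without fine-tuning. Its absence
  raises a targeted error and affects nothing else.

Cosine of a zero vector (e.g. the hashing embedding of an empty string) is
defined as 0 with a warning rather than an error, keeping the pipeline
total. Exemplar embeddings are computed once at `fit` and row-normalized;
candidate scoring is a matrix product over the gated rows.

## Threshold calibration

Gold labels are sentence-level: `(note_id, sent_index) -> domain or
"none"`. Scoring is one-vs-rest per domain — tp: accepted with the gold
domain; fp: accepted with gold "none" or another domain; fn: gold domain
sentence not covered by a matching accepted annotation — with the 0/0 → 0
convention for precision, recall and F1. The selection objective is
**macro F1 over the six domains**; the "none" class is never averaged in
(micro F1 is reported for reference only). The default grid is 0.05 to
0.95 in steps of 0.05; ties select the smallest threshold, preferring
recall. Because matches are θ-independent, the sweep computes similarities
once and replays the acceptance rule per grid point; a property test
verifies the sweep equals an independent full re-run.

On the shipped calibration fixture the hashing backend selects θ ≈ 0.40
with every per-domain F1 ≥ 0.99. The pretrained backend's published
operating point for this task family is θ = 0.3; `MatcherConfig` defaults
to 0.3 but every experiment in this repository passes the
hashing-calibrated value explicitly. θ is always configuration, never a
constant baked into the matcher: other dictionaries or backends will
calibrate differently.

## Cohort statistics

Patient profiles aggregate accepted annotations into per-domain counts;
cohort **prevalence** of a domain is the fraction of patients with at
least one instance (mean counts are also available — prevalence was chosen
as the primary scale because patient-level flags are robust to a few
highly verbose charts). Two cohorts are compared by their six paired
per-domain prevalences with an **exact Wilcoxon signed-rank test**: zero
differences dropped, |differences| ranked with midranks, W = sum of ranks
of positive differences, and the null distribution built by enumerating
all 2^n sign assignments of the realized ranks. This tie-respecting
permutation null was chosen over the classical no-tie tables because
prevalences at n = 6 tie often. The two-sided p is
P(|W* − μ| ≥ |W − μ|), μ = n(n+1)/4. With six non-zero same-sign
differences the test attains its floor, p = 2/2⁶ = 0.03125 — the value a
six-domain "consistent increase/decrease" comparison reports. Enumeration
is vectorized and capped at n = 20 (the test is for small paired designs;
n > 20 should use a large-sample method instead).

p-values that are not multiples of 2⁻⁶ cannot arise from this design at
n = 6; comparisons reported elsewhere with such values must come from a
different (unspecified) procedure and are out of scope here.

Trajectory tables anchor each patient at an index event date and count
accepted instances in **half-open calendar-year windows**: a w-year window
contains annotations with index ≤ date < index + w years (pandas
`DateOffset`, so "1 year" respects leap years). Windows are cumulative and
therefore monotone; patients lacking the index event are excluded and
counted. The pre/post psychotherapy split assigns a patient's annotations
dated before the psychotherapy start to "before" and on/after it to
"after", so one patient can contribute to both periods.

## The synthetic corpus generator

Real clinical corpora cannot ship with the package, so every experiment
runs on generated notes whose statistical structure matches what the
analyses assume. Three sentence populations:

* **Plants** (per-domain base rate 0.05 per sentence): exemplar sentences
  with paraphrase noise — word dropout (p = 0.10), synonym substitution
  from a small editable TSV map (p = 0.20), and an appended filler clause
  (p = 0.15). Perturbation never drops or rewrites keyword tokens, so the
  gate always remains satisfiable — by construction, as in the curated
  dictionaries, a domain sentence contains its keyword.
* **Distractors** (rate 0.10): a random dictionary keyword slotted into an
  administrative template ("A billing code related to {kw} was added...").
  They pass the gate but sit far from every exemplar in embedding space,
  creating the low-similarity mode that makes threshold calibration
  non-trivial. Labeled "none".
* **Filler** (remaining mass): keyword-free boilerplate, labeled "none",
  never even becomes a candidate.

Patients carry gender (p(F) = 0.5), veteran status (p = 0.25), and
optional event dates (first PTSD diagnosis p = 0.9, SRE p = 0.3, ASUD
p = 0.4, psychotherapy start p = 0.4) drawn uniformly over a six-year
study window; notes (2–5 per patient, 4–8 sentences) get uniform dates.
Cohort effects are multiplicative on plant rates: female ×1.6 (all
domains), veteran ×1.4 (the two valence domains), psychotherapy ×0.5 for
notes on/after the start date, and ×1.5 after the first PTSD diagnosis.
These defaults produce the qualitative structure the cohort analyses
probe — an all-domain gender effect, a valence-specific veteran effect, a
consistent post-psychotherapy decrease, rising post-diagnosis counts — at
magnitudes recoverable from a few hundred patients. Sentences are
newline-joined so the rule-based segmenter recovers exactly the generated
boundaries; gold keys are `(note_id, sent_index)` and a test asserts the
alignment.

The **calibration fixture** is 1,200 labeled sentences — 150 perturbed
plants per domain plus 150 distractors and 150 fillers — standing in for
an expert-annotated gold sample. The class histogram is exact by
construction.

What the generator does *not* emulate: real clinical language (telegraphic
style, misspellings, section headers), negated mentions, de-identification
artifacts, correlated symptoms within a patient, and non-uniform visit
patterns. Passing tests therefore demonstrate the pipeline's mechanics —
gating, matching, calibration, statistics — not clinical-grade extraction
accuracy; the reported F1 values describe the synthetic fixture, not
hospital notes.

## Numerical and design choices

* Offsets are 0-based half-open everywhere (character spans, token spans,
  trajectory windows).
* Sentence segmentation is rule-based for clinical text: hard newlines are
  always boundaries (notes are list-heavy), terminal punctuation splits
  unless the preceding word is a protected clinical abbreviation (Dr.,
  pt., hx., b.i.d., single-letter initials).
* Cosine scores are clamped to [−1, 1] against floating-point drift; the
  ungated sentinel score is −∞ and serializes as an empty field.
* Matcher tie-break: smallest exemplar id. Calibration tie-break: smallest
  threshold. Signed-rank p uses a 1e-12 comparison slack so midrank
  arithmetic cannot flip a ≥ into a > at machine precision.
* Problem sizes in the test and acceptance runs (60–600 patients,
  1,200-sentence fixture, 200 null replicates, 100 randomized
  matcher-oracle corpora) were chosen so each suite completes in seconds
  to a few minutes while keeping binomial noise well inside the asserted
  margins; they are stated in the tests themselves.
* `DictionarySentenceMatcher` and `ThresholdCalibrator` follow the
  scikit-learn estimator idiom (constructor params, `fit`, `predict`,
  trailing-underscore fitted attributes) so they compose with sklearn
  tooling; the module-level functions mirror them for scripting.
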