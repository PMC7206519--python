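# Methods

This note documents the model implemented by `edurec`, the choices made
where the published description left the design open, what the synthetic
fixtures do and do not emulate, and known limitations.

## The shared term space

Both patients and documents are represented in one ordered list of L term
labels (default 33) that double as patient characteristics and document
topics: chronic conditions (hypertension, diabetes, stroke, hyperlipidemia,
coronary artery disease, COPD, other disease), measurable risk factors
(blood pressure, blood glucose, total cholesterol, triglyceride, HDL, LDL,
uric acid, BMI), lifestyle and psychosocial factors (smoking, drinking,
diet, physical activity, depression, salt intake, weight control, exercise,
sleep, mental health), demographics (pregnancy, female, male, age), and
drug/education topics (antihypertensive, hypoglycemic and hypolipidemic
drugs, medication adherence). The label list is configuration
(`VectorSpace`, YAML-loadable), not code; the default is a faithful
reconstruction from the published patient-characteristic tables, not the
original (unavailable) term list.

## Patient side: severity rules

A `SeverityRule` is (target term, declarative condition, value 0–3,
priority). Evaluation is total and fail-soft: for each term, the matching
rule of highest priority wins, ties take the maximum value, and a term with
no matching rule — or a condition referencing missing data — stays 0 ("no
evidence of need"). Unknown field names are a load-time configuration
error, never an evaluation-time one. Rule-order permutation therefore
cannot change the result, and an all-normal record maps to the zero
vector.

Where only the "normal" boundary of a quantity is published, severity
grades are banded as follows (all overridable in YAML):

* blood pressure: grade 1/2/3 at 140–159/90–99, 160–179/100–109,
  ≥180/≥110 mm Hg, taking the worse of the systolic and diastolic grade;
* laboratory tests: graded by fold over the reference limit — ≤1.2× → 1,
  ≤1.5× → 2, else 3, symmetrically below the lower limit (reference ranges:
  glucose 3.9–6.1, total cholesterol 2.9–5.2, triglyceride 0.56–1.70, HDL
  1.20–1.68, LDL 2.07–3.12 mmol/L; uric acid by sex and age band; BMI
  18.5–23.9 kg/m² for Chinese adults);
* PHQ-9: 0–4/5–9/10–14/≥15 → 0/1/2/3; IPAQ high/moderate/low → 0/1/2;
  diet and adherence good/medium/poor → 0/1/2;
* disease history presence → 2; a current medication → 1 (the drug topic is
  relevant education); smoking 1–9/10–19/≥20 cigarettes per day → 1/2/3;
  drinking 1–7/8–14/≥15 drinks per week → 1/2/3;
* the female/male terms fire only together with a sex-specific need
  (pregnancy, smoking) so that a patient with no abnormal finding keeps a
  zero vector.

These are standard clinical cut-points; the original system's severity
banding beyond the blood-pressure example is not published, so they are
this package's choices.

## Document side

**Tokenization.** The `Tokenizer` contract produces POS-tagged tokens from
a closed tag set {noun, verb, adj, other}. The shipped tokenizer reads
whitespace-separated, `/`-tag-annotated text (the fixture format); a real
segmenter for unsegmented languages can plug in behind the same contract.
Title tokens enter the stream once, before the body, flagged `in_title`,
and count toward document frequencies.

**Compound induction.** Sequences of 2–3 atoms that occur in fixed order,
strictly adjacent, at least `min_adjacency` (default 5) times corpus-wide
and whose tag sequence matches a configured pattern (defaults: noun-noun,
adj-noun, noun-noun-noun) become user-dictionary entries. Adjacency never
spans the title/body boundary. Re-segmentation merges matches
leftmost-longest and non-overlapping into single noun tokens; the published
description fixes neither the thresholds nor the overlap policy, so both
are configurable with these defaults.

**Scoring.** TF-IDF uses raw term frequency and the smoothed inverse
document frequency ln((N+1)/(df+1)) + 1 (the variant is unspecified in the
source; this one never zeroes a ubiquitous term and collapses to ranking
by tf·w on a single-document corpus). TextRank builds an undirected graph
over distinct candidate surfaces with edge weights equal to co-occurrence
counts within a sliding window of 2 and iterates the non-normalized
PageRank-style update S(v) = (1−d) + d·Σ_u (w_uv/deg(u))·S(u) with d =
0.85, uniform start S = 1, tolerance 1e−6, at most 100 iterations
(non-convergence returns the current scores with a warning). An isolated
candidate scores 1−d. Candidates exclude stopwords and single-character
surfaces.

**Strategies.** The title factor (3) and POS factor (1.2 noun / 0.8 verb)
combine multiplicatively; the published description lists the three
weights but not a combination rule. For TextRank the combined factor is
applied to converged node scores rather than to edges, keeping strategy
application symmetric across the two extractors. Synonym elimination
compares binary character-set vectors (cosine = |A∩B|/√(|A||B|), threshold
0.5 by default) and removes the shorter surface (ties: lower score, then
lexicographically larger); it runs over the *full* ranked candidate list
before top-k truncation so that eliminated synonyms free slots for
lower-ranked non-synonyms. With all strategies disabled, extraction is
exactly the baseline method.

**Embeddings.** Word2vec CBOW with negative sampling is implemented
directly in numpy: window 5 with uniform random shrinking, mean-pooled
context, 5 negatives from the unigram distribution raised to 3/4,
frequent-word subsampling with keep probability √(t/f) + t/f at t = 1e−3
(epochs whose subsampled stream would be empty — possible only on
miniature corpora — fall back to the full stream), linear learning-rate
decay 0.025 → 1e−4, single-threaded and bit-reproducible for a fixed seed.
Defaults: 200 dimensions, 5 epochs, min_count 1 (the source fixes only the
architecture, window and dimensionality).

**Mapping.** The text vector sums, per term, the keyword–term embedding
cosines that reach the threshold (default 0.5, *inclusive*). Keyword
extraction scores do not weight the sum. Out-of-vocabulary keywords
contribute nothing; a term with no embedding (tried as its label, its
space-free compound form, then configured aliases) keeps entry 0 with one
logged warning per table. Since the threshold is nonnegative, text-vector
entries are nonnegative and each entry is bounded by the number of
keywords.

## Ranking, queue, metrics

The patient–document score is the plain inner product. Ranking sorts by
descending score with doc-id tie-breaks for determinism. The queue accepts
documents scoring *strictly* above v (default 2 — deliberately small given
vector sparsity), excludes already-delivered and non-reproducible
documents, and is rebuilt wholesale on vector updates.

Credited P@k counts grade 2 as 1 and grade 1 as 0.5. Average precision
uses grade ≥ 1 as the relevance indicator while keeping credited P@k inside
the sum, and normalizes by the patient's relevant-document count R_i — the
published formula is ambiguous on the normalizer, and the R_i choice is
the only one under which a perfect binary ranking scores exactly 1.
Patients with no relevant document are excluded from MAP (their AP is
undefined) with a warning. Keyword precision is exact surface match after
whitespace/case normalization; when automatic and manual counts per
document are equal it coincides with recall. The random-recommendation
baseline samples uniformly random rankings with a fixed number of grade-2
documents per patient; its expectation is relevant/n.

## Synthetic fixtures

`generate_corpus` plants one topic per document: the title names the topic
term (compound-form token) plus cycled topic words; the body mixes topic
words (weighted toward the term token) with a shared background
vocabulary; planted compound pairs occur strictly adjacently at a target
frequency (default 10, one occurrence per document); planted synonyms are
truncated variants of a topic word sharing all but one character,
concentrated in a few documents per topic. Content nouns are separated by
function-word-like "other" tokens except at planted compound sites, as in
real segmented text where particles keep content words apart — without
this, i.i.d. token sampling produces spurious high-frequency bigrams that
no real corpus would contain. Manual-annotation ground truth per document
is its five most frequent topic words (short synonym plants excluded, so
elimination is rewarded). Synthetic words are random low-alphabet strings,
which exercises the character-set synonym cosine without real Chinese
text.

`generate_patients` draws each characteristic independently from marginal
prevalences; the default population mirrors a 50-adult, all-hypertensive
cohort (abnormal BP 54 %, overweight 68 %, smoking 14 %, mean age 57 —
the published age dispersion of 0.57 years is implausible for 50 adults
and is replaced by sd 10, realized through an explicit elderly-fraction
prevalence of 0.38 so the age marginal stays controllable). A patient's
true need set is *defined* as the terms where the default ruleset fires,
making generated judgments consistent with the rule engine by
construction: grade 2 when a document's topic is a needed term, grade 1
for configured adjacent term pairs, 0 otherwise.

The end-to-end recovery experiment uses 3 topics (hypertension, blood
glucose, depression — hypertension history at prevalence 1.0 guarantees,
as in the study cohort, that every patient has at least one need), 30
documents, 10 patients, 50-dimensional embeddings and 20 epochs: small
enough to run in seconds, large enough that embedding noise, strategy
interactions and rule evaluation are all exercised. Across seeds it
reaches macro P@5 ≈ 1.

What passing these tests shows — and does not. The fixtures prove the
pipeline recovers relevance structure that is *present and clean*: topics
are disjoint, titles are informative, judgments derive from the same rule
semantics the profiler uses. Real corpora have overlapping topics, noisy
titles, annotation disagreement and vocabulary two orders of magnitude
larger; synthetic performance therefore bounds correctness of the
machinery, not expected clinical performance. Notably, the strategy
ablation on these fixtures reproduces the published *direction* for both
extractors: the three strategies improve TextRank markedly while slightly
hurting TF-IDF (whose idf already suppresses the background words that the
weights strategy re-boosts in titles).

## Numerical and degenerate-input policy

Cosine of a zero vector is defined as 0 with a warning. Empty keyword sets
map to zero text vectors. Score ties in ranking and surface ties in
keyword ranking break lexicographically. TextRank convergence is max
per-node change < tol. P@k with k beyond the ranking length computes over
the full ranking with a warning. All generators, embedding training and
the Monte-Carlo baseline are deterministic given their seeds.

## Known limitations

* No real Chinese segmenter adapter is shipped; the tokenizer contract is
  the integration point and all tests run on annotated fixtures.
* The default term space and severity rules are reconstructions faithful
  to the published constraints, not the original ontology or rule set.
* The hand-rolled word2vec is intended for corpus scales of the test
  suite and small studies; very large corpora would need a C-backed
  implementation behind the same `EmbeddingTable` interface.
* Judgments generated for fixtures are noiseless; no inter-annotator
  disagreement is modeled.
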