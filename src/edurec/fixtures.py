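"""Deterministic synthetic data: planted-topic corpora, patient
populations with configurable marginal prevalences, and ground-truth
relevance judgments.

The corpus generator emulates the structure the recommendation pipeline
assumes about real patient-education material: each document belongs to one
topic term of the vector space, its title names the topic, its body mixes
topic words with a shared background vocabulary, and the text additionally
carries planted compound-word pairs (adjacent atom tokens at a target
frequency) and planted synonyms (a shorter surface sharing most of a topic
word's characters), so that every improvement strategy has something to
find.  Synthetic "words" are random low-alphabet strings, which exercises
the character-composition synonym cosine without requiring real Chinese
text.

The patient generator draws each characteristic independently from
configurable marginal prevalences (defaults: an all-hypertensive chronic
disease cohort, e.g. abnormal BP 54%, overweight 68%, smoking 14%).  A
patient's *true need terms* are by construction the terms where the default
severity ruleset fires, so pipeline output can be scored against generated
judgments: grade 2 when a document's topic is a needed term, grade 1 for
configured adjacent term pairs, 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, build_corpus
from .metrics import RelevanceJudgment
from .patients import PatientRecord, URIC_ACID_RANGES, LAB_RANGES, default_ruleset, evaluate_rules
from .vectorspace import VectorSpace, default_space

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

#: marginal prevalences mirroring a 50-patient hypertensive cohort
DEFAULT_PREVALENCES: dict[str, float] = {
    "female": 0.46,
    "overweight": 0.68,
    "pregnant": 0.0,
    "history_hypertension": 1.0,
    "history_diabetes": 0.12,
    "history_stroke": 0.08,
    "history_hyperlipidemia": 0.24,
    "history_coronary artery disease": 0.06,
    "history_copd": 0.04,
    "history_other": 0.34,
    "abnormal_glucose": 0.28,
    "abnormal_total_cholesterol": 0.28,
    "abnormal_triglyceride": 0.42,
    "abnormal_hdl": 0.14,
    "abnormal_ldl": 0.20,
    "abnormal_uric_acid": 0.22,
    "abnormal_bp": 0.54,
    "smoking": 0.14,
    "drinking": 0.18,
    "diet_medium": 0.54,
    "diet_poor": 0.08,
    "med_antihypertensive": 1.0,
    "med_hypoglycemic": 0.06,
    "med_hypolipidemic": 0.24,
    "phq9_mild": 0.24,
    "phq9_moderate": 0.06,
    "phq9_moderately_severe": 0.04,
    "phq9_severe": 0.0,
    "ipaq_moderate": 0.46,
    "ipaq_low": 0.18,
    # fraction of patients aged >= 60 (cohort mean age 57)
    "elderly": 0.38,
    "adherence_medium": 0.30,
    "adherence_poor": 0.10,
}


@dataclass
class TopicModelSpec:
    """Specification of a planted-topic corpus."""

    topic_terms: tuple[str, ...] = ("hypertension", "blood glucose", "depression")
    words_per_topic: int = 8
    background_vocab: int = 40
    docs_per_topic: int = 10
    tokens_per_doc: tuple[float, float] = (60.0, 10.0)  # mean, sd
    title_topic_words: int = 2
    topic_token_share: float = 0.5
    n_compound_plants: int = 2
    compound_target_freq: int = 10
    synonym_plant_occurrences: int = 3   # per planted document
    synonym_plant_docs: int = 3          # documents per topic carrying the short synonym
    seed: int = 0
    #: explicit topic word lists (term -> [(word, pos)]); generated when None
    topics: dict[str, list[tuple[str, str]]] | None = None

    def __post_init__(self) -> None:
        if self.title_topic_words > self.words_per_topic:
            raise ValueError("title_topic_words cannot exceed words_per_topic")
        if min(self.words_per_topic, self.background_vocab, self.docs_per_topic,
               self.title_topic_words) < 1:
            raise ValueError("all corpus spec counts must be positive")


@dataclass
class PatientPopulationSpec:
    m: int = 50
    prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    age_mean: float = 57.0
    age_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.prevalences.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"prevalences must lie in [0, 1]: {bad}")


def _make_word(rng: np.random.Generator, used: set[str],
               length_range: tuple[int, int] = (4, 6)) -> str:
    while True:
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        w = "".join(_ALPHABET[i] for i in rng.integers(0, len(_ALPHABET), n))
        if w not in used:
            used.add(w)
            return w


def _term_token(term: str) -> str:
    return term.replace(" ", "")


def generate_corpus(spec: TopicModelSpec,
                    ) -> tuple[Corpus, dict[str, str], dict[str, set[str]]]:
    """Generate a seeded corpus.

    Returns ``(corpus, topic_labels, annotations)`` where ``topic_labels``
    maps each doc_id to its generating topic term and ``annotations`` maps
    each doc_id to its five "manual" keywords (the document's most frequent
    topic words — the ground truth for keyword-precision tests).
    """
    rng = np.random.default_rng(spec.seed)
    used: set[str] = {_term_token(t) for t in spec.topic_terms}

    # topic lexicons: the term's own (compound-form) token plus fresh words
    if spec.topics is None:
        topics = {}
        for term in spec.topic_terms:
            words = [(_term_token(term), "noun")]
            for i in range(spec.words_per_topic - 1):
                pos = "verb" if i == spec.words_per_topic - 2 else "noun"
                words.append((_make_word(rng, used), pos))
            topics[term] = words
    else:
        topics = {t: list(ws) for t, ws in spec.topics.items()}

    background = []
    for i in range(spec.background_vocab):
        pos = ("noun", "verb", "other")[i % 3]
        background.append((_make_word(rng, used), pos))
    # function-word-like separators (as in real segmented text, particles
    # keep content nouns apart except inside true collocations)
    fillers = [(_make_word(rng, used, (2, 3)), "other") for _ in range(5)]

    # planted synonyms: short variant of one non-term topic word per topic
    synonym_plants: dict[str, tuple[str, str]] = {}   # term -> (long, short)
    for term, words in topics.items():
        long_word = next((w for w, p in words[1:] if p == "noun" and len(w) >= 4), None)
        if long_word:
            synonym_plants[term] = (long_word, long_word[:-1])

    # planted compounds: adjacent (noun, noun) atom pairs at a target frequency
    compound_plants = [(_make_word(rng, used), _make_word(rng, used))
                       for _ in range(spec.n_compound_plants)]

    records = []
    topic_labels: dict[str, str] = {}
    annotations: dict[str, set[str]] = {}
    doc_no = 0
    all_doc_slots: list[str] = []
    doc_token_lists: dict[str, list[tuple[str, str]]] = {}

    for term in topics:
        words = topics[term]
        weights = np.full(len(words), 1.0)
        weights[0] = 3.0  # the term token dominates its topic
        weights /= weights.sum()
        for d in range(spec.docs_per_topic):
            doc_id = f"doc{doc_no:03d}"
            doc_no += 1
            topic_labels[doc_id] = term
            all_doc_slots.append(doc_id)

            title_words = [words[0]]
            # cycle the extra title topic words deterministically so no
            # title bigram repeats often enough to look like a compound
            for j in range(spec.title_topic_words - 1):
                title_words.append(words[1 + (d + j) % (len(words) - 1)])
            title_words.append(background[int(rng.integers(len(background)))])

            mean, sd = spec.tokens_per_doc
            n_tokens = max(20, int(round(rng.normal(mean, sd))))
            body: list[tuple[str, str]] = []
            for _ in range(n_tokens):
                if rng.random() < spec.topic_token_share:
                    body.append(words[int(rng.choice(len(words), p=weights))])
                else:
                    body.append(background[int(rng.integers(len(background)))])

            # plant the short synonym in the first few documents of the topic
            if term in synonym_plants and d < spec.synonym_plant_docs:
                _, short = synonym_plants[term]
                for _ in range(spec.synonym_plant_occurrences):
                    body.insert(int(rng.integers(len(body) + 1)), (short, "noun"))

            doc_token_lists[doc_id] = body
            records.append((doc_id, title_words, body))

    # distribute compound plants: one adjacent occurrence per document,
    # cycling; never insert inside a previously planted pair
    pair_set = set(compound_plants)
    for atoms in compound_plants:
        for i in range(spec.compound_target_freq):
            doc_id = all_doc_slots[i % len(all_doc_slots)]
            body = doc_token_lists[doc_id]
            while True:
                pos = int(rng.integers(len(body) + 1))
                if (0 < pos < len(body)
                        and (body[pos - 1][0], body[pos][0]) in pair_set):
                    continue
                break
            body[pos:pos] = [(atoms[0], "noun"), (atoms[1], "noun")]

    allowed_pairs = set(compound_plants)

    def _separate(tokens: list[tuple[str, str]]) -> list[tuple[str, str]]:
        # keep planted compounds the only repeated noun-noun adjacencies
        out: list[tuple[str, str]] = []
        k = 0
        for w, p in tokens:
            if (out and p == "noun" and out[-1][1] == "noun"
                    and (out[-1][0], w) not in allowed_pairs):
                out.append(fillers[k % len(fillers)])
                k += 1
            out.append((w, p))
        return out

    jsonl_records = []
    for doc_id, title_words, body in records:
        term = topic_labels[doc_id]
        title_words = _separate(title_words)
        body = _separate(body)
        title = " ".join(f"{w}/{p[0]}" for w, p in title_words)
        text = " ".join(f"{w}/{p[0]}" for w, p in body)
        jsonl_records.append((doc_id, title, text, True))

        # manual annotation: the 5 most frequent topic words present in the
        # document (title + body), short synonym plants excluded
        topic_surfaces = {w for w, _ in topics[term]}
        shorts = {synonym_plants[term][1]} if term in synonym_plants else set()
        counts: dict[str, int] = {}
        for w, _ in [*title_words, *body]:
            if w in topic_surfaces and w not in shorts:
                counts[w] = counts.get(w, 0) + 1
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        annotations[doc_id] = {w for w, _ in top}

    corpus = build_corpus(jsonl_records)
    return corpus, topic_labels, annotations


def _band_value(rng, low, high):
    return float(rng.uniform(low, high))


def generate_patients(spec: PatientPopulationSpec,
                      space: VectorSpace | None = None,
                      ) -> tuple[list[PatientRecord], dict[str, set[str]]]:
    """Generate seeded patient records and their true need-term sets.

    A record's need set is *defined* as the terms where the default ruleset
    evaluates to a nonzero severity, so judgments generated from it are
    consistent with the rule engine by construction.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.prevalences
    space = space or default_space()
    ruleset = default_ruleset(space)

    records: list[PatientRecord] = []
    needs: dict[str, set[str]] = {}
    for i in range(spec.m):
        pid = f"pt{i:03d}"
        sex = "female" if rng.random() < p.get("female", 0.5) else "male"
        # age drawn within the band implied by the elderly prevalence so the
        # age-severity marginal is exactly controllable
        if rng.random() < p.get("elderly", 0):
            age = float(rng.uniform(60.0, 85.0))
        else:
            age = float(rng.uniform(35.0, 59.0))

        bmi = (_band_value(rng, 24.0, 32.0) if rng.random() < p.get("overweight", 0)
               else _band_value(rng, 18.5, 23.9))

        history = {h for h in ("hypertension", "diabetes", "stroke", "hyperlipidemia",
                               "coronary artery disease", "copd", "other")
                   if rng.random() < p.get(f"history_{h}", 0)}

        labs: dict[str, float] = {}
        for lab, (lo, hi) in LAB_RANGES.items():
            if rng.random() < p.get(f"abnormal_{lab}", 0):
                labs[lab] = hi * _band_value(rng, 1.02, 1.8)
            else:
                labs[lab] = _band_value(rng, lo, hi)
        ua_lo, ua_hi = URIC_ACID_RANGES[(sex, "under60" if age < 60 else "over60")]
        if rng.random() < p.get("abnormal_uric_acid", 0):
            labs["uric_acid"] = ua_hi * _band_value(rng, 1.02, 1.8)
        else:
            labs["uric_acid"] = _band_value(rng, ua_lo, ua_hi)

        if rng.random() < p.get("abnormal_bp", 0):
            systolic = _band_value(rng, 140.0, 195.0)
            diastolic = _band_value(rng, 85.0, 118.0)
        else:
            systolic = _band_value(rng, 95.0, 135.0)
            diastolic = _band_value(rng, 60.0, 85.0)

        cigarettes = int(rng.integers(5, 31)) if rng.random() < p.get("smoking", 0) else 0
        drinks = int(rng.integers(2, 21)) if rng.random() < p.get("drinking", 0) else 0

        u = rng.random()
        diet = ("poor" if u < p.get("diet_poor", 0)
                else "medium" if u < p.get("diet_poor", 0) + p.get("diet_medium", 0)
                else "good")
        meds = {m for m in ("antihypertensive", "hypoglycemic", "hypolipidemic")
                if rng.random() < p.get(f"med_{m}", 0)}
        u = rng.random()
        adherence = ("poor" if u < p.get("adherence_poor", 0)
                     else "medium" if u < p.get("adherence_poor", 0) + p.get("adherence_medium", 0)
                     else "good")

        u = rng.random()
        if u < p.get("phq9_severe", 0):
            phq9 = int(rng.integers(20, 28))
        elif u < p.get("phq9_severe", 0) + p.get("phq9_moderately_severe", 0):
            phq9 = int(rng.integers(15, 20))
        elif u < (p.get("phq9_severe", 0) + p.get("phq9_moderately_severe", 0)
                  + p.get("phq9_moderate", 0)):
            phq9 = int(rng.integers(10, 15))
        elif u < (p.get("phq9_severe", 0) + p.get("phq9_moderately_severe", 0)
                  + p.get("phq9_moderate", 0) + p.get("phq9_mild", 0)):
            phq9 = int(rng.integers(5, 10))
        else:
            phq9 = int(rng.integers(0, 5))

        u = rng.random()
        ipaq = ("low" if u < p.get("ipaq_low", 0)
                else "moderate" if u < p.get("ipaq_low", 0) + p.get("ipaq_moderate", 0)
                else "high")

        record = PatientRecord(
            patient_id=pid, sex=sex, age=age, bmi=bmi,
            pregnant=rng.random() < p.get("pregnant", 0),
            history=history, labs=labs,
            monitoring={"systolic_bp": systolic, "diastolic_bp": diastolic,
                        "cigarettes_per_day": cigarettes, "drinks_per_week": drinks,
                        "diet": diet, "medications": meds, "adherence": adherence},
            questionnaires={"phq9": phq9, "ipaq": ipaq},
        )
        records.append(record)
        vec = evaluate_rules(record, ruleset, space)
        needs[pid] = {t for t, v in zip(space.terms, vec.values) if v > 0}
    return records, needs


def generate_judgments(true_topics: dict[str, str],
                       true_needs: dict[str, set[str]],
                       adjacency: dict[str, set[str]] | None = None,
                       space: VectorSpace | None = None) -> list[RelevanceJudgment]:
    """Ground-truth graded judgments from planted topics and need sets.

    Grade 2 when the document's topic is in the patient's need set, grade 1
    when the topic is adjacent (per ``adjacency``) to a needed term, else 0.
    """
    if space is not None:
        unknown = (set(true_topics.values()) - set(space.terms))
        for s in (adjacency or {}).items():
            unknown |= ({s[0]} | set(s[1])) - set(space.terms)
        if unknown:
            raise ValueError(f"unknown term label(s): {sorted(unknown)}")
    adjacency = adjacency or {}
    out = []
    for pid, need in true_needs.items():
        partial = set()
        for t in need:
            partial |= adjacency.get(t, set())
        for doc_id, topic in true_topics.items():
            grade = 2 if topic in need else (1 if topic in partial else 0)
            out.append(RelevanceJudgment(pid, doc_id, grade))
    return out
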