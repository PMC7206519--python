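"""Document corpus model, pluggable POS-tagged tokenization, and
compound-word dictionary induction.

Educational documents arrive as plain text with an optional title.  Before
keyword extraction the text is segmented into *atom* tokens, each carrying a
part-of-speech tag from a small closed set.  Frequent, strictly adjacent atom
sequences whose tag pattern looks like a content phrase (noun-noun,
adj-noun, ...) are collected into a user dictionary of *compound words*; a
second segmentation pass then keeps those compounds whole, so that multiword
concepts ("blood pressure", 高血压) survive as single keyword candidates.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Protocol, Sequence

POS_TAGS = frozenset({"noun", "verb", "adj", "other"})

#: short tag aliases accepted in annotated text ("word/n") and user dictionaries
_TAG_ALIASES = {
    "n": "noun", "noun": "noun",
    "v": "verb", "verb": "verb",
    "a": "adj", "adj": "adj",
    "x": "other", "other": "other",
}

DEFAULT_POS_PATTERNS = frozenset({
    ("noun", "noun"),
    ("adj", "noun"),
    ("noun", "noun", "noun"),
})


@dataclass(frozen=True)
class Token:
    """A segmented atom (or merged compound) with its POS tag."""

    surface: str
    pos: str = "other"
    in_title: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.pos not in POS_TAGS:
            raise ValueError(f"unknown POS tag {self.pos!r}; expected one of {sorted(POS_TAGS)}")


@dataclass
class Document:
    """One educational material: title + body, plus its token stream.

    ``reproducible=False`` marks material that may be used for training
    (frequency counts, embeddings) but must never be delivered to patients.
    """

    doc_id: str
    title: str = ""
    body: str = ""
    reproducible: bool = True
    tokens: list[Token] = field(default_factory=list)

    @property
    def title_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.in_title]

    @property
    def body_tokens(self) -> list[Token]:
        return [t for t in self.tokens if not t.in_title]

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class Corpus:
    documents: list[Document]
    vocabulary: dict[str, int] = field(default_factory=dict)

    @property
    def total_docs(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def get(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    def df(self, surface: str) -> int:
        """Document frequency: number of documents containing ``surface``."""
        return self.vocabulary.get(surface, 0)

    def recompute_vocabulary(self) -> None:
        df: Counter[str] = Counter()
        for d in self.documents:
            df.update(set(d.surfaces()))
        self.vocabulary = dict(df)


class Tokenizer(Protocol):
    """Segmentation contract.

    ``segment`` must be deterministic for a fixed input and dictionary, and
    must treat any user-dictionary entry as a single token wherever its atom
    sequence appears adjacently in the text.
    """

    def segment(self, text: str, user_dictionary: "CompoundLexicon | None" = None,
                in_title: bool = False) -> list[Token]: ...


class TaggedWhitespaceTokenizer:
    """Whitespace tokenizer for pre-tagged text (``surface/n surface2/v``).

    Untagged tokens default to ``other``.  This is the reference tokenizer
    for synthetic fixtures, which carry explicit POS annotations; a real
    segmenter for unsegmented languages plugs in behind the same contract.
    """

    def segment(self, text: str, user_dictionary: "CompoundLexicon | None" = None,
                in_title: bool = False) -> list[Token]:
        tokens = []
        for piece in text.split():
            surface, sep, tag = piece.rpartition("/")
            if sep and tag in _TAG_ALIASES:
                tokens.append(Token(surface, _TAG_ALIASES[tag], in_title))
            else:
                tokens.append(Token(piece, "other", in_title))
        if user_dictionary is not None:
            tokens = merge_compounds(tokens, user_dictionary)
        return tokens


@dataclass(frozen=True)
class CompoundEntry:
    atoms: tuple[str, ...]
    count: int
    pos: str = "noun"

    @property
    def surface(self) -> str:
        return "".join(self.atoms)


@dataclass
class CompoundLexicon:
    """User dictionary of induced compound words, keyed by atom sequence."""

    entries: dict[tuple[str, ...], CompoundEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return any(e.surface == surface for e in self.entries.values())

    @property
    def surfaces(self) -> set[str]:
        return {e.surface for e in self.entries.values()}

    @property
    def max_atoms(self) -> int:
        return max((len(a) for a in self.entries), default=0)

    def to_user_dict_text(self) -> str:
        """One entry per line: ``surface count pos`` (segmenter user-dictionary style)."""
        lines = [f"{e.surface} {e.count} {e.pos}"
                 for e in sorted(self.entries.values(), key=lambda e: (-e.count, e.surface))]
        return "\n".join(lines) + ("\n" if lines else "")


def build_corpus(records: Iterable[tuple[str, str, str, bool]],
                 tokenizer: Tokenizer | None = None,
                 user_dictionary: CompoundLexicon | None = None) -> Corpus:
    """Assemble a tokenized :class:`Corpus` from ``(doc_id, title, body, reproducible)``.

    Title tokens enter the token stream once (before the body) and are
    flagged ``in_title``; document frequencies count both.
    """
    tokenizer = tokenizer or TaggedWhitespaceTokenizer()
    docs: list[Document] = []
    seen: set[str] = set()
    for doc_id, title, body, reproducible in records:
        if doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc_id!r}")
        if not body:
            raise ValueError(f"document {doc_id!r} has an empty body")
        seen.add(doc_id)
        tokens = tokenizer.segment(title, user_dictionary, in_title=True)
        tokens += tokenizer.segment(body, user_dictionary, in_title=False)
        docs.append(Document(doc_id, title, body, bool(reproducible), tokens))
    if not docs:
        raise ValueError("cannot build an empty corpus")
    corpus = Corpus(docs)
    corpus.recompute_vocabulary()
    return corpus


def read_corpus_jsonl(path, tokenizer: Tokenizer | None = None) -> Corpus:
    """Load a corpus from JSONL records ``{id, title, text, reproducible}``."""
    def records():
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                yield (rec["id"], rec.get("title", ""), rec["text"],
                       rec.get("reproducible", True))
    return build_corpus(records(), tokenizer)


def write_corpus_jsonl(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus:
            fh.write(json.dumps({"id": d.doc_id, "title": d.title, "text": d.body,
                                 "reproducible": d.reproducible}, ensure_ascii=False) + "\n")


def _token_runs(doc: Document) -> list[list[Token]]:
    # adjacency never spans the title/body boundary
    title = doc.title_tokens
    body = doc.body_tokens
    return [run for run in (title, body) if run]


def identify_compounds(corpus: Corpus,
                       min_adjacency: int = 5,
                       pos_patterns: frozenset[tuple[str, ...]] = DEFAULT_POS_PATTERNS,
                       max_atoms: int = 3) -> CompoundLexicon:
    """Induce a compound-word dictionary from strictly adjacent atom sequences.

    A sequence of 2..``max_atoms`` atoms qualifies when it occurs in fixed
    order with no intervening token at least ``min_adjacency`` times
    corpus-wide and its POS-tag sequence matches a configured pattern.
    """
    if min_adjacency < 1:
        raise ValueError("min_adjacency must be >= 1")
    if any(not d.tokens for d in corpus):
        raise ValueError("corpus must be tokenized before compound identification")
    lengths = {len(p) for p in pos_patterns if 2 <= len(p) <= max_atoms}
    counts: Counter[tuple[tuple[str, str], ...]] = Counter()
    for doc in corpus:
        for run in _token_runs(doc):
            for n in lengths:
                for i in range(len(run) - n + 1):
                    gram = tuple((t.surface, t.pos) for t in run[i:i + n])
                    if tuple(g[1] for g in gram) in pos_patterns:
                        counts[gram] += 1
    lex = CompoundLexicon()
    for gram, c in counts.items():
        if c >= min_adjacency:
            atoms = tuple(g[0] for g in gram)
            lex.entries[atoms] = CompoundEntry(atoms, c)
    return lex


def merge_compounds(tokens: Sequence[Token], lexicon: CompoundLexicon) -> list[Token]:
    """Merge each leftmost-longest, non-overlapping lexicon match into one noun token."""
    if not lexicon.entries:
        return list(tokens)
    longest = lexicon.max_atoms
    out: list[Token] = []
    i = 0
    while i < len(tokens):
        merged = False
        for n in range(min(longest, len(tokens) - i), 1, -1):
            span = tokens[i:i + n]
            atoms = tuple(t.surface for t in span)
            if atoms in lexicon.entries and len({t.in_title for t in span}) == 1:
                out.append(Token("".join(atoms), "noun", span[0].in_title))
                i += n
                merged = True
                break
        if not merged:
            out.append(tokens[i])
            i += 1
    return out


def resegment_with_lexicon(corpus: Corpus, lexicon: CompoundLexicon) -> Corpus:
    """Return a new corpus with compound matches merged and frequencies recomputed."""
    docs = [replace(d, tokens=merge_compounds(d.title_tokens, lexicon)
                    + merge_compounds(d.body_tokens, lexicon))
            for d in corpus]
    out = Corpus(docs)
    out.recompute_vocabulary()
    return out
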