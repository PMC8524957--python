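"""Data model and I/O for E3 dictionaries and sentence corpora.

A corpus is a list of :class:`AnnotatedSentence` objects: a sentence, its
E3 ligase mentions found by dictionary matching, an optional set of
substrate spans, and a binary interaction label.  Dictionaries map a
canonical E3 identifier (e.g. a UniProt-style accession) to the synonym
surface forms under which the ligase appears in text; matching is
case-insensitive, longest-match-first and non-overlapping.

On-disk formats are line-oriented and diff-friendly: dictionaries are
two-column TSV (``canonical_id<TAB>synonym``, one row per synonym) and
corpora are JSONL with one annotated sentence per line.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "E3Dictionary",
    "Sentence",
    "E3Mention",
    "AnnotatedSentence",
    "CorpusSplit",
    "segment_article",
    "tokenize",
    "find_e3_mentions",
    "filter_sentences",
    "split_corpus",
    "corpus_stats",
    "read_dictionary_tsv",
    "write_dictionary_tsv",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class E3Dictionary:
    """Canonical E3 ligase IDs mapped to their synonym surface forms.

    Synonym lookup is case-insensitive.  Every synonym must be non-empty
    after whitespace trimming and no canonical ID may repeat.
    """

    entries: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("dictionary must contain at least one entry")
        cleaned: dict[str, tuple[str, ...]] = {}
        for cid, synonyms in self.entries.items():
            syns = tuple(s.strip() for s in synonyms)
            if any(not s for s in syns) or not syns:
                raise ValueError(f"entry {cid!r} has an empty synonym")
            cleaned[cid] = syns
        object.__setattr__(self, "entries", cleaned)

    @property
    def canonical_ids(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def synonyms(self, canonical_id: str) -> tuple[str, ...]:
        return self.entries[canonical_id]

    def surface_index(self) -> dict[str, str]:
        """Lowercased surface form -> canonical ID (first entry wins on clash)."""
        index: dict[str, str] = {}
        for cid, syns in self.entries.items():
            for s in syns:
                index.setdefault(s.lower(), cid)
        return index


@dataclass(frozen=True)
class Sentence:
    """One sentence of article text, addressable by (doc_id, sent_index)."""

    text: str
    doc_id: str = ""
    sent_index: int = 0

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("sentence text must be non-empty")
        if self.sent_index < 0:
            raise ValueError("sent_index must be non-negative")


@dataclass(frozen=True)
class E3Mention:
    """A dictionary match inside a sentence.

    ``char_start``/``char_end`` are 0-based half-open offsets into the
    sentence text; ``token_rank`` is the 1-based rank of the mention's
    first token among the sentence tokens (whitespace split, punctuation
    stripped), the quantity the positional channel consumes.
    """

    surface: str
    canonical_id: str
    char_start: int
    char_end: int
    token_rank: int


@dataclass(frozen=True)
class AnnotatedSentence:
    """A sentence with its E3 mentions, optional substrate spans, and label.

    ``label`` is ``"positive"`` (the sentence states at least one
    E3-substrate interaction), ``"negative"``, or ``None`` (unlabeled).
    By corpus design every sentence carries at least one E3 mention.
    """

    sentence: Sentence
    label: str | None = None
    e3_mentions: tuple[E3Mention, ...] = ()
    substrate_spans: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 'positive', 'negative' or None, got {self.label!r}")
        if not self.e3_mentions:
            raise ValueError("an annotated sentence must have at least one E3 mention")
        for m in self.e3_mentions:
            span = self.sentence.text[m.char_start : m.char_end]
            if span.lower() != m.surface.lower():
                raise ValueError(
                    f"mention offsets [{m.char_start}:{m.char_end}] yield {span!r}, "
                    f"expected {m.surface!r}"
                )

    @property
    def text(self) -> str:
        return self.sentence.text


@dataclass(frozen=True)
class CorpusSplit:
    """A seeded train/test partition of a corpus."""

    train: tuple[AnnotatedSentence, ...]
    test: tuple[AnnotatedSentence, ...]
    train_fraction: float
    seed: int


# Abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS = (
    "fig", "figs", "et al", "e.g", "i.e", "cf", "vs", "ref", "refs",
    "dr", "prof", "no", "vol", "ca", "approx", "inc", "spp", "sp",
)
_BOUNDARY_RE = re.compile(r"([.!?])\s+(?=[A-Z(\"'])")


def segment_article(text: str) -> list[Sentence]:
    """Split raw article text into sentences.

    Boundaries are placed at ``.``, ``!`` or ``?`` followed by whitespace
    and an uppercase opener, guarded by a list of common abbreviations
    ("Fig.", "et al.", ...) so that they do not trigger a break.
    Concatenating the returned sentence texts (modulo the inter-sentence
    whitespace) recovers the input.
    """
    if not text or not text.strip():
        raise ValueError("cannot segment empty text")
    pieces: list[str] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        end = match.end(1)
        prefix = text[start:end]
        lowered = prefix[:-1].rstrip().lower()
        if any(lowered.endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        pieces.append(prefix.strip())
        start = match.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return [Sentence(text=p, doc_id="", sent_index=i) for i, p in enumerate(pieces)]


_TOKEN_STRIP = ".,;:!?()[]{}\"'"


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with leading/trailing punctuation stripped.

    Tokens that are pure punctuation are dropped.  This is the word count
    against which the positional channel's token rank is computed.
    """
    tokens = []
    for raw in text.split():
        tok = raw.strip(_TOKEN_STRIP)
        if tok:
            tokens.append(tok)
    return tokens


def _token_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of the tokens produced by :func:`tokenize`."""
    spans = []
    for m in re.finditer(r"\S+", text):
        raw = m.group()
        lead = len(raw) - len(raw.lstrip(_TOKEN_STRIP))
        trail = len(raw) - len(raw.rstrip(_TOKEN_STRIP))
        start, end = m.start() + lead, m.end() - trail
        if end > start:
            spans.append((start, end))
    return spans


def _is_word_boundary(text: str, start: int, end: int) -> bool:
    def wordish(ch: str) -> bool:
        return ch.isalnum() or ch == "_"

    before_ok = start == 0 or not wordish(text[start - 1])
    after_ok = end == len(text) or not wordish(text[end])
    return before_ok and after_ok


def find_e3_mentions(sentence: Sentence, dictionary: E3Dictionary) -> list[E3Mention]:
    """Locate dictionary E3 surface forms in a sentence.

    Matching is case-insensitive, anchored at word boundaries,
    longest-match-first and non-overlapping; results come back in
    left-to-right order.  Longest-first resolves nested synonyms
    ("Mdm2" inside "Oncoprotein Mdm2") deterministically.
    """
    index = dictionary.surface_index()
    lowered = sentence.text.lower()
    n = len(lowered)
    # Surface forms sorted longest first so the outer form wins at a position.
    surfaces = sorted(index, key=len, reverse=True)
    occupied = np.zeros(n, dtype=bool)
    hits: list[tuple[int, int, str]] = []
    for surf in surfaces:
        start = 0
        while True:
            pos = lowered.find(surf, start)
            if pos < 0:
                break
            end = pos + len(surf)
            if _is_word_boundary(sentence.text, pos, end) and not occupied[pos:end].any():
                occupied[pos:end] = True
                hits.append((pos, end, surf))
            start = pos + 1
    hits.sort()

    spans = _token_spans(sentence.text)
    mentions = []
    for pos, end, surf in hits:
        rank = 1
        for i, (ts, te) in enumerate(spans, start=1):
            if ts <= pos < te or pos <= ts < end:
                rank = i
                break
        mentions.append(
            E3Mention(
                surface=sentence.text[pos:end],
                canonical_id=index[surf],
                char_start=pos,
                char_end=end,
                token_rank=rank,
            )
        )
    return mentions


def filter_sentences(
    sentences: Iterable[Sentence], dictionary: E3Dictionary
) -> list[AnnotatedSentence]:
    """Keep exactly the sentences containing at least one dictionary E3.

    Each retained sentence is wrapped, unlabeled, with its mentions;
    input order is preserved.
    """
    out = []
    for sent in sentences:
        mentions = find_e3_mentions(sent, dictionary)
        if mentions:
            out.append(
                AnnotatedSentence(sentence=sent, label=None, e3_mentions=tuple(mentions))
            )
    return out


def split_corpus(
    corpus: Sequence[AnnotatedSentence],
    train_fraction: float = 0.70,
    seed: int = 0,
) -> CorpusSplit:
    """Seeded uniform random 70/30 (by default) train/test split.

    The train partition takes the first ``floor(train_fraction * N)``
    items of a seeded permutation, so a corpus of 3195 sentences at
    fraction 0.70 yields 2236 train and 959 test sentences.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 sentences to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    train = tuple(corpus[i] for i in order[:n_train])
    test = tuple(corpus[i] for i in order[n_train:])
    return CorpusSplit(train=train, test=test, train_fraction=train_fraction, seed=seed)


def corpus_stats(
    corpus_or_split: Sequence[AnnotatedSentence] | CorpusSplit,
) -> pd.DataFrame:
    """Per-partition positive/negative/total counts.

    Returns a DataFrame indexed by partition ("Training", "Test", "Total"
    for a split; "Total" only for a flat corpus) with columns
    ``positive``, ``negative``, ``total``.  Raises if any sentence is
    unlabeled.
    """

    def count(part: Sequence[AnnotatedSentence]) -> tuple[int, int]:
        pos = neg = 0
        for s in part:
            if s.label == POSITIVE:
                pos += 1
            elif s.label == NEGATIVE:
                neg += 1
            else:
                raise ValueError("corpus_stats requires every sentence to be labeled")
        return pos, neg

    if isinstance(corpus_or_split, CorpusSplit):
        rows = {}
        tp, tn = count(corpus_or_split.train)
        rows["Training"] = (tp, tn, tp + tn)
        sp, sn = count(corpus_or_split.test)
        rows["Test"] = (sp, sn, sp + sn)
        rows["Total"] = (tp + sp, tn + sn, tp + tn + sp + sn)
    else:
        p, n = count(corpus_or_split)
        rows = {"Total": (p, n, p + n)}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["positive", "negative", "total"]
    )


# ---------------------------------------------------------------------------
# I/O


def read_dictionary_tsv(path: str | Path) -> E3Dictionary:
    """Read ``canonical_id<TAB>synonym`` rows (UTF-8, no header)."""
    entries: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            cid, synonym = parts
            entries.setdefault(cid, []).append(synonym)
    return E3Dictionary(entries={cid: tuple(s) for cid, s in entries.items()})


def write_dictionary_tsv(dictionary: E3Dictionary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, synonyms in dictionary.entries.items():
            for s in synonyms:
                fh.write(f"{cid}\t{s}\n")


def _sentence_to_record(item: AnnotatedSentence) -> dict:
    return {
        "text": item.sentence.text,
        "doc_id": item.sentence.doc_id,
        "sent_index": item.sentence.sent_index,
        "label": item.label,
        "e3_mentions": [
            {
                "surface": m.surface,
                "canonical_id": m.canonical_id,
                "char_start": m.char_start,
                "char_end": m.char_end,
                "token_rank": m.token_rank,
            }
            for m in item.e3_mentions
        ],
        "substrates": [
            {"char_start": s, "char_end": e, "surface": surf}
            for s, e, surf in item.substrate_spans
        ],
    }


def _record_to_sentence(rec: dict) -> AnnotatedSentence:
    sentence = Sentence(
        text=rec["text"], doc_id=rec.get("doc_id", ""), sent_index=rec.get("sent_index", 0)
    )
    mentions = tuple(
        E3Mention(
            surface=m["surface"],
            canonical_id=m["canonical_id"],
            char_start=m["char_start"],
            char_end=m["char_end"],
            token_rank=m["token_rank"],
        )
        for m in rec.get("e3_mentions", [])
    )
    substrates = tuple(
        (s["char_start"], s["char_end"], s["surface"]) for s in rec.get("substrates", [])
    )
    return AnnotatedSentence(
        sentence=sentence,
        label=rec.get("label"),
        e3_mentions=mentions,
        substrate_spans=substrates,
    )


def read_corpus_jsonl(path: str | Path) -> list[AnnotatedSentence]:
    """Read one :class:`AnnotatedSentence` JSON object per line."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(_record_to_sentence(json.loads(line)))
    return out


def write_corpus_jsonl(corpus: Iterable[AnnotatedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in corpus:
            fh.write(json.dumps(_sentence_to_record(item), ensure_ascii=False) + "\n")
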