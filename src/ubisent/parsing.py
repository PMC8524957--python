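"""Lightweight dependency analysis for the syntactic channel.

The syntactic signal the classifier uses is narrow: does the E3 ligase
mention stand in a nominal-subject ("nsubj") relation to a verb ("Cbl-b
... is the nsubj of the verb targets")?  Any parser exposing
:class:`DependencyParser` can provide it.  The built-in
:class:`HeuristicDependencyParser` is a deterministic rule-based tagger
tuned to declarative biomedical prose: verbs come from a lemma lexicon
plus regular inflections; be/have/modal forms are auxiliaries (so
copular statements like "X is an E3 ligase" have no verb subject);
passive participles after an auxiliary take no agentive subject; the
subject search walks left over adverbs, auxiliaries, comma-bounded
appositives and prepositional objects to the governing noun.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

from ubisent.corpus import E3Mention, Sentence

__all__ = [
    "ParsedToken",
    "DependencyParser",
    "HeuristicDependencyParser",
    "find_nsubj_verb",
]

logger = logging.getLogger(__name__)

_STRIP = ".,;:!?()[]\"'"


@dataclass(frozen=True)
class ParsedToken:
    """Per-token parse output: surface, POS tag, head index, relation.

    ``head`` is the 0-based index of the governing token, or -1 for
    unattached tokens.
    """

    surface: str
    pos: str
    head: int
    deprel: str


@runtime_checkable
class DependencyParser(Protocol):
    def parse(self, tokens: Sequence[str]) -> list[ParsedToken]:  # pragma: no cover
        ...


_AUX = {
    "is", "are", "was", "were", "be", "been", "being", "am",
    "has", "have", "had", "can", "could", "may", "might", "will",
    "would", "does", "do", "did", "should", "must",
}
_ADVERBS = {
    "also", "similarly", "directly", "specifically", "subsequently", "then",
    "further", "efficiently", "strongly", "robustly", "thereby", "rapidly",
    "selectively", "primarily", "markedly", "potently", "consequently",
    "additionally", "moreover", "however", "thus", "physically", "both",
    "notably", "interestingly",
}
_PREPOSITIONS = {
    "of", "in", "on", "at", "to", "from", "by", "with", "under", "during",
    "after", "before", "between", "into", "through", "within", "for",
}
_VERB_LEMMAS = {
    "target", "ubiquitylate", "ubiquitinate", "polyubiquitylate",
    "polyubiquitinate", "monoubiquitinate", "promote", "mediate", "catalyze",
    "catalyse", "induce", "trigger", "reverse", "degrade", "bind", "interact",
    "regulate", "control", "modulate", "stimulate", "facilitate", "drive",
    "accelerate", "tag", "mark", "destabilize", "stabilize", "increase",
    "recognize", "recognise", "recruit", "select", "attach", "conjugate",
    "transfer", "identify", "localize", "localise", "colocalize", "associate",
    "accumulate", "express", "measure", "observe", "detect", "remain", "belong",
    "contain", "exhibit", "show", "display", "encode", "require", "act",
    "function", "participate", "cooperate", "suppress", "inhibit", "enhance",
}


def _verb_lemma(token: str) -> str | None:
    """Lemma if the token is a recognized verb inflection, else None."""
    w = token.lower()
    candidates = [w]
    if w.endswith("ies"):
        candidates.append(w[:-3] + "y")
    if w.endswith("es"):
        candidates.append(w[:-2])
    if w.endswith("s"):
        candidates.append(w[:-1])
    if w.endswith("ed"):
        candidates.append(w[:-2])
        candidates.append(w[:-1])  # "mediated" -> "mediate"
        candidates.append(w[:-2] + "e")
    if w.endswith("ing"):
        candidates.append(w[:-3])
        candidates.append(w[:-3] + "e")
    for c in candidates:
        if c in _VERB_LEMMAS:
            return c
    return None


class HeuristicDependencyParser:
    """Deterministic rule-based POS tagging and subject attachment.

    Operates on raw whitespace tokens (punctuation kept, so commas mark
    appositive boundaries).  Adequate for the clause structures of the
    synthetic templates and simple declarative prose; not a general
    parser.
    """

    name = "heuristic"

    def parse(self, tokens: Sequence[str]) -> list[ParsedToken]:
        n = len(tokens)
        pos = []
        for tok in tokens:
            w = tok.lower().strip(_STRIP)
            if w in _AUX:
                pos.append("AUX")
            elif w in _ADVERBS:
                pos.append("ADV")
            elif w in _PREPOSITIONS:
                pos.append("ADP")
            elif _verb_lemma(w) is not None:
                pos.append("VERB")
            elif not any(ch.isalnum() for ch in tok):
                pos.append("PUNCT")
            else:
                pos.append("NOUN")

        head = [-1] * n
        deprel = ["dep"] * n
        for j in range(n):
            if pos[j] != "VERB":
                continue
            # Passive "was <verb>ed": the left noun is not an agentive subject.
            k = j - 1
            while k >= 0 and pos[k] == "ADV":
                k -= 1
            if k >= 0 and pos[k] == "AUX" and tokens[j].lower().rstrip(_STRIP).endswith(("ed", "en")):
                continue
            subj = self._subject_of(tokens, pos, j)
            if subj is not None and deprel[subj] == "dep":
                head[subj] = j
                deprel[subj] = "nsubj"

        return [
            ParsedToken(surface=tokens[i], pos=pos[i], head=head[i], deprel=deprel[i])
            for i in range(n)
        ]

    @staticmethod
    def _subject_of(tokens: Sequence[str], pos: Sequence[str], j: int) -> int | None:
        """Index of the subject noun of the verb at j, or None."""
        i = j - 1
        while i >= 0:
            tok = tokens[i]
            if pos[i] in ("ADV", "AUX"):
                i -= 1
                continue
            if tok.endswith(","):
                # Possibly the closing comma of an appositive ("Skp2, an
                # F-box protein, targets ..."): jump to the head noun,
                # which carries the opening comma.  Without an earlier
                # comma the token itself is the candidate.
                k = i - 1
                while k >= 0 and not tokens[k].endswith(","):
                    k -= 1
                if k >= 0:
                    i = k
            if pos[i] == "NOUN":
                # A noun right after a preposition is a PP object, not the
                # subject; keep walking left past the preposition.
                if i > 0 and pos[i - 1] == "ADP":
                    i -= 2
                    continue
                return i
            return None
        return None


def _raw_token_spans(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]


def find_nsubj_verb(
    sentence: Sentence,
    mention: E3Mention,
    parser: DependencyParser | None = None,
) -> str | None:
    """Surface of the leftmost verb governing the E3 mention as "nsubj".

    Returns ``None`` when the mention is not a verb subject or the parser
    fails (the failure is logged and treated as no match).
    """
    if parser is None:
        parser = HeuristicDependencyParser()
    tokens = sentence.text.split()
    try:
        parsed = parser.parse(tokens)
    except Exception:  # pragma: no cover - defensive
        logger.warning("dependency parse failed for %r; using no-match", sentence.text[:60])
        return None
    spans = _raw_token_spans(sentence.text)
    idx = next(
        (k for k, (s, e) in enumerate(spans) if s <= mention.char_start < e), None
    )
    if idx is None:
        return None
    verbs = []
    # Multi-token mentions: any token of the mention may carry the edge.
    for off in range(max(1, len(mention.surface.split()))):
        i = idx + off
        if i < len(parsed) and parsed[i].deprel == "nsubj" and parsed[i].head >= 0:
            verbs.append(parsed[i].head)
    if not verbs:
        return None
    return parsed[min(verbs)].surface.strip(_STRIP)
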