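"""Seeded synthetic corpus generator.

The manually curated corpus the classifier was designed around (3,195
sentences, 1,056 positives : 2,139 negatives, split 70/30) is not
publicly deposited, so this module generates labeled stand-in corpora
with the same structure: every sentence contains at least one dictionary
E3 ligase; positives instantiate interaction templates (an E3, a
substrate and an interaction trigger such as "ubiquitylates" or
"targets ... for degradation"); negatives mention an E3 without stating
an interaction, including hard cases that contain "ubiquit" or "degrad"
substrings without an interaction claim.  Generation is a pure function
of the :class:`GeneratorConfig`, so the same config yields a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ubisent.corpus import (
    AnnotatedSentence,
    CorpusSplit,
    E3Dictionary,
    Sentence,
    find_e3_mentions,
)

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "default_fixture",
    "generate_benchmark_split",
    "INTERACTION_TRIGGERS",
    "has_interaction_trigger",
    "BENCHMARK_COUNTS",
]

#: Trigger substrings whose presence marks an interaction statement in the
#: generated corpora.  With label noise 0 the rule "positive iff a trigger
#: is present" scores accuracy 1.0 by construction.
INTERACTION_TRIGGERS = (
    "ubiquitylat",
    "ubiquitinat",
    "targets",
    "novel e3 ligase for",
    "direct substrate of",
)

#: Partition sizes emulating the curated corpus: (positives, negatives).
BENCHMARK_COUNTS = {"train": (739, 1497), "test": (317, 642)}


def has_interaction_trigger(text: str) -> bool:
    lowered = text.lower()
    return any(t in lowered for t in INTERACTION_TRIGGERS)


_POSITIVE_TEMPLATES = (
    "{e3} ubiquitylates {sub} and promotes its proteasomal degradation.",
    "These data identify {e3} as a novel E3 ligase for {sub}.",
    "{e3} also targets active {sub} for degradation in cells.",
    "We found that {e3} directly ubiquitylates {sub} in vitro.",
    "{e3} promotes the ubiquitylation and subsequent degradation of {sub}.",
    "Overexpression of {e3} enhanced the polyubiquitylation of {sub}.",
    "{sub} is a direct substrate of the E3 ligase {e3}.",
    "{e3} catalyzes the ubiquitylation of {sub} at multiple lysine residues.",
    "Our results demonstrate that {e3} targets {sub} for proteasome-dependent degradation.",
    "Knockdown of {e3} reduced {sub} ubiquitylation and stabilized the protein.",
    "{e3} binds and ubiquitylates {sub}, thereby controlling its turnover.",
    "The E3 ligase {e3} mediates ubiquitylation of {sub} in response to cellular stress.",
)

_NEGATIVE_TEMPLATES = (
    "{e3} expression was measured in cell lysates by western blotting.",
    "{e3} is a RING-type ubiquitin ligase expressed in brain.",
    "The promoter region of {e3} contains several conserved elements.",
    "Mutations in {e3} have been associated with tumor progression.",
    "{e3} localizes to the nucleus under oxidative stress.",
    "Levels of {e3} mRNA remained unchanged after treatment.",
    "{e3} belongs to the HECT family of ubiquitin ligases.",
    "{e3} and {sub} were both detected in the nuclear fraction.",
    "The crystal structure of {e3} was solved at high resolution.",
    "Expression of {e3} increased during differentiation.",
    "{e3} has been implicated in the regulation of protein degradation pathways.",
    "Recombinant {e3} was purified from bacterial extracts.",
)

_PREFIXES = ("", "Notably, ", "In this study, ", "Interestingly, ", "Consistent with this, ")

_DISTRACTORS = (
    ", as previously reported",
    ", consistent with earlier findings",
    ", although the underlying mechanism remains unclear",
    ", in agreement with independent observations",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic corpus; generation is pure in it."""

    n_positive: int
    n_negative: int
    e3_dict: E3Dictionary
    substrate_names: tuple[str, ...]
    seed: int = 0
    label_noise_rate: float = 0.0
    distractor_rate: float = 0.0
    doc_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be non-negative")
        if self.n_positive + self.n_negative < 1:
            raise ValueError("need at least one sentence")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ValueError("label_noise_rate must be in [0, 1)")
        if not 0.0 <= self.distractor_rate < 1.0:
            raise ValueError("distractor_rate must be in [0, 1)")
        if self.n_positive > 0 and not self.substrate_names:
            raise ValueError("positive sentences require a non-empty substrate list")


def default_fixture() -> tuple[E3Dictionary, tuple[str, ...]]:
    """A built-in E3 dictionary and substrate list for synthetic corpora.

    24 well-known E3 ligases, each with at least two synonym surface
    forms (e.g. Mdm2 / Hdm2 / Oncoprotein Mdm2), and 24 reported
    ubiquitylation substrates (p53, FOXOs, Src, ...).  The fixture is a
    constant: every call returns identical content.
    """
    entries = {
        "MDM2_HUMAN": ("Mdm2", "Hdm2", "Oncoprotein Mdm2"),
        "CBLB_HUMAN": ("Cbl-b", "CBLB"),
        "CBL_HUMAN": ("c-Cbl", "Cbl"),
        "NEDD4_HUMAN": ("Nedd4", "NEDD4-1"),
        "SMUF1_HUMAN": ("Smurf1", "SMURF-1"),
        "SMUF2_HUMAN": ("Smurf2", "SMURF-2"),
        "ITCH_HUMAN": ("Itch", "AIP4"),
        "WWP1_HUMAN": ("WWP1", "Tiul1"),
        "WWP2_HUMAN": ("WWP2", "AIP2"),
        "TRI25_HUMAN": ("TRIM25", "EFP"),
        "RO52_HUMAN": ("TRIM21", "Ro52"),
        "PRKN_HUMAN": ("Parkin", "PARK2"),
        "CHIP_HUMAN": ("CHIP", "STUB1"),
        "VHL_HUMAN": ("pVHL", "VHL"),
        "FBW1A_HUMAN": ("beta-TrCP", "BTRC"),
        "SKP2_HUMAN": ("Skp2", "FBXL1"),
        "FBXW7_HUMAN": ("Fbxw7", "hCdc4"),
        "MARH5_HUMAN": ("MARCH5", "MITOL"),
        "RNF4_HUMAN": ("RNF4", "SNURF"),
        "RNF8_HUMAN": ("RNF8", "KIAA0646"),
        "HUWE1_HUMAN": ("HUWE1", "Mule"),
        "UBR5_HUMAN": ("UBR5", "EDD"),
        "TRAF6_HUMAN": ("TRAF6", "RNF85"),
        "XIAP_HUMAN": ("XIAP", "BIRC4"),
    }
    substrates = (
        "p53", "FOXOs", "Src", "beta-catenin", "cyclin E", "c-Myc",
        "HIF-1alpha", "IkBalpha", "Snail", "Twist1", "PTEN", "p27",
        "p21", "Notch1", "EGFR", "Smad2", "Smad4", "RhoA", "Mcl-1",
        "Nrf2", "c-Jun", "Chk1", "Aurora-A", "Claspin",
    )
    return E3Dictionary(entries=entries), substrates


def _instantiate(
    rng: np.random.Generator,
    template: str,
    dictionary: E3Dictionary,
    substrates: Sequence[str],
    distractor_rate: float,
) -> str:
    cids = dictionary.canonical_ids
    cid = cids[rng.integers(len(cids))]
    synonyms = dictionary.synonyms(cid)
    e3 = synonyms[rng.integers(len(synonyms))]
    sub = substrates[rng.integers(len(substrates))] if substrates else ""
    text = template.format(e3=e3, sub=sub)
    prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
    if prefix:
        # Entity-initial templates keep their capitalization after a prefix.
        if not template.startswith(("{e3}", "{sub}")):
            text = text[0].lower() + text[1:]
        text = prefix + text
    if distractor_rate > 0 and rng.random() < distractor_rate:
        clause = _DISTRACTORS[rng.integers(len(_DISTRACTORS))]
        if text.endswith("."):
            text = text[:-1] + clause + "."
        else:
            text = text + clause
    return text


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedSentence]:
    """Generate exactly ``n_positive`` + ``n_negative`` labeled sentences.

    Positives instantiate interaction templates (E3 + substrate +
    trigger); negatives mention an E3 without an interaction statement.
    With probability ``label_noise_rate`` a sentence's label is flipped
    (its text is untouched, so every sentence still passes the dictionary
    filter).  With probability ``distractor_rate`` a non-informative
    clause is appended.  The output order is a seeded shuffle of the two
    classes.  Identical configs produce identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    items: list[AnnotatedSentence] = []
    plan = [(True, i) for i in range(config.n_positive)] + [
        (False, i) for i in range(config.n_negative)
    ]
    for is_positive, _ in plan:
        templates = _POSITIVE_TEMPLATES if is_positive else _NEGATIVE_TEMPLATES
        template = templates[rng.integers(len(templates))]
        while True:
            text = _instantiate(
                rng, template, config.e3_dict, config.substrate_names, config.distractor_rate
            )
            sentence = Sentence(text=text, doc_id=config.doc_id, sent_index=len(items))
            mentions = find_e3_mentions(sentence, config.e3_dict)
            if mentions:
                break
        label = "positive" if is_positive else "negative"
        if config.label_noise_rate > 0 and rng.random() < config.label_noise_rate:
            label = "negative" if label == "positive" else "positive"
        substrate_spans: tuple[tuple[int, int, str], ...] = ()
        if is_positive:
            # Record the substrate span actually used, if locatable.
            for sub in config.substrate_names:
                pos = text.find(sub)
                if pos >= 0:
                    substrate_spans = ((pos, pos + len(sub), sub),)
                    break
        items.append(
            AnnotatedSentence(
                sentence=sentence,
                label=label,
                e3_mentions=tuple(mentions),
                substrate_spans=substrate_spans,
            )
        )
    order = rng.permutation(len(items))
    shuffled = []
    for new_index, old in enumerate(order):
        item = items[old]
        shuffled.append(
            AnnotatedSentence(
                sentence=Sentence(
                    text=item.sentence.text, doc_id=item.sentence.doc_id, sent_index=new_index
                ),
                label=item.label,
                e3_mentions=item.e3_mentions,
                substrate_spans=item.substrate_spans,
            )
        )
    return shuffled


def generate_benchmark_split(
    seed: int = 0,
    label_noise_rate: float = 0.0,
    distractor_rate: float = 0.0,
) -> CorpusSplit:
    """Train/test corpora with the curated-corpus partition sizes.

    Training: 739 positives + 1497 negatives (2236 sentences); test: 317
    positives + 642 negatives (959 sentences); 3195 sentences total at
    the 1056:2139 class ratio.  Train and test are generated with
    distinct sub-seeds and distinct doc_ids, so they are disjoint.
    """
    dictionary, substrates = default_fixture()
    parts = {}
    for offset, name in enumerate(("train", "test")):
        n_pos, n_neg = BENCHMARK_COUNTS[name]
        config = GeneratorConfig(
            n_positive=n_pos,
            n_negative=n_neg,
            e3_dict=dictionary,
            substrate_names=substrates,
            seed=(seed * 2 + offset) % (2**31),
            label_noise_rate=label_noise_rate,
            distractor_rate=distractor_rate,
            doc_id=f"synthetic-{name}",
        )
        parts[name] = tuple(generate_corpus(config))
    return CorpusSplit(train=parts["train"], test=parts["test"], train_fraction=0.70, seed=seed)
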