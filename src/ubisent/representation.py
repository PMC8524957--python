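"""Five-channel sentence representation for E3-substrate interaction classification.

Each (sentence, E3 mention) instance is described by five information
channels:

1. **semantic** — an embedding of the full sentence text;
2. **e3** — an embedding of the E3 mention's surface form;
3. **position** — a 100-bin one-hot encoding of the mention's relative
   token position (rank 3 of 10 words falls in bin 30);
4. **syntactic** — an embedding of the "nsubj <verb> <E3>" triple when
   the E3 is the nominal subject of a verb, else the zero vector;
5. **strings** — an embedding of the interaction-related string patterns
   ("ubiquit", "target", ...) found in the sentence, else zeros.

Each channel is reduced to ``channel_dim`` (default 100) components by a
PCA fitted on training instances only, the five blocks are concatenated
in the order above (5 x 100 = 500 dimensions by default), and the result
is L2-normalized: v_i -> v_i / max(||v||_p, eps) with p = 2.

:class:`RepresentationBuilder` packages the whole stage as a
scikit-learn transformer so it composes with sklearn pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ubisent.corpus import AnnotatedSentence, E3Mention, Sentence, tokenize
from ubisent.encoders import HashingTextEncoder, TextEncoder
from ubisent.parsing import DependencyParser, HeuristicDependencyParser, find_nsubj_verb

__all__ = [
    "CHANNELS",
    "DEFAULT_PATTERNS",
    "PCAProjector",
    "RepresentationConfig",
    "RepresentationBuilder",
    "encode_semantic",
    "encode_e3",
    "position_feature",
    "syntactic_feature",
    "string_pattern_feature",
    "fit_projectors",
    "l2_normalize",
    "build_representation",
    "expand_instances",
]

logger = logging.getLogger(__name__)

CHANNELS = ("semantic", "e3", "position", "syntactic", "strings")

#: Substring patterns associated with ubiquitylation interaction statements.
#: "ubiquit" covers "ubiquitylation"/"ubiquitylate"/"ubiquitin"; "target"
#: covers "targets"/"targeting".  The list is configurable.
DEFAULT_PATTERNS = ("ubiquit", "target", "degrad", "E3 ligase", "proteasom", "substrate")

POSITION_BINS = 100


@dataclass
class RepresentationConfig:
    """Tunable knobs of the representation stage."""

    encoder: TextEncoder = field(default_factory=HashingTextEncoder)
    pattern_list: tuple[str, ...] = DEFAULT_PATTERNS
    channel_dim: int = 100
    norm_p: float = 2.0
    norm_eps: float = 1e-12
    multi_e3_policy: str = "first_mention"  # or "per_mention"
    per_channel_norm: bool = False
    parser: DependencyParser | None = None

    def __post_init__(self) -> None:
        if not self.pattern_list:
            raise ValueError("pattern_list must be non-empty")
        if self.channel_dim < 1:
            raise ValueError("channel_dim must be positive")
        if self.multi_e3_policy not in ("first_mention", "per_mention"):
            raise ValueError(f"unknown multi_e3_policy {self.multi_e3_policy!r}")


# ---------------------------------------------------------------------------
# Channel features


def encode_semantic(sentence: Sentence, encoder: TextEncoder) -> np.ndarray:
    """Embedding of the full sentence text."""
    return encoder.encode(sentence.text)


def encode_e3(mention: E3Mention, encoder: TextEncoder) -> np.ndarray:
    """Embedding of the E3 mention's bare surface form."""
    return encoder.encode(mention.surface)


def position_feature(sentence: Sentence, mention: E3Mention) -> np.ndarray:
    """One-hot relative position of the E3 among the sentence's words.

    bin = round(100 * token_rank / n_words), clipped to [1, 100]; the
    returned vector has a single 1 at that (1-based) bin.
    """
    n_words = len(tokenize(sentence.text))
    if n_words == 0:
        raise ValueError("sentence has no words")
    if not 1 <= mention.token_rank <= n_words:
        raise ValueError(
            f"token_rank {mention.token_rank} outside [1, {n_words}] for {sentence.text!r}"
        )
    bin_ = int(round(POSITION_BINS * mention.token_rank / n_words))
    bin_ = min(max(bin_, 1), POSITION_BINS)
    vec = np.zeros(POSITION_BINS, dtype=np.float64)
    vec[bin_ - 1] = 1.0
    return vec


def syntactic_feature(
    sentence: Sentence,
    mention: E3Mention,
    encoder: TextEncoder,
    parser: DependencyParser | None = None,
) -> np.ndarray:
    """Embedding of the subject-verb relation carrying the E3, if any.

    When the E3 mention is the "nsubj" of some verb, the string
    ``"nsubj <verb> <E3 surface>"`` is embedded (leftmost verb wins);
    otherwise the zero vector is returned.
    """
    verb = find_nsubj_verb(sentence, mention, parser)
    if verb is None:
        return encoder.encode("")
    return encoder.encode(f"nsubj {verb} {mention.surface}")


def string_pattern_feature(
    sentence: Sentence,
    pattern_list: Sequence[str],
    encoder: TextEncoder,
) -> np.ndarray:
    """Embedding of the interaction string patterns present in the sentence.

    Patterns are matched case-insensitively as substrings, collected in
    ``pattern_list`` order and embedded as a space-joined string; a
    sentence matching nothing encodes to the zero vector.
    """
    if not pattern_list:
        raise ValueError("pattern_list must be non-empty")
    lowered = sentence.text.lower()
    matched = [p for p in pattern_list if p.lower() in lowered]
    return encoder.encode(" ".join(matched))


# ---------------------------------------------------------------------------
# PCA projection


@dataclass
class PCAProjector:
    """Per-channel PCA fitted on training data, padding below-rank output.

    Holds the training mean and the top ``n_components`` principal axes
    (orthonormal rows).  If the attainable rank r is smaller than the
    requested width, only r axes are kept and projected vectors are
    zero-padded to the full width.
    """

    channel: str
    n_components: int
    mean_: np.ndarray | None = None
    components_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.components_ is not None

    def fit(self, X: np.ndarray) -> "PCAProjector":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 training instances")
        k = min(self.n_components, X.shape[0], X.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(X)
        # Keep only axes carrying real variance; the rest would be noise
        # directions of the SVD and are replaced by zero padding.
        tol = max(X.shape) * np.finfo(np.float64).eps * float(pca.singular_values_.max(initial=0.0))
        rank = int(np.sum(pca.singular_values_ > tol))
        if rank < self.n_components:
            logger.info(
                "channel %s: rank %d < %d requested components; zero-padding",
                self.channel, rank, self.n_components,
            )
        self.mean_ = pca.mean_
        self.components_ = pca.components_[:rank]
        return self

    def project(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError(f"projector for channel {self.channel!r} is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        scores = (X - self.mean_) @ self.components_.T
        out = np.zeros((X.shape[0], self.n_components), dtype=np.float64)
        out[:, : scores.shape[1]] = scores
        return out


def _raw_channels(
    instances: Sequence[tuple[Sentence, E3Mention]],
    config: RepresentationConfig,
) -> dict[str, np.ndarray]:
    """Stack raw (pre-PCA) channel vectors for a list of instances."""
    cache: dict[str, np.ndarray] = {}

    def enc(text: str) -> np.ndarray:
        if text not in cache:
            cache[text] = config.encoder.encode(text)
        return cache[text]

    sem, e3, pos, syn, pat = [], [], [], [], []
    for sentence, mention in instances:
        sem.append(enc(sentence.text))
        e3.append(enc(mention.surface))
        pos.append(position_feature(sentence, mention))
        verb = find_nsubj_verb(sentence, mention, config.parser)
        syn.append(enc("" if verb is None else f"nsubj {verb} {mention.surface}"))
        lowered = sentence.text.lower()
        matched = [p for p in config.pattern_list if p.lower() in lowered]
        pat.append(enc(" ".join(matched)))
    return {
        "semantic": np.asarray(sem),
        "e3": np.asarray(e3),
        "position": np.asarray(pos),
        "syntactic": np.asarray(syn),
        "strings": np.asarray(pat),
    }


def fit_projectors(
    instances: Sequence[tuple[Sentence, E3Mention]],
    config: RepresentationConfig,
) -> dict[str, PCAProjector]:
    """Fit one PCA projector per channel on training instances only."""
    if len(instances) < 2:
        raise ValueError("need at least 2 training instances to fit projectors")
    raw = _raw_channels(instances, config)
    return {
        ch: PCAProjector(channel=ch, n_components=config.channel_dim).fit(raw[ch])
        for ch in CHANNELS
    }


def l2_normalize(vector: np.ndarray, p: float = 2.0, eps: float = 1e-12) -> np.ndarray:
    """Scale ``vector`` by 1 / max(||vector||_p, eps).

    With the default p = 2 this is Euclidean normalization; the eps floor
    leaves the zero vector unchanged instead of dividing by zero.
    """
    v = np.asarray(vector, dtype=np.float64)
    norm = float(np.linalg.norm(v.ravel(), ord=p))
    return v / max(norm, eps)


def build_representation(
    sentence: Sentence,
    mention: E3Mention,
    projectors: dict[str, PCAProjector],
    config: RepresentationConfig,
) -> np.ndarray:
    """Assemble the final normalized representation of one instance.

    The five channels are projected to ``channel_dim`` each, concatenated
    in the fixed channel order and L2-normalized as one vector of length
    ``5 * channel_dim`` (500 by default).
    """
    raw = _raw_channels([(sentence, mention)], config)
    blocks = []
    for ch in CHANNELS:
        proj = projectors[ch].project(raw[ch])[0]
        if config.per_channel_norm:
            proj = l2_normalize(proj, config.norm_p, config.norm_eps)
        blocks.append(proj)
    vec = np.concatenate(blocks)
    if not config.per_channel_norm:
        vec = l2_normalize(vec, config.norm_p, config.norm_eps)
    return vec


def expand_instances(
    corpus: Iterable[AnnotatedSentence],
    policy: str = "first_mention",
) -> tuple[list[tuple[Sentence, E3Mention]], np.ndarray]:
    """Turn annotated sentences into (sentence, mention) instances + labels.

    ``first_mention`` keeps one instance per sentence keyed to the
    leftmost E3 mention (so instance counts equal sentence counts);
    ``per_mention`` emits one instance per E3 mention.  Labels are 1 for
    positive, 0 for negative, -1 for unlabeled.
    """
    instances: list[tuple[Sentence, E3Mention]] = []
    labels: list[int] = []
    for item in corpus:
        mentions = sorted(item.e3_mentions, key=lambda m: m.char_start)
        chosen = mentions if policy == "per_mention" else mentions[:1]
        for m in chosen:
            instances.append((item.sentence, m))
            labels.append({"positive": 1, "negative": 0, None: -1}[item.label])
    return instances, np.asarray(labels, dtype=np.int64)


class RepresentationBuilder(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping the whole representation stage.

    ``fit`` accepts a list of :class:`AnnotatedSentence` (or bare
    (sentence, mention) pairs), fits the per-channel PCA projectors on
    those instances only, and ``transform`` maps further sentences to the
    concatenated, normalized feature matrix of shape
    ``(n, 5 * channel_dim)``.

    Parameters mirror :class:`RepresentationConfig`.
    """

    def __init__(
        self,
        encoder: TextEncoder | None = None,
        pattern_list: tuple[str, ...] = DEFAULT_PATTERNS,
        channel_dim: int = 100,
        norm_p: float = 2.0,
        norm_eps: float = 1e-12,
        multi_e3_policy: str = "first_mention",
        per_channel_norm: bool = False,
        parser: DependencyParser | None = None,
    ) -> None:
        self.encoder = encoder
        self.pattern_list = pattern_list
        self.channel_dim = channel_dim
        self.norm_p = norm_p
        self.norm_eps = norm_eps
        self.multi_e3_policy = multi_e3_policy
        self.per_channel_norm = per_channel_norm
        self.parser = parser

    def _config(self) -> RepresentationConfig:
        return RepresentationConfig(
            encoder=self.encoder if self.encoder is not None else HashingTextEncoder(),
            pattern_list=tuple(self.pattern_list),
            channel_dim=self.channel_dim,
            norm_p=self.norm_p,
            norm_eps=self.norm_eps,
            multi_e3_policy=self.multi_e3_policy,
            per_channel_norm=self.per_channel_norm,
            parser=self.parser,
        )

    @staticmethod
    def _as_instances(X, policy: str) -> list[tuple[Sentence, E3Mention]]:
        items = list(X)
        if items and isinstance(items[0], AnnotatedSentence):
            instances, _ = expand_instances(items, policy)
            return instances
        return items

    def fit(self, X, y=None) -> "RepresentationBuilder":
        config = self._config()
        instances = self._as_instances(X, config.multi_e3_policy)
        self.projectors_ = fit_projectors(instances, config)
        self.n_features_out_ = 5 * config.channel_dim
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "projectors_"):
            raise RuntimeError("RepresentationBuilder is not fitted")
        config = self._config()
        instances = self._as_instances(X, config.multi_e3_policy)
        raw = _raw_channels(instances, config)
        blocks = []
        for ch in CHANNELS:
            proj = self.projectors_[ch].project(raw[ch])
            if config.per_channel_norm:
                norms = np.linalg.norm(proj, ord=config.norm_p, axis=1, keepdims=True)
                proj = proj / np.maximum(norms, config.norm_eps)
            blocks.append(proj)
        M = np.concatenate(blocks, axis=1)
        if not config.per_channel_norm:
            norms = np.linalg.norm(M, ord=config.norm_p, axis=1, keepdims=True)
            M = M / np.maximum(norms, config.norm_eps)
        return M
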