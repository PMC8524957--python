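"""End-to-end convenience wrappers: representation + classifier as one unit."""

from __future__ import annotations

from typing import Sequence

from sklearn.pipeline import Pipeline

from ubisent.corpus import AnnotatedSentence, CorpusSplit
from ubisent.evaluation import evaluate_model
from ubisent.lstm import LSTMSentenceClassifier
from ubisent.metrics import MetricsReport
from ubisent.representation import RepresentationBuilder, expand_instances
from ubisent.synthetic import generate_benchmark_split

__all__ = ["make_pipeline", "fit_evaluate", "run_benchmark"]


def make_pipeline(
    channel_dim: int = 100,
    epochs: int = 10,
    seed: int = 0,
    **classifier_kwargs,
) -> Pipeline:
    """Representation builder + LSTM classifier as one sklearn pipeline."""
    return Pipeline(
        [
            ("representation", RepresentationBuilder(channel_dim=channel_dim)),
            (
                "classifier",
                LSTMSentenceClassifier(epochs=epochs, seed=seed, **classifier_kwargs),
            ),
        ]
    )


def fit_evaluate(
    train_corpus: Sequence[AnnotatedSentence],
    test_corpus: Sequence[AnnotatedSentence],
    channel_dim: int = 100,
    epochs: int = 10,
    seed: int = 0,
    **classifier_kwargs,
) -> tuple[Pipeline, dict[str, MetricsReport]]:
    """Fit the full pipeline on the training corpus, evaluate both partitions."""
    instances_train, y_train = expand_instances(train_corpus)
    instances_test, y_test = expand_instances(test_corpus)
    pipe = make_pipeline(channel_dim=channel_dim, epochs=epochs, seed=seed, **classifier_kwargs)
    pipe.fit(instances_train, y_train)
    return pipe, {
        "train": evaluate_model(pipe, instances_train, y_train),
        "test": evaluate_model(pipe, instances_test, y_test),
    }


def run_benchmark(
    seed: int = 0,
    epochs: int = 10,
    channel_dim: int = 100,
    label_noise_rate: float = 0.0,
    distractor_rate: float = 0.0,
    **classifier_kwargs,
) -> tuple[CorpusSplit, Pipeline, dict[str, MetricsReport]]:
    """Full pipeline on the synthetic benchmark corpus (2236 train / 959 test)."""
    split = generate_benchmark_split(
        seed=seed, label_noise_rate=label_noise_rate, distractor_rate=distractor_rate
    )
    pipe, reports = fit_evaluate(
        split.train,
        split.test,
        channel_dim=channel_dim,
        epochs=epochs,
        seed=seed,
        **classifier_kwargs,
    )
    return split, pipe, reports
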