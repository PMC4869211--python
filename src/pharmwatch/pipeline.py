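"""End-to-end orchestration: ingest -> keyword match -> FTC drop -> exclusion
cascade -> non-English removal -> featurize -> classify -> threshold.

The report records the surviving count after every stage (monotonically
non-increasing), the calibrated threshold, and the classifier operating
point; given the same config and seed the report is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import filtering, io
from ._util import spawn_rngs
from .features import (
    ClassifierSettings,
    TrainedClassifier,
    calibrate_threshold,
    evaluate,
    extract_features,
    fit_token_models,
    train,
)
from .sentiment import ConsensusSet, consensus
from .types import RaterAnnotation, Tweet


@dataclass
class PipelineConfig:
    keywords: tuple[str, ...] = filtering.KEYWORDS
    stages: tuple = filtering.DEFAULT_STAGES
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    target_efficiency: float = 0.90
    english_threshold: float = 0.15
    bin_days: int = 60
    calibration_fraction: float = 0.4  # share of consensus signal held out for tau
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_efficiency <= 1:
            raise ValueError("target efficiency must be in (0, 1]")
        if self.bin_days < 1:
            raise ValueError("bin width must be at least 1 day")


@dataclass
class RunReport:
    stage_counts: list[tuple[str, int]]
    threshold: Optional[float]
    signal_efficiency: Optional[float]  # on the held-out calibration signal
    noise_rejection: Optional[float]  # on the consensus noise sample
    classifier_skipped: bool
    final_ids: list[str]
    seed: int

    def to_json(self) -> str:
        d = asdict(self)
        d["n_final"] = len(self.final_ids)
        return json.dumps(d, sort_keys=True, indent=2)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _split_ids(ids: Sequence[str], fraction_held_out: float, rng: np.random.Generator):
    ids = sorted(ids)
    n_cal = max(1, int(round(fraction_held_out * len(ids)))) if len(ids) > 1 else len(ids)
    perm = rng.permutation(len(ids))
    cal = {ids[i] for i in perm[:n_cal]}
    tr = {ids[i] for i in perm[n_cal:]} or cal  # tiny sets: reuse
    return tr, cal


def train_and_classify(
    survivors: Sequence[Tweet],
    training_tweets_by_id: dict[str, Tweet],
    labels: ConsensusSet,
    config: PipelineConfig,
) -> tuple[Optional[TrainedClassifier], Optional[float], list[Tweet], dict]:
    """Train on consensus-labeled tweets, calibrate tau, and score survivors.

    Returns (classifier, tau, final signal tweets, info). When the consensus
    labels cover a single class no classifier can be trained; the stage is
    skipped and all survivors pass through, flagged in `info`.
    """
    rng_split, _ = spawn_rngs(config.seed, 2)
    signal_ids = sorted(i for i in labels.signal_ids if i in training_tweets_by_id)
    noise_ids = sorted(i for i in labels.noise_ids if i in training_tweets_by_id)
    if not signal_ids or not noise_ids:
        return None, None, list(survivors), {"classifier_skipped": True}

    train_sig, cal_sig = _split_ids(signal_ids, config.calibration_fraction, rng_split)
    sig_tweets = [training_tweets_by_id[i] for i in sorted(train_sig)]
    noi_tweets = [training_tweets_by_id[i] for i in noise_ids]
    models = fit_token_models(sig_tweets, noi_tweets)

    feats = lambda tws: [extract_features(t, models) for t in tws]
    settings = ClassifierSettings(
        family=config.classifier.family, seed=config.seed, params=dict(config.classifier.params)
    )
    clf = train(feats(sig_tweets), feats(noi_tweets), settings)
    cal_feats = feats([training_tweets_by_id[i] for i in sorted(cal_sig)])
    tau = calibrate_threshold(clf, cal_feats, config.target_efficiency)
    ev = evaluate(clf, tau, cal_feats, feats(noi_tweets))

    surv_scores = clf.score(feats(survivors)) if survivors else np.empty(0)
    final = [t for t, s in zip(survivors, surv_scores) if s >= tau]
    info = {
        "classifier_skipped": False,
        "signal_efficiency": ev.signal_efficiency,
        "noise_rejection": ev.noise_rejection,
        "models": models,
        "classifier": clf,
    }
    return clf, tau, final, info


def run_pipeline_tweets(
    tweets: Sequence[Tweet],
    annotations: Sequence[RaterAnnotation],
    config: PipelineConfig,
    training_tweets: Optional[Sequence[Tweet]] = None,
) -> RunReport:
    """Run the full cascade + classification over in-memory tweets.

    `training_tweets` supplies the texts behind the annotation tweet_ids when
    they come from a reference corpus other than `tweets` (defaults to
    `tweets` itself).
    """
    counts: list[tuple[str, int]] = [("ingested", len(tweets))]
    try:
        matched = [
            t for t in tweets
            if filtering.match_keywords(filtering.tokenize_ordered(t.text), config.keywords)
        ]
    except Exception as exc:  # pragma: no cover
        raise StageError("keyword-match", exc)
    counts.append(("keyword-matched", len(matched)))

    current = filtering.drop_ftc_subsample(matched, config.keywords)
    counts.append(("ftc-dropped", len(current)))

    current, reports = filtering.apply_cascade(current, config.stages)
    for rep in reports:
        counts.append((rep.stage, rep.n_surviving))

    detector = filtering.EnglishDetector(threshold=config.english_threshold)
    current = filtering.remove_non_english(current, detector)
    counts.append(("english", len(current)))

    lookup = {t.tweet_id: t for t in (training_tweets if training_tweets is not None else tweets)}
    try:
        labels = consensus(annotations)
    except Exception as exc:
        raise StageError("consensus", exc)
    try:
        clf, tau, final, info = train_and_classify(current, lookup, labels, config)
    except Exception as exc:
        raise StageError("classify", exc)
    counts.append(("classified", len(final)))

    return RunReport(
        stage_counts=counts,
        threshold=tau,
        signal_efficiency=info.get("signal_efficiency"),
        noise_rejection=info.get("noise_rejection"),
        classifier_skipped=info["classifier_skipped"],
        final_ids=sorted(t.tweet_id for t in final),
        seed=config.seed,
    )


def run_pipeline(
    config: PipelineConfig,
    corpus_path: str | Path,
    annotations_path: str | Path,
    training_corpus_path: Optional[str | Path] = None,
) -> RunReport:
    """File-level entry point: JSONL corpus + CSV annotations -> run report."""
    tweets = io.read_corpus(corpus_path)
    annotations = io.read_annotations(annotations_path)
    training = io.read_corpus(training_corpus_path) if training_corpus_path else None
    return run_pipeline_tweets(tweets, annotations, config, training)
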