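"""The drug-name-recognition model: featurize, select, train, predict.

:class:`DrugNER` is constructed from annotated sentences plus a feature
configuration; :meth:`DrugNER.fit` runs the pipeline — singleton feature
extraction over the 5-token window, optional S1/S2 conjunction features,
optional chi-square / mutual-information / information-gain feature
selection, then CRF training — and returns a :class:`DrugNERResults` that
predicts, evaluates and summarizes.

    >>> model = DrugNER(train_sentences, extractor, feature_config)
    >>> res = model.fit()
    >>> res.evaluate(test_sentences, "strict").f1
    >>> print(res.summary())
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluation
from .conjunction import ConjunctionTemplateSet, apply_conjunctions
from .corpus import (
    DEFAULT_ENTITY_TYPES,
    AnnotatedSentence,
    TypedTag,
    decode_bilou,
    encode_bilou,
    tag_inventory,
)
from .crf import LinearChainCRF, build_feature_vocab, vectorize_sentence
from .evaluation import EvalScores
from .features import SentenceFeatureExtractor
from .selection import ImportanceTable, score_features, select_top_fraction

logger = logging.getLogger(__name__)

#: The regularization grid searched by default, 0.5 to 1.5 in steps of 0.1.
DEFAULT_C2_GRID: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class FeatureConfig:
    """What the tagger sees: conjunction sets and selection policy."""

    conjunctions: ConjunctionTemplateSet | None = None
    selection_statistic: str | None = None  # None, "chi2", "mi" or "ig"
    selection_fraction: float = 1.0
    typed_selection: bool = False


@dataclass
class TrainConfig:
    """CRF training knobs; ``c2`` is the L2 regularization coefficient."""

    c2: float = 1.0
    c2_grid: tuple[float, ...] = DEFAULT_C2_GRID
    cv_folds: int = 10
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c2_grid):
            raise ValueError("grid values must be positive")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 folds")


class DrugNER:
    """CRF-based drug name recognizer over engineered sparse features.

    Parameters
    ----------
    sentences : training corpus of :class:`AnnotatedSentence`.
    extractor : configured :class:`SentenceFeatureExtractor` (templates,
        tagger, dictionaries, embedding clusters).
    feature_config : conjunction and selection policy.
    train_config : CRF regularization / optimization settings.
    entity_types : the closed type set; the label alphabet is the BILOU
        inventory over it (17 tags for the four DDI types).
    """

    def __init__(
        self,
        sentences: Sequence[AnnotatedSentence],
        extractor: SentenceFeatureExtractor | None = None,
        feature_config: FeatureConfig | None = None,
        train_config: TrainConfig | None = None,
        entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES,
    ) -> None:
        if not sentences:
            raise ValueError("empty training corpus")
        self.sentences = list(sentences)
        self.extractor = extractor if extractor is not None else SentenceFeatureExtractor()
        self.feature_config = feature_config or FeatureConfig()
        self.train_config = train_config or TrainConfig()
        self.entity_types = tuple(entity_types)
        self.labels = [str(t) for t in tag_inventory(self.entity_types)]
        self._train_features: list[list[list[str]]] | None = None
        self._train_tags: list[list[TypedTag]] | None = None

    # -- featurization -----------------------------------------------------

    def featurize(self, sentence: AnnotatedSentence) -> list[list[str]]:
        """Serialized singleton (+ conjunction) features, one list per token."""
        base = self.extractor.base_values(sentence)
        singles = self.extractor.extract(sentence)
        per_token = [[str(f) for f in feats] for feats in singles]
        if self.feature_config.conjunctions is not None:
            conj = apply_conjunctions(
                self.extractor, sentence, self.feature_config.conjunctions, base=base
            )
            for toks, extra in zip(per_token, conj):
                toks.extend(str(f) for f in extra)
        return per_token

    def _training_data(self) -> tuple[list[list[list[str]]], list[list[TypedTag]]]:
        if self._train_features is None:
            self._train_features = [self.featurize(s) for s in self.sentences]
            self._train_tags = [encode_bilou(s) for s in self.sentences]
        return self._train_features, self._train_tags

    # -- selection ---------------------------------------------------------

    def importance_table(self, statistic: str | None = None) -> ImportanceTable:
        """Score every training feature with the configured statistic."""
        statistic = statistic or self.feature_config.selection_statistic or "ig"
        feats, tags = self._training_data()
        flat_feats = [set(tf) for sent in feats for tf in sent]
        flat_tags = [t for sent in tags for t in sent]
        return score_features(
            flat_feats, flat_tags, statistic, typed=self.feature_config.typed_selection
        )

    @staticmethod
    def assemble_instances(
        sentence_features: Sequence[Sequence[Sequence[str]]],
        retained: set[str] | None,
    ) -> list[list[list[str]]]:
        """Drop features outside the retained set (None keeps everything)."""
        if not sentence_features:
            raise ValueError("empty corpus")
        if retained is None:
            return [[list(tf) for tf in sent] for sent in sentence_features]
        if not retained:
            logger.warning("retained feature set is empty; instances carry no features")
        before = sum(len(tf) for sent in sentence_features for tf in sent)
        out = [
            [[f for f in tf if f in retained] for tf in sent]
            for sent in sentence_features
        ]
        after = sum(len(tf) for sent in out for tf in sent)
        logger.info("feature filtering kept %d of %d feature tokens", after, before)
        return out

    # -- fitting -----------------------------------------------------------

    def fit(self, c2: float | None = None) -> "DrugNERResults":
        """Run selection (if configured) and CRF training."""
        feats, tags = self._training_data()
        cfg = self.feature_config
        importance = None
        retained = None
        if cfg.selection_statistic is not None:
            importance = self.importance_table(cfg.selection_statistic)
            retained = set(select_top_fraction(importance, cfg.selection_fraction))
        inst = self.assemble_instances(feats, retained)
        vocab = build_feature_vocab(inst)
        tcfg = self.train_config if c2 is None else replace(self.train_config, c2=c2)
        crf = LinearChainCRF(
            labels=list(self.labels),
            vocab=vocab,
            c2=tcfg.c2,
            max_iter=tcfg.max_iter,
        )
        mats = [vectorize_sentence(sent, vocab) for sent in inst]
        labels = [[str(t) for t in sent] for sent in tags]
        crf.fit(mats, labels)
        n_total = len(importance) if importance is not None else len(vocab)
        return DrugNERResults(
            model=self,
            crf=crf,
            retained=retained,
            importance=importance,
            n_features_total=n_total,
        )

    # -- regularization tuning --------------------------------------------

    @staticmethod
    def fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
        """Sentence-level fold labels: a seeded permutation dealt round-robin,
        so fold sizes differ by at most one and every sentence validates in
        exactly one fold."""
        order = np.random.default_rng(seed).permutation(n)
        fold_of = np.empty(n, dtype=int)
        for pos, idx in enumerate(order):
            fold_of[idx] = pos % folds
        return fold_of

    def tune_regularization(
        self,
        grid: Sequence[float] | None = None,
        folds: int | None = None,
        seed: int | None = None,
    ) -> tuple[float, dict[float, float]]:
        """Grid-search c2 by K-fold cross-validated strict F1.

        Folds partition sentences (each sentence validates exactly once);
        the split is deterministic under the seed.  Returns the best value
        (ties broken toward smaller c2) and the full per-value score table.
        """
        grid = tuple(grid) if grid is not None else self.train_config.c2_grid
        folds = folds if folds is not None else self.train_config.cv_folds
        seed = seed if seed is not None else self.train_config.seed
        n = len(self.sentences)
        if n < folds:
            raise ValueError(f"{n} sentences cannot fill {folds} folds")
        fold_of = self.fold_assignment(n, folds, seed)

        scores: dict[float, float] = {}
        for c2 in grid:
            total = EvalScores(0, 0, 0)
            for k in range(folds):
                train_idx = [i for i in range(n) if fold_of[i] != k]
                val_idx = [i for i in range(n) if fold_of[i] == k]
                sub = DrugNER(
                    [self.sentences[i] for i in train_idx],
                    extractor=self.extractor,
                    feature_config=self.feature_config,
                    train_config=replace(self.train_config, c2=c2),
                    entity_types=self.entity_types,
                )
                res = sub.fit()
                val = [self.sentences[i] for i in val_idx]
                total = total + res.evaluate(val, "strict")
            scores[c2] = total.f1
            logger.info("c2=%.2f: CV strict F1 = %.2f", c2, total.f1)
        best = max(scores, key=lambda c: (scores[c], -c))
        return best, scores


class DrugNERResults:
    """A fitted recognizer: prediction, evaluation and a summary table."""

    def __init__(
        self,
        model: DrugNER,
        crf: LinearChainCRF,
        retained: set[str] | None,
        importance: ImportanceTable | None,
        n_features_total: int,
    ) -> None:
        self.model = model
        self.crf = crf
        self.retained = retained
        self.importance = importance
        self.n_features_total = n_features_total
        self.n_features_used = len(crf.vocab)

    # -- prediction --------------------------------------------------------

    def predict_tags(self, sentence: AnnotatedSentence) -> list[TypedTag]:
        feats = self.model.featurize(sentence)
        if self.retained is not None:
            feats = [[f for f in tf if f in self.retained] for tf in feats]
        X = vectorize_sentence(feats, self.crf.vocab)
        return [TypedTag.parse(l) for l in self.crf.predict(X)]

    def predict(self, sentences: Sequence[AnnotatedSentence]) -> list[list[TypedTag]]:
        return [self.predict_tags(s) for s in sentences]

    def predict_mentions(self, sentence: AnnotatedSentence):
        """Predicted tags decoded to mentions (lenient repair of rare
        ill-formed transition patterns)."""
        tags = self.predict_tags(sentence)
        return decode_bilou(tags, sentence.tokens, text=sentence.text, strict=False)

    def annotate(self, sentence: AnnotatedSentence) -> AnnotatedSentence:
        """A copy of ``sentence`` carrying the predicted mentions."""
        return AnnotatedSentence(
            sentence.text,
            list(sentence.tokens),
            self.predict_mentions(sentence),
            doc_id=sentence.doc_id,
        )

    # -- evaluation ---------------------------------------------------------

    def evaluate(
        self, sentences: Sequence[AnnotatedSentence], criterion: str = "strict"
    ) -> EvalScores:
        gold = [s.mentions for s in sentences]
        pred = [self.predict_mentions(s) for s in sentences]
        return evaluation.score(gold, pred, criterion)

    def evaluation_report(self, sentences: Sequence[AnnotatedSentence]) -> str:
        gold = [s.mentions for s in sentences]
        pred = [self.predict_mentions(s) for s in sentences]
        return evaluation.report(gold, pred)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.feature_config
        conj = cfg.conjunctions.name if cfg.conjunctions is not None else "none"
        sel = (
            f"{cfg.selection_statistic} @ {cfg.selection_fraction:.0%}"
            if cfg.selection_statistic
            else "none"
        )
        n_tok = sum(len(s) for s in self.model.sentences)
        rows = [
            ("No. sentences", len(self.model.sentences)),
            ("No. tokens", n_tok),
            ("Label alphabet", len(self.crf.labels)),
            ("Singleton templates", len(self.model.extractor.templates)),
            ("Conjunction set", conj),
            ("Feature selection", sel),
            ("Features (all)", self.n_features_total),
            ("Features (used)", self.n_features_used),
            ("Regularization c2", self.crf.c2),
            ("Converged", self.crf.converged),
        ]
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Drug Name Recognition CRF", "=" * (width + 20)]
        lines += [f"{k + ':':<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist CRF weights (.npz) and a JSON sidecar of the retained set."""
        path = Path(path)
        self.crf.save(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "retained": sorted(self.retained) if self.retained is not None else None,
                    "n_features_total": self.n_features_total,
                    "entity_types": list(self.model.entity_types),
                }
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path, model: DrugNER) -> "DrugNERResults":
        """Rebind persisted weights to a :class:`DrugNER` carrying the same
        extractor/feature configuration used at training time."""
        path = Path(path)
        crf = LinearChainCRF.load(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        retained = set(meta["retained"]) if meta["retained"] is not None else None
        return cls(
            model=model,
            crf=crf,
            retained=retained,
            importance=None,
            n_features_total=meta["n_features_total"],
        )
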