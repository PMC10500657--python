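"""Cross-ontology score alignment.

Answers to one question arrive from several per-ontology QA engines, each
trained independently and possibly under a different embedding method, so
their scores live on incomparable scales.  The baseline remedy is max
normalization: divide each engine's scores by its own maximum and merge.
That erases scale information entirely — every engine's top answer lands at
exactly 1.0 — so the merged top-1 is decided by ties rather than evidence.

The alignment model instead learns, per ontology ``o``, a scale ``w_o`` and a
question-dependent bias ``u_o . phi(q)`` (binary bag-of-words features plus
an intercept), and reranks with

    s' = w_o * s_norm + u_o . phi(q) .

Training minimizes a pairwise hinge that pushes each gold answer above every
non-gold answer after adjustment.  ``w_o`` is kept positive, so the
adjustment is monotone within an ontology: only the cross-ontology
interleaving can change.  The question-ontology affiliation itself is
exposed through a bag-of-words naive-Bayes classifier (per-label priors are
returned exactly for a featureless question).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import rank_of
from .qa import ScoredCandidate

__all__ = [
    "AlignmentExample", "AlignmentModel",
    "normalize_scores_baseline", "compute_affiliation",
    "train_alignment", "rerank_cross_ontology", "merged_gold_ranks",
]

logger = logging.getLogger(__name__)

_TOKEN = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> list[str]:
    return _TOKEN.findall(text.lower())


@dataclass
class AlignmentExample:
    """One training item: a question, its gold answer, and per-engine answers."""

    question: str
    gold_entity: str
    gold_ontology: str
    answers: dict[str, list[ScoredCandidate]]  # ontology label -> candidates


# ---------------------------------------------------------------------------
# Max-normalization baseline


def normalize_scores_baseline(
    answers: dict[str, list[ScoredCandidate]],
) -> list[ScoredCandidate]:
    """Merge per-ontology answers after dividing each list by its maximum.

    Operates on polarity-normalized scores (higher = better).  A list whose
    maximum is not positive is mapped to all zeros with a logged warning.
    Sorted descending; ties broken by (ontology label, entity id).
    """
    merged: list[ScoredCandidate] = []
    for ont in sorted(answers):
        cands = answers[ont]
        if not cands:
            continue
        top = max(c.normalized_score for c in cands)
        if top <= 0:
            logger.warning("ontology %r has non-positive maximum score %.4g; "
                           "its scores are mapped to 0", ont, top)
            scale = None
        else:
            scale = top
        for c in cands:
            s = c.normalized_score / scale if scale else 0.0
            merged.append(ScoredCandidate(
                entity=c.entity, score=c.score, normalized_score=s,
                ontology_label=c.ontology_label, numeric_values=c.numeric_values,
            ))
    merged.sort(key=lambda c: (-c.normalized_score, c.ontology_label, c.entity))
    return merged


# ---------------------------------------------------------------------------
# Affiliation classifier (bag-of-words naive Bayes, one-vs-rest per ontology)


@dataclass
class _AffiliationNB:
    vocabulary: dict[str, int]
    priors: dict[str, float]                  # ontology -> base rate
    log_likelihood: dict[str, np.ndarray]     # ontology -> (2, V) word log-probs
    smoothing: float = 1.0

    def predict(self, question: str) -> dict[str, float]:
        # presence-only scoring: a featureless question falls back to the
        # class prior exactly
        toks = set(_tokens(question))
        present = np.zeros(len(self.vocabulary), dtype=bool)
        for t in toks:
            idx = self.vocabulary.get(t)
            if idx is not None:
                present[idx] = True
        out = {}
        for ont, prior in self.priors.items():
            ll_pos = float(self.log_likelihood[ont][1][present].sum())
            ll_neg = float(self.log_likelihood[ont][0][present].sum())
            logit = math.log(prior / (1 - prior)) + ll_pos - ll_neg if 0 < prior < 1 else (
                math.inf if prior >= 1 else -math.inf)
            out[ont] = 1.0 / (1.0 + math.exp(-logit)) if math.isfinite(logit) else (
                1.0 if logit > 0 else 0.0)
        return out


def _fit_affiliation(questions: Sequence[str], gold_onts: Sequence[str],
                     smoothing: float = 1.0) -> _AffiliationNB:
    vocab: dict[str, int] = {}
    for q in questions:
        for t in _tokens(q):
            vocab.setdefault(t, len(vocab))
    V = len(vocab)
    onts = sorted(set(gold_onts))
    X = np.zeros((len(questions), V), dtype=bool)
    for i, q in enumerate(questions):
        for t in set(_tokens(q)):
            X[i, vocab[t]] = True
    priors, ll = {}, {}
    for ont in onts:
        y = np.array([g == ont for g in gold_onts])
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        priors[ont] = n_pos / len(y)
        p_pos = (X[y].sum(axis=0) + smoothing) / (n_pos + 2 * smoothing)
        p_neg = (X[~y].sum(axis=0) + smoothing) / (n_neg + 2 * smoothing)
        # rows: log p(word|other classes), log p(word|this class)
        ll[ont] = np.stack([np.log(p_neg), np.log(p_pos)])
    return _AffiliationNB(vocabulary=vocab, priors=priors, log_likelihood=ll,
                          smoothing=smoothing)


# ---------------------------------------------------------------------------
# Alignment model


@dataclass
class AlignmentModel:
    """Per-ontology affine score adjustment with question-dependent bias."""

    ontologies: list[str]
    vocabulary: dict[str, int]
    scale: dict[str, float]                 # w_o > 0
    bias_weights: dict[str, np.ndarray]     # u_o, length V + 1 (intercept last)
    affiliation: _AffiliationNB | None = None
    training_trace: list[float] = field(default_factory=list)

    def features(self, question: str) -> np.ndarray:
        phi = np.zeros(len(self.vocabulary) + 1)
        for t in set(_tokens(question)):
            idx = self.vocabulary.get(t)
            if idx is not None:
                phi[idx] = 1.0
        phi[-1] = 1.0
        return phi

    def adjust(self, question: str, ont: str, normalized_score: float) -> float:
        if ont not in self.scale:
            raise KeyError(f"ontology {ont!r} unknown to the alignment model")
        return self.scale[ont] * normalized_score + float(
            self.bias_weights[ont] @ self.features(question))

    def save(self, path) -> None:
        payload = {
            "ontologies": self.ontologies,
            "vocabulary": self.vocabulary,
            "scale": self.scale,
            "bias_weights": {o: w.tolist() for o, w in self.bias_weights.items()},
            "training_trace": self.training_trace,
        }
        if self.affiliation is not None:
            payload["affiliation"] = {
                "priors": self.affiliation.priors,
                "log_likelihood": {o: a.tolist()
                                   for o, a in self.affiliation.log_likelihood.items()},
                "smoothing": self.affiliation.smoothing,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "AlignmentModel":
        with open(path) as fh:
            payload = json.load(fh)
        aff = None
        if "affiliation" in payload:
            a = payload["affiliation"]
            aff = _AffiliationNB(
                vocabulary=payload["vocabulary"],
                priors=a["priors"],
                log_likelihood={o: np.array(v) for o, v in a["log_likelihood"].items()},
                smoothing=a["smoothing"],
            )
        return cls(
            ontologies=payload["ontologies"],
            vocabulary=payload["vocabulary"],
            scale=payload["scale"],
            bias_weights={o: np.array(w) for o, w in payload["bias_weights"].items()},
            affiliation=aff,
            training_trace=payload.get("training_trace", []),
        )


def compute_affiliation(question_text: str, model: AlignmentModel) -> dict[str, float]:
    """Per-ontology affiliation probabilities for a question.

    A featureless (empty) question returns each ontology's training base rate.
    """
    if model.affiliation is None:
        raise ValueError("alignment model was trained without affiliation data")
    return model.affiliation.predict(question_text)


def train_alignment(
    training_set: Sequence[AlignmentExample],
    seed: int = 0,
    margin: float = 0.1,
    learning_rate: float = 0.05,
    epochs: int = 200,
    min_scale: float = 0.01,
) -> AlignmentModel:
    """Fit the per-ontology affine adjustment by pairwise margin SGD.

    Each epoch visits the examples in a seeded random order; for every
    (gold, non-gold) answer pair the hinge ``max(0, margin - (s'_gold -
    s'_other))`` is stepped.  ``w_o`` is clamped to stay positive so
    within-ontology order is preserved.  Reproducible by seed.
    """
    onts = sorted({ont for ex in training_set for ont in ex.answers})
    if len(onts) < 2:
        raise ValueError("score alignment needs answers from at least 2 ontologies")
    vocab: dict[str, int] = {}
    for ex in training_set:
        for t in _tokens(ex.question):
            vocab.setdefault(t, len(vocab))
    V = len(vocab)
    scale = {o: 1.0 for o in onts}
    bias = {o: np.zeros(V + 1) for o in onts}
    model = AlignmentModel(ontologies=onts, vocabulary=vocab, scale=scale,
                           bias_weights=bias)

    norm_cache = [
        {ont: normalize_scores_baseline({ont: cands})
         for ont, cands in ex.answers.items() if cands}
        for ex in training_set
    ]
    feats = [model.features(ex.question) for ex in training_set]

    rng = np.random.default_rng(seed)
    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(training_set))
        epoch_loss, n_pairs = 0.0, 0
        for i in order:
            ex = training_set[i]
            phi = feats[i]
            flat = [(c.ontology_label, c.entity, c.normalized_score)
                    for cands in norm_cache[i].values() for c in cands]
            gold = [(o, e, s) for o, e, s in flat
                    if o == ex.gold_ontology and e == ex.gold_entity]
            if not gold:
                continue
            go, _, gs = gold[0]
            g_adj = scale[go] * gs + bias[go] @ phi
            for o, e, s in flat:
                if o == ex.gold_ontology and e == ex.gold_entity:
                    continue
                adj = scale[o] * s + bias[o] @ phi
                hinge = margin - (g_adj - adj)
                n_pairs += 1
                if hinge > 0:
                    epoch_loss += hinge
                    scale[go] += learning_rate * gs
                    bias[go] += learning_rate * phi
                    scale[o] -= learning_rate * s
                    bias[o] -= learning_rate * phi
                    scale[go] = max(scale[go], min_scale)
                    scale[o] = max(scale[o], min_scale)
                    g_adj = scale[go] * gs + bias[go] @ phi
        trace.append(epoch_loss / max(n_pairs, 1))
    model.training_trace = trace

    model.affiliation = _fit_affiliation(
        [ex.question for ex in training_set],
        [ex.gold_ontology for ex in training_set],
    )
    return model


def rerank_cross_ontology(
    question_text: str,
    answers: dict[str, list[ScoredCandidate]],
    model: AlignmentModel,
) -> list[ScoredCandidate]:
    """Merge per-ontology answers under the learned adjustment.

    Scores are max-normalized per ontology, then adjusted with the model;
    the merged list is sorted descending with deterministic tie-break
    (ontology label, entity id).  Unknown ontology labels are an error.
    """
    for ont in answers:
        if ont not in model.scale:
            raise KeyError(f"ontology {ont!r} unknown to the alignment model")
    merged: list[ScoredCandidate] = []
    for ont in sorted(answers):
        if not answers[ont]:
            continue
        for c in normalize_scores_baseline({ont: answers[ont]}):
            merged.append(ScoredCandidate(
                entity=c.entity, score=c.score,
                normalized_score=model.adjust(question_text, ont, c.normalized_score),
                ontology_label=c.ontology_label, numeric_values=c.numeric_values,
            ))
    merged.sort(key=lambda c: (-c.normalized_score, c.ontology_label, c.entity))
    return merged


def merged_gold_ranks(
    examples: Sequence[AlignmentExample],
    model: AlignmentModel | None = None,
    tie_policy: str = "average",
) -> list[float]:
    """Rank of each gold answer in the merged list (model or baseline merge).

    Ties are resolved by the evaluation tie policy (average by default), so a
    gold answer tied with a junk answer at the top does not count as rank 1.
    """
    ranks = []
    for ex in examples:
        if model is None:
            merged = normalize_scores_baseline(ex.answers)
        else:
            merged = rerank_cross_ontology(ex.question, ex.answers, model)
        scores = [c.normalized_score for c in merged]
        idx = next(i for i, c in enumerate(merged)
                   if c.ontology_label == ex.gold_ontology and c.entity == ex.gold_entity)
        ranks.append(rank_of(scores, idx, polarity="similarity", tie_policy=tie_policy))
    return ranks
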