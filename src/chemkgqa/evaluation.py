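"""Ranking metrics and link-prediction / QA evaluation protocols.

The quality of an embedding space is measured by tail inference: for each
held-out triple ``(h, r, t)`` every entity is scored as a candidate tail and
the rank of the true tail is recorded.  Aggregates are hits@k (fraction of
questions whose true answer ranks within the top k) and the mean reciprocal
rank

    MRR = (1/Q) * sum_i 1 / rank_i .

Two senses of "filtered" exist in this area and are kept as distinct named
protocols: *filtered link prediction* removes other known-true tails of the
same ``(h, r)`` from the candidate list before ranking (so a 1-to-N relation
does not penalize the model for ranking its own true answers above the
probe), and *gold-head* evaluation supplies the true head entity to the QA
pipeline instead of relying on entity linking.  Both can only improve the
measured numbers relative to their raw counterparts.

Distance-polarity scores are negated internally so ranking uses a single
higher-is-better convention.  Ties default to the *average* policy (a tie
block contributes the mean of its ranks), so a constant-score model cannot
score perfect metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .embedding import EmbeddingSpace
from .kg import AttributeTriple, KnowledgeGraph, Triple

__all__ = ["EvalReport", "rank_of", "hits_at_k", "mrr",
           "evaluate_link_prediction", "attribute_error_metrics"]

PROTOCOLS = ("raw", "filtered-link-prediction", "gold-head")


def rank_of(
    scores: Sequence[float],
    true_index: int,
    polarity: str = "similarity",
    tie_policy: str = "average",
) -> float:
    """Rank of the true candidate: 1 + strictly-better count + tie share.

    ``tie_policy`` distributes candidates scoring exactly equal to the true
    one: ``average`` adds half of them, ``optimistic`` none, ``pessimistic``
    all.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score list")
    if not 0 <= true_index < s.size:
        raise IndexError(f"true_index {true_index} out of range")
    if polarity == "distance":
        s = -s
    elif polarity != "similarity":
        raise ValueError(f"unknown polarity {polarity!r}")
    true = s[true_index]
    better = int(np.sum(s > true))
    ties = int(np.sum(s == true)) - 1
    if tie_policy == "average":
        return 1.0 + better + ties / 2.0
    if tie_policy == "optimistic":
        return 1.0 + better
    if tie_policy == "pessimistic":
        return 1.0 + better + ties
    raise ValueError(f"unknown tie policy {tie_policy!r}")


def hits_at_k(ranks: Sequence[float], k: int) -> float:
    """Fraction of ranks at most ``k``."""
    r = np.asarray(ranks, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank list")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.mean(r <= k))


def mrr(ranks: Sequence[float]) -> float:
    """Mean reciprocal rank, in (0, 1]."""
    r = np.asarray(ranks, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank list")
    if np.any(r < 1):
        raise ValueError("ranks must be >= 1")
    return float(np.mean(1.0 / r))


@dataclass
class EvalReport:
    """Aggregated ranking results under a named protocol."""

    protocol: str
    ranks: list[float]
    ks: tuple[int, ...] = (1, 5, 10)
    hits_at: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not self.hits_at:
            self.hits_at = {k: hits_at_k(self.ranks, k) for k in self.ks}

    @property
    def Q(self) -> int:
        return len(self.ranks)

    @property
    def mrr(self) -> float:
        return mrr(self.ranks)

    def to_json(self) -> str:
        return json.dumps({
            "protocol": self.protocol,
            "Q": self.Q,
            "mrr": self.mrr,
            "hits_at": {str(k): v for k, v in self.hits_at.items()},
        }, indent=1)

    def to_csv_row(self) -> str:
        """One-row CSV in the ``hit k rate`` / ``mrr`` column convention."""
        header = "protocol," + ",".join(f"hit {k} rate" for k in self.ks) + ",mrr"
        row = self.protocol + "," + ",".join(f"{self.hits_at[k]:.4f}" for k in self.ks)
        return f"{header}\n{row},{self.mrr:.4f}\n"


def evaluate_link_prediction(
    train_kg: KnowledgeGraph,
    test_triples: Iterable[Triple],
    space: EmbeddingSpace,
    protocol: str = "filtered-link-prediction",
    ks: Sequence[int] = (1, 5, 10),
    tie_policy: str = "average",
) -> EvalReport:
    """Tail-inference evaluation: rank the true tail among all entities.

    Under ``filtered-link-prediction`` the candidates ``t' != t`` with
    ``(h, r, t')`` known true in train or test are removed before ranking.
    ``gold-head`` ranks like ``raw`` but records that heads were supplied
    rather than entity-linked (the QA-level convention).
    """
    test_triples = list(test_triples)
    missing = sorted(
        {t.head for t in test_triples if t.head not in space.entity_id}
        | {t.tail for t in test_triples if t.tail not in space.entity_id}
        | {t.relation for t in test_triples if t.relation not in space.relation_id}
    )
    if missing:
        raise KeyError(f"items absent from the embedding space: {missing}")
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")

    known_tails: dict[tuple[str, str], set[str]] = {}
    if protocol == "filtered-link-prediction":
        for h, r, t in set(train_kg.relation_triples) | set(test_triples):
            known_tails.setdefault((h, r), set()).add(t)

    all_ids = np.arange(len(space.entity_vocab))
    ranks: list[float] = []
    for h, r, t in test_triples:
        hid, rid, tid = space.entity_id[h], space.relation_id[r], space.entity_id[t]
        if protocol == "filtered-link-prediction":
            drop = {space.entity_id[t2] for t2 in known_tails[(h, r)] if t2 != t}
            cids = np.array([i for i in all_ids if i not in drop])
        else:
            cids = all_ids
        scores = space.score_candidates(
            space.entity_embeddings[hid], space.relation_embeddings[rid],
            cids, relation_id=rid, h_id=hid,
        )
        true_pos = int(np.searchsorted(cids, tid))
        ranks.append(rank_of(scores, true_pos, polarity=space.score_polarity,
                             tie_policy=tie_policy))
    return EvalReport(protocol=protocol, ranks=ranks, ks=tuple(ks))


def attribute_error_metrics(
    space: EmbeddingSpace,
    attr_triples: Iterable[AttributeTriple],
) -> dict:
    """Mean absolute error of predicted literal values, overall and per attribute."""
    if space.attribute_vectors is None:
        raise ValueError(f"{space.method} space carries no attribute parameters")
    per_attr: dict[str, list[float]] = {}
    for e, a, v, _ in attr_triples:
        if a not in space.attribute_id:
            raise KeyError(f"attribute {a!r} absent from the embedding space")
        err = abs(space.predict_attribute(e, a) - v)
        per_attr.setdefault(a, []).append(err)
    all_errs = [e for errs in per_attr.values() for e in errs]
    if not all_errs:
        raise ValueError("no attribute triples supplied")
    return {
        "mean_absolute_error": float(np.mean(all_errs)),
        "mean_value_error_per_attribute": {a: float(np.mean(v)) for a, v in per_attr.items()},
    }
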