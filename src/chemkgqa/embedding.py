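"""Translation and complex-bilinear knowledge-graph embeddings with joint
numerical-attribute modeling.

Five methods share one training loop:

* **TransE** — score ``d(h, r, t) = ||h + r - t||`` (L1 or L2); a triple is
  plausible when the relation translates the head onto the tail.
* **TransEA** — TransE plus a linear attribute head: each numeric literal
  ``(e, l, v)`` is fit by ``v ~ e . l + b_l``; the attribute loss is mixed
  into the relation loss with a factor ``alpha``.
* **TransR** — entities are projected into a relation-specific space by a
  learned matrix ``M_r`` before the translation distance is taken.
* **TransRA** — TransR's projection combined with the TransEA attribute
  head; built for graphs that are mostly numeric and contain 1-to-N
  relations.
* **ComplEx** — complex-valued embeddings scored by the real part of the
  trilinear product with the tail conjugated; a similarity (higher=better)
  rather than a distance.

Training is pairwise margin ranking: every observed triple is paired with a
corrupted one (head or tail replaced by a random entity) and the hinge
``max(0, gamma + d_pos - d_neg)`` is minimized by plain SGD.  ComplEx scores
are negated into distances so it trains under the same scheme (a logistic
loss is available as an option).  Attribute parameters are updated from a
separate pass over the attribute triples, weighted ``alpha`` against
``1 - alpha`` on the relation loss; with ``alpha = 0`` the attribute pass is
skipped entirely, so TransEA reduces exactly to TransE and TransRA to TransR,
including the consumed random streams.

All randomness derives from ``TrainingConfig.seed`` through independent
spawned generators (initialization / batch order / negative sampling /
attribute pass), so traces are bitwise reproducible and adding the attribute
pass does not perturb the relation-side stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .kg import KnowledgeGraph, Triple

__all__ = [
    "TrainingConfig",
    "EmbeddingSpace",
    "transe_score",
    "complex_score",
    "transr_project",
    "transr_score",
    "margin_ranking_loss",
    "attribute_loss",
    "combined_loss",
    "predict_attribute_value",
    "negative_sample",
    "train_embeddings",
    "NegativeSamplingExhausted",
]

TRANSLATION_METHODS = ("TransE", "TransEA", "TransR", "TransRA")
ATTRIBUTE_METHODS = ("TransEA", "TransRA", "ComplEx_numerical")
PROJECTION_METHODS = ("TransR", "TransRA")
METHODS = ("TransE", "TransEA", "TransR", "TransRA", "ComplEx", "ComplEx_numerical")


class NegativeSamplingExhausted(RuntimeError):
    """No corrupted triple exists outside the graph (filtered sampling)."""


# ---------------------------------------------------------------------------
# Score functions and losses (the per-example contracts; training uses
# vectorized equivalents of the same formulas)


def _check_dims(*vecs: np.ndarray) -> None:
    dims = {np.asarray(v).shape[-1] for v in vecs}
    if len(dims) > 1:
        raise ValueError(f"dimension mismatch: {sorted(dims)}")


def transe_score(
    h_vec: np.ndarray,
    r_vec: np.ndarray,
    t_vec: np.ndarray,
    norm_order: int = 2,
    squared: bool = False,
) -> float:
    """Translation distance ``||h + r - t||`` (optionally squared, L2 only)."""
    h_vec, r_vec, t_vec = map(np.asarray, (h_vec, r_vec, t_vec))
    _check_dims(h_vec, r_vec, t_vec)
    if norm_order not in (1, 2):
        raise ValueError("norm_order must be 1 or 2")
    diff = h_vec + r_vec - t_vec
    if norm_order == 1:
        return float(np.abs(diff).sum())
    d = float(np.sqrt((diff * diff).sum()))
    return d * d if squared else d


def complex_score(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """``Re(<h, r, conj(t)>)`` — positive for plausible triples."""
    h, r, t = (np.asarray(v, dtype=complex) for v in (h, r, t))
    _check_dims(h, r, t)
    return float(np.real(np.sum(h * r * np.conj(t))))


def transr_project(e_vec: np.ndarray, M_r: np.ndarray) -> np.ndarray:
    """Project an entity into a relation-specific space: ``M_r @ e``."""
    e_vec = np.asarray(e_vec)
    M_r = np.asarray(M_r)
    if M_r.shape != (e_vec.shape[-1], e_vec.shape[-1]):
        raise ValueError(f"projection shape {M_r.shape} incompatible with d={e_vec.shape[-1]}")
    return M_r @ e_vec


def transr_score(
    h_vec: np.ndarray,
    M_r: np.ndarray,
    r_vec: np.ndarray,
    t_vec: np.ndarray,
    norm_order: int = 2,
    squared: bool = False,
) -> float:
    """Translation distance in the relation space: ``||M h + r - M t||`` (optionally squared)."""
    return transe_score(
        transr_project(h_vec, M_r), r_vec, transr_project(t_vec, M_r),
        norm_order=norm_order, squared=squared,
    )


def margin_ranking_loss(pos_score: float, neg_score: float, gamma: float) -> float:
    """Hinge on distance scores: ``max(0, gamma + pos - neg)``."""
    return max(0.0, gamma + pos_score - neg_score)


def predict_attribute_value(e_vec: np.ndarray, l_vec: np.ndarray, b: float) -> float:
    """Predicted literal value ``v_hat = e . l + b``."""
    e_vec, l_vec = np.asarray(e_vec), np.asarray(l_vec)
    _check_dims(e_vec, l_vec)
    return float(e_vec @ l_vec + b)


def attribute_loss(
    e_vec: np.ndarray,
    l_vec: np.ndarray,
    b: float,
    v: float,
    penalty: str = "squared",
) -> float:
    """Penalty on the attribute residual ``e . l + b - v``."""
    if not np.isfinite(v):
        raise ValueError(f"attribute value {v} is not finite")
    resid = predict_attribute_value(e_vec, l_vec, b) - v
    if penalty == "squared":
        return resid * resid
    if penalty == "absolute":
        return abs(resid)
    raise ValueError(f"unknown penalty {penalty!r}")


def combined_loss(relation_loss: float, attr_loss: float, alpha: float) -> float:
    """Convex mix ``(1 - alpha) * L_relation + alpha * L_attribute``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return (1.0 - alpha) * relation_loss + alpha * attr_loss


def negative_sample(
    triple: Triple,
    kg: KnowledgeGraph,
    side: str = "uniform-random-side",
    filtered: bool = False,
    rng: np.random.Generator | None = None,
) -> Triple:
    """Corrupt one side of a triple with a uniformly random entity.

    With ``filtered`` on, the corrupted triple is guaranteed absent from the
    graph; :class:`NegativeSamplingExhausted` is raised when no such
    corruption exists.
    """
    if kg.n_entities < 2:
        raise ValueError("need at least 2 entities to sample negatives")
    rng = rng if rng is not None else np.random.default_rng()
    if side == "uniform-random-side":
        side = "head" if rng.integers(2) == 0 else "tail"
    if side not in ("head", "tail"):
        raise ValueError(f"unknown side {side!r}")
    current = triple.head if side == "head" else triple.tail
    candidates = None
    for _ in range(32):  # rejection sampling, then fall back to enumeration
        repl = kg.entities[int(rng.integers(kg.n_entities))]
        cand = _corrupt(triple, side, repl)
        if repl != current and (not filtered or cand not in kg.relation_triples):
            return cand
    candidates = [
        e
        for e in kg.entities
        if e != current
        and (not filtered or _corrupt(triple, side, e) not in kg.relation_triples)
    ]
    if not candidates:
        raise NegativeSamplingExhausted(
            f"no valid {side} corruption exists for {triple} under filtered sampling"
        )
    return _corrupt(triple, side, candidates[int(rng.integers(len(candidates)))])


def _corrupt(triple: Triple, side: str, replacement: str) -> Triple:
    if side == "head":
        return Triple(replacement, triple.relation, triple.tail)
    return Triple(triple.head, triple.relation, replacement)


# ---------------------------------------------------------------------------
# Containers


@dataclass
class TrainingConfig:
    """Hyperparameters of the margin-ranking SGD trainer.

    ``margin`` is the ranking margin gamma; ``attribute_weight`` is the mix
    factor alpha in ``(1 - alpha) L_relation + alpha L_attribute`` (used only
    by the attribute-aware methods).  Defaults target desk-scale graphs
    (hundreds of entities) on one CPU.
    """

    dimension: int = 32
    margin: float = 1.0
    attribute_weight: float = 0.3
    norm_order: int = 2
    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int = 128
    negatives_per_positive: int = 1
    norm_constraint: bool = True
    negative_policy: str = "bernoulli"  # bernoulli (1-to-N aware) | uniform
    squared_distance: bool | None = None  # None = unsquared L2 for all methods
    loss: str = "margin"  # margin | logistic (ComplEx option)
    attribute_penalty: str = "squared"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("dimension/epochs/batch_size out of range")
        if not 0.0 <= self.attribute_weight <= 1.0:
            raise ValueError("attribute_weight must lie in [0, 1]")
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")
        if self.norm_order not in (1, 2):
            raise ValueError("norm_order must be 1 or 2")


@dataclass
class EmbeddingSpace:
    """Trained embeddings for one ontology under one method.

    ``entity_embeddings``/``relation_embeddings`` are real ``(n, d)`` arrays;
    for ComplEx the imaginary parts live in the ``*_imag`` companions.
    ``projections`` holds the per-relation ``d x d`` matrices of the TransR
    family.  ``score_polarity`` is ``"distance"`` (lower = better) for the
    translation methods and ``"similarity"`` (higher = better) for ComplEx.
    """

    method: str
    dimension: int
    entity_vocab: list[str]
    relation_vocab: list[str]
    attribute_vocab: list[str]
    entity_embeddings: np.ndarray
    relation_embeddings: np.ndarray
    entity_imag: np.ndarray | None = None
    relation_imag: np.ndarray | None = None
    projections: np.ndarray | None = None
    attribute_vectors: np.ndarray | None = None
    attribute_bias: np.ndarray | None = None
    config: TrainingConfig | None = None
    loss_trace: list[float] = field(default_factory=list)
    ontology_label: str = "kg"

    def __post_init__(self) -> None:
        self.entity_id = {e: i for i, e in enumerate(self.entity_vocab)}
        self.relation_id = {r: i for i, r in enumerate(self.relation_vocab)}
        self.attribute_id = {a: i for i, a in enumerate(self.attribute_vocab)}
        if self.entity_embeddings.shape != (len(self.entity_vocab), self.dimension):
            raise ValueError("entity embedding shape does not match vocabulary")
        if self.relation_embeddings.shape[0] != len(self.relation_vocab):
            raise ValueError("relation embedding shape does not match vocabulary")

    @property
    def score_polarity(self) -> str:
        return "similarity" if self.method.startswith("ComplEx") else "distance"

    @property
    def is_squared(self) -> bool:
        if self.config is not None and self.config.squared_distance is not None:
            return bool(self.config.squared_distance)
        return False

    # -- scoring -----------------------------------------------------------

    def score_candidates(
        self,
        h_vec: np.ndarray,
        r_vec: np.ndarray,
        candidate_ids: np.ndarray,
        relation_id: int | None = None,
        h_id: int | None = None,
    ) -> np.ndarray:
        """Score the hypothetical triples ``(h, r, a')`` for a candidate batch.

        For the TransR family the relation's projection matrix is applied to
        head and candidates when ``relation_id`` is known; an externally
        supplied relation vector with no known relation uses the identity
        projection.  ComplEx needs entity ids to fetch imaginary parts.
        """
        cids = np.asarray(candidate_ids, dtype=int)
        T = self.entity_embeddings[cids]
        if self.method.startswith("ComplEx"):
            if h_id is None:
                raise ValueError("ComplEx scoring requires the head entity id")
            h_c = self.entity_embeddings[h_id] + 1j * self.entity_imag[h_id]
            if relation_id is not None:
                r_c = self.relation_embeddings[relation_id] + 1j * self.relation_imag[relation_id]
            else:
                r_c = np.asarray(r_vec, dtype=complex)
            T_c = T + 1j * self.entity_imag[cids]
            return np.real((h_c * r_c) @ np.conj(T_c).T)
        norm = self.config.norm_order if self.config else 2
        if self.method in PROJECTION_METHODS and relation_id is not None:
            M = self.projections[relation_id]
            h_vec = M @ h_vec
            T = T @ M.T
        diff = (h_vec + r_vec)[None, :] - T
        if norm == 1:
            return np.abs(diff).sum(axis=1)
        d = np.sqrt((diff * diff).sum(axis=1))
        return d * d if self.is_squared else d

    def score_triples(self, triples: Sequence[Triple]) -> np.ndarray:
        """Score known-vocabulary triples under the trained model."""
        out = np.empty(len(triples))
        for i, (h, r, t) in enumerate(triples):
            hid, rid, tid = self.entity_id[h], self.relation_id[r], self.entity_id[t]
            out[i] = self.score_candidates(
                self.entity_embeddings[hid],
                self.relation_embeddings[rid],
                np.array([tid]),
                relation_id=rid,
                h_id=hid,
            )[0]
        return out

    def predict_attribute(self, entity: str, attribute: str) -> float:
        if self.attribute_vectors is None:
            raise ValueError(f"{self.method} space has no attribute parameters")
        if attribute not in self.attribute_id:
            raise KeyError(f"attribute {attribute!r} absent from space")
        aid = self.attribute_id[attribute]
        return predict_attribute_value(
            self.entity_embeddings[self.entity_id[entity]],
            self.attribute_vectors[aid],
            float(self.attribute_bias[aid]),
        )

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "method": self.method,
            "dimension": self.dimension,
            "ontology_label": self.ontology_label,
            "score_polarity": self.score_polarity,
            "alpha": self.config.attribute_weight if self.config else None,
            "entity_vocab": self.entity_vocab,
            "relation_vocab": self.relation_vocab,
            "attribute_vocab": self.attribute_vocab,
            "vocab_hash": vocab_hash(self.entity_vocab, self.relation_vocab, self.attribute_vocab),
            "config": vars(self.config) if self.config else None,
            "loss_trace": self.loss_trace,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        arrays = {"entity_embeddings": self.entity_embeddings,
                  "relation_embeddings": self.relation_embeddings}
        for name in ("entity_imag", "relation_imag", "projections",
                     "attribute_vectors", "attribute_bias"):
            arr = getattr(self, name)
            if arr is not None:
                arrays[name] = arr
        np.savez(directory / "arrays.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path, kg: KnowledgeGraph | None = None) -> "EmbeddingSpace":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if kg is not None:
            expect = vocab_hash(kg.entities, kg.relations, kg.attributes)
            if manifest["vocab_hash"] != expect:
                raise ValueError("embedding space vocabulary does not match the graph")
        data = np.load(directory / "arrays.npz")
        cfg = TrainingConfig(**manifest["config"]) if manifest["config"] else None
        return cls(
            method=manifest["method"],
            dimension=manifest["dimension"],
            entity_vocab=manifest["entity_vocab"],
            relation_vocab=manifest["relation_vocab"],
            attribute_vocab=manifest["attribute_vocab"],
            entity_embeddings=data["entity_embeddings"],
            relation_embeddings=data["relation_embeddings"],
            entity_imag=data.get("entity_imag"),
            relation_imag=data.get("relation_imag"),
            projections=data.get("projections"),
            attribute_vectors=data.get("attribute_vectors"),
            attribute_bias=data.get("attribute_bias"),
            config=cfg,
            loss_trace=list(manifest.get("loss_trace", [])),
            ontology_label=manifest.get("ontology_label", "kg"),
        )


def vocab_hash(entities: Sequence[str], relations: Sequence[str],
               attributes: Sequence[str]) -> str:
    h = hashlib.sha256()
    for group in (entities, relations, attributes):
        for item in group:
            h.update(item.encode())
            h.update(b"\x00")
        h.update(b"\x01")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Training


def train_embeddings(
    kg: KnowledgeGraph,
    method: str,
    config: TrainingConfig | None = None,
) -> EmbeddingSpace:
    """Train an :class:`EmbeddingSpace` on a graph with seeded SGD.

    Reproducible: identical ``(kg, method, config)`` give bitwise-identical
    parameters and loss traces.  The per-epoch mean combined loss is recorded
    in ``loss_trace``.  Requesting an attribute-aware method on a graph with
    no attribute triples is an error.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    config = config or TrainingConfig()
    if not kg.relation_triples:
        raise ValueError("graph has no relation triples to train on")
    uses_attributes = method in ATTRIBUTE_METHODS
    if uses_attributes and not kg.attribute_triples:
        raise ValueError(f"{method} requires attribute triples, but the graph has none")
    if kg.n_entities < 2:
        raise ValueError("need at least 2 entities")

    n_ent, n_rel = kg.n_entities, kg.n_relations
    d = config.dimension
    is_complex = method.startswith("ComplEx")
    has_proj = method in PROJECTION_METHODS
    squared = bool(config.squared_distance) if config.squared_distance is not None else False
    alpha = config.attribute_weight if uses_attributes else 0.0
    rel_weight = (1.0 - alpha) if uses_attributes else 1.0
    lr = config.learning_rate

    ss = np.random.SeedSequence(config.seed)
    init_rng, batch_rng, neg_rng, attr_rng = (np.random.default_rng(s) for s in ss.spawn(4))

    bound = 6.0 / np.sqrt(d)
    E = init_rng.uniform(-bound, bound, (n_ent, d))
    R = init_rng.uniform(-bound, bound, (n_rel, d))
    E_im = R_im = None
    if is_complex:
        E_im = init_rng.uniform(-bound, bound, (n_ent, d))
        R_im = init_rng.uniform(-bound, bound, (n_rel, d))
    M = np.tile(np.eye(d), (n_rel, 1, 1)) if has_proj else None
    norm_constraint = config.norm_constraint and not is_complex
    if norm_constraint:
        _project_norm(E, np.arange(n_ent))

    L = b = None
    n_attr = len(kg.attributes)
    if method in ("TransEA", "TransRA", "ComplEx_numerical") and n_attr:
        # attribute parameters come from their own stream so that the
        # relation-side initialization is method-independent
        L = attr_rng.uniform(-bound, bound, (n_attr, d))
        b = np.zeros(n_attr)

    triples = sorted(kg.relation_triples,
                     key=lambda t: (kg.entity_id[t.head], kg.relation_id[t.relation],
                                    kg.entity_id[t.tail]))
    H = np.array([kg.entity_id[t.head] for t in triples])
    Rel = np.array([kg.relation_id[t.relation] for t in triples])
    T = np.array([kg.entity_id[t.tail] for t in triples])
    n_pos = len(triples)

    # Bernoulli corruption: for 1-to-N relations corrupt the head more often,
    # which avoids sampling the relation's own true tails as false negatives
    if config.negative_policy == "bernoulli":
        tph = np.ones(n_rel)
        hpt = np.ones(n_rel)
        for r in range(n_rel):
            mask = Rel == r
            if mask.any():
                heads, tails = H[mask], T[mask]
                tph[r] = mask.sum() / max(len(np.unique(heads)), 1)
                hpt[r] = mask.sum() / max(len(np.unique(tails)), 1)
        p_corrupt_head = tph / (tph + hpt)
    elif config.negative_policy == "uniform":
        p_corrupt_head = np.full(n_rel, 0.5)
    else:
        raise ValueError(f"unknown negative_policy {config.negative_policy!r}")

    attr_list = sorted(kg.attribute_triples,
                       key=lambda a: (kg.entity_id[a.entity], kg.attribute_id[a.attribute],
                                      a.value, a.unit))
    AE = np.array([kg.entity_id[a.entity] for a in attr_list], dtype=int)
    AA = np.array([kg.attribute_id[a.attribute] for a in attr_list], dtype=int)
    AV = np.array([a.value for a in attr_list])

    trace: list[float] = []
    k_neg = config.negatives_per_positive
    for _epoch in range(config.epochs):
        perm = batch_rng.permutation(n_pos)
        epoch_rel_loss = 0.0
        for start in range(0, n_pos, config.batch_size):
            idx = perm[start:start + config.batch_size]
            bsz = len(idx)
            h_id, r_id, t_id = H[idx], Rel[idx], T[idx]
            if k_neg > 1:
                h_id = np.repeat(h_id, k_neg)
                r_id = np.repeat(r_id, k_neg)
                t_id = np.repeat(t_id, k_neg)
                bsz *= k_neg
            corrupt_head = neg_rng.uniform(size=bsz) < p_corrupt_head[r_id]
            repl = neg_rng.integers(n_ent, size=bsz)
            nh_id = np.where(corrupt_head, repl, h_id)
            nt_id = np.where(corrupt_head, t_id, repl)
            live = (nh_id != h_id) | (nt_id != t_id)

            if is_complex:
                batch_loss = _complex_batch(E, E_im, R, R_im, h_id, r_id, t_id,
                                            nh_id, nt_id, live, config, lr * rel_weight)
            else:
                batch_loss = _translation_batch(E, R, M, h_id, r_id, t_id, nh_id, nt_id,
                                                live, config, squared, lr * rel_weight)
            epoch_rel_loss += batch_loss * bsz
            if norm_constraint:
                touched = np.unique(np.concatenate([h_id, t_id, nh_id, nt_id]))
                _project_norm(E, touched)
        mean_rel = epoch_rel_loss / (n_pos * k_neg)

        mean_attr = 0.0
        if alpha > 0.0 and L is not None and len(attr_list):
            perm_a = attr_rng.permutation(len(attr_list))
            total = 0.0
            for start in range(0, len(attr_list), config.batch_size):
                ai = perm_a[start:start + config.batch_size]
                e_id, a_id, v = AE[ai], AA[ai], AV[ai]
                resid = np.einsum("ij,ij->i", E[e_id], L[a_id]) + b[a_id] - v
                if config.attribute_penalty == "squared":
                    total += float(resid @ resid)
                    g = 2.0 * resid
                else:
                    total += float(np.abs(resid).sum())
                    g = np.sign(resid)
                w = lr * alpha
                gE = g[:, None] * L[a_id]
                gL = g[:, None] * E[e_id]
                np.add.at(E, e_id, -w * gE)
                np.add.at(L, a_id, -w * gL)
                np.add.at(b, a_id, -w * g)
            mean_attr = total / len(attr_list)
            if norm_constraint:
                _project_norm(E, np.unique(AE))

        trace.append(combined_loss(mean_rel, mean_attr, alpha) if uses_attributes
                     else mean_rel)

    return EmbeddingSpace(
        method=method,
        dimension=d,
        entity_vocab=list(kg.entities),
        relation_vocab=list(kg.relations),
        attribute_vocab=list(kg.attributes),
        entity_embeddings=E,
        relation_embeddings=R,
        entity_imag=E_im,
        relation_imag=R_im,
        projections=M,
        attribute_vectors=L,
        attribute_bias=b,
        config=replace(config),
        loss_trace=trace,
        ontology_label=kg.ontology_label,
    )


def _project_norm(E: np.ndarray, rows: np.ndarray) -> None:
    norms = np.linalg.norm(E[rows], axis=1)
    over = norms > 1.0
    if np.any(over):
        sel = rows[over]
        E[sel] /= norms[over][:, None]


def _translation_batch(E, R, M, h_id, r_id, t_id, nh_id, nt_id, live, config,
                       squared, lr) -> float:
    """One SGD step of margin-ranking loss for the translation methods.

    Returns the mean hinge loss over the batch.  Gradients: with
    ``u = P h + r - P t`` (P the relation projection, identity for TransE),
    d = ||u||  ->  dd/du = u / d        (L2)
    d = ||u||^2 -> dd/du = 2 u          (L2 squared)
    d = |u|_1   -> dd/du = sign(u)      (L1)
    and dd/dM accumulates ``g (h - t)^T``.
    """
    has_proj = M is not None

    def dist_and_grad(hi, ri, ti):
        h, r, t = E[hi], R[ri], E[ti]
        if has_proj:
            P = M[ri]
            ph = np.einsum("bij,bj->bi", P, h)
            pt = np.einsum("bij,bj->bi", P, t)
            u = ph + r - pt
        else:
            u = h + r - t
        if config.norm_order == 1:
            dist = np.abs(u).sum(axis=1)
            g = np.sign(u)
        else:
            dist = np.sqrt((u * u).sum(axis=1))
            if squared:
                g = 2.0 * u
                dist = dist * dist
            else:
                safe = np.maximum(dist, 1e-12)
                g = u / safe[:, None]
        return dist, g

    d_pos, g_pos = dist_and_grad(h_id, r_id, t_id)
    d_neg, g_neg = dist_and_grad(nh_id, r_id, nt_id)
    hinge = config.margin + d_pos - d_neg
    active = (hinge > 0) & live
    loss = float(np.where(active, hinge, 0.0).sum()) / len(h_id)
    if not np.any(active):
        return loss

    w = lr
    gp = np.where(active[:, None], g_pos, 0.0)
    gn = np.where(active[:, None], g_neg, 0.0)
    if has_proj:
        Pp = M[r_id]
        bp = np.einsum("bij,bi->bj", Pp, gp)   # P^T g
        bn = np.einsum("bij,bi->bj", Pp, gn)
        np.add.at(E, h_id, -w * bp)
        np.add.at(E, t_id, +w * bp)
        np.add.at(E, nh_id, +w * bn)
        np.add.at(E, nt_id, -w * bn)
        np.add.at(R, r_id, -w * (gp - gn))
        gM_pos = np.einsum("bi,bj->bij", gp, E[h_id] - E[t_id])
        gM_neg = np.einsum("bi,bj->bij", gn, E[nh_id] - E[nt_id])
        np.add.at(M, r_id, -w * (gM_pos - gM_neg))
    else:
        np.add.at(E, h_id, -w * gp)
        np.add.at(E, t_id, +w * gp)
        np.add.at(E, nh_id, +w * gn)
        np.add.at(E, nt_id, -w * gn)
        np.add.at(R, r_id, -w * (gp - gn))
    return loss


def _complex_batch(E, E_im, R, R_im, h_id, r_id, t_id, nh_id, nt_id, live,
                   config, lr) -> float:
    """One SGD step for ComplEx under margin ranking (scores negated to
    distances) or logistic loss.

    With ``s = Re(<h, r, conj(t)>)`` the partials are
      ds/dh_re = r_re*t_re + r_im*t_im     ds/dh_im = r_im*t_re - r_re*t_im
      ds/dr_re = h_re*t_re - h_im*t_im     ds/dr_im = h_im*t_re + h_re*t_im
      ds/dt_re = h_re*r_re + h_im*r_im     ds/dt_im = h_re*r_im - h_im*r_re
    """

    def score_and_grads(hi, ri, ti):
        hr, hi_, rr, ri_, tr, ti_ = E[hi], E_im[hi], R[ri], R_im[ri], E[ti], E_im[ti]
        s = np.einsum("bd,bd->b", hr * rr + hi_ * ri_, tr) + \
            np.einsum("bd,bd->b", hr * ri_ - hi_ * rr, ti_)
        grads = (
            rr * tr + ri_ * ti_,      # dh_re
            ri_ * tr - rr * ti_,      # dh_im
            hr * tr - hi_ * ti_,      # dr_re
            hi_ * tr + hr * ti_,      # dr_im
            hr * rr + hi_ * ri_,      # dt_re
            hr * ri_ - hi_ * rr,      # dt_im
        )
        return s, grads

    s_pos, g_pos = score_and_grads(h_id, r_id, t_id)
    s_neg, g_neg = score_and_grads(nh_id, r_id, nt_id)

    if config.loss == "logistic":
        # softplus(-s_pos) + softplus(s_neg); coefficient on ds
        c_pos = -_sigmoid(-s_pos)
        c_neg = _sigmoid(s_neg)
        loss = float((_softplus(-s_pos) + _softplus(np.where(live, s_neg, -np.inf))).mean())
        c_pos = np.where(live, c_pos, c_pos)  # positives always update
        c_neg = np.where(live, c_neg, 0.0)
    else:
        hinge = config.margin - s_pos + s_neg
        active = (hinge > 0) & live
        loss = float(np.where(active, hinge, 0.0).sum()) / len(h_id)
        c_pos = np.where(active, -1.0, 0.0)
        c_neg = np.where(active, 1.0, 0.0)
    if not np.any(c_pos) and not np.any(c_neg):
        return loss

    w = lr
    for coeff, ids, g in (
        (c_pos, h_id, (g_pos[0], g_pos[1])),
        (c_neg, nh_id, (g_neg[0], g_neg[1])),
    ):
        np.add.at(E, ids, -w * coeff[:, None] * g[0])
        np.add.at(E_im, ids, -w * coeff[:, None] * g[1])
    np.add.at(R, r_id, -w * (c_pos[:, None] * g_pos[2] + c_neg[:, None] * g_neg[2]))
    np.add.at(R_im, r_id, -w * (c_pos[:, None] * g_pos[3] + c_neg[:, None] * g_neg[3]))
    for coeff, ids, g in (
        (c_pos, t_id, (g_pos[4], g_pos[5])),
        (c_neg, nt_id, (g_neg[4], g_neg[5])),
    ):
        np.add.at(E, ids, -w * coeff[:, None] * g[0])
        np.add.at(E_im, ids, -w * coeff[:, None] * g[1])
    return loss


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)
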