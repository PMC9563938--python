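"""TransE embedding training and entity prediction with degree-normalised weights.

TransE embeds entities and relations in R^d so that a true predication
(h, r, t) satisfies h + r ~ t; the plausibility of a candidate triple is
the distance ||h + r - t||_p (smaller = more plausible).  Training
minimises the margin-ranking loss against uniformly corrupted negatives
by minibatch SGD, renormalising entity vectors to unit norm each epoch.

Predicted links carry a degree-normalised strength

    raw_weight = exp(-distance) / (1 + ln(1 + weighted_degree(tail)))

min-max rescaled to [0, 1] within each candidate list, so that hub-like
high-degree tails do not dominate purely through connectivity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .kgraph import KnowledgeGraph

log = logging.getLogger(__name__)


@dataclass
class TransEConfig:
    dim: int = 32
    margin: float = 1.0
    norm: int = 2
    epochs: int = 200
    lr: float = 0.05
    batch_size: int = 64
    n_negatives: int = 1


@dataclass
class EmbeddingModel:
    entity_ids: list[str]
    relation_ids: list[str]
    entities: np.ndarray      # n_entities x dim
    relations: np.ndarray     # n_relations x dim
    config: TransEConfig
    seed: int
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self._eidx = {e: i for i, e in enumerate(self.entity_ids)}
        self._ridx = {r: i for i, r in enumerate(self.relation_ids)}

    def distance(self, head: str, predicate: str, tail: str) -> float:
        v = (self.entities[self._eidx[head]]
             + self.relations[self._ridx[predicate]]
             - self.entities[self._eidx[tail]])
        return float(np.linalg.norm(v, ord=self.config.norm))

    def save(self, prefix: str) -> None:
        np.savetxt(f"{prefix}.entities.tsv", self.entities, delimiter="\t")
        np.savetxt(f"{prefix}.relations.tsv", self.relations, delimiter="\t")
        meta = {"entity_ids": self.entity_ids, "relation_ids": self.relation_ids,
                "config": self.config.__dict__, "seed": self.seed}
        with open(f"{prefix}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)


@dataclass
class PredictedLink:
    head: str
    predicate: str
    tail: str
    distance: float
    raw_weight: float
    norm_weight: float


def degree_normalized_weight(distance: float, tail_weighted_degree: float) -> float:
    """exp(-distance) discounted by the tail's (log-damped) weighted degree."""
    return math.exp(-distance) / (1.0 + math.log1p(tail_weighted_degree))


def _init_model(g: KnowledgeGraph, config: TransEConfig,
                seed: int, rng: np.random.Generator) -> EmbeddingModel:
    entity_ids = sorted(g.nodes)
    relation_ids = sorted({p for (_, p, _) in g.edges})
    bound = 6.0 / math.sqrt(config.dim)
    E = rng.uniform(-bound, bound, size=(len(entity_ids), config.dim))
    R = rng.uniform(-bound, bound, size=(len(relation_ids), config.dim))
    R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)
    return EmbeddingModel(entity_ids=entity_ids, relation_ids=relation_ids,
                          entities=E, relations=R, config=config, seed=seed)


def untrained_model(g: KnowledgeGraph, config: TransEConfig | None = None,
                    seed: int = 0) -> EmbeddingModel:
    """Randomly initialised embeddings; the no-learning baseline."""
    config = config or TransEConfig()
    return _init_model(g, config, seed, np.random.default_rng(seed))


def train_transe(g: KnowledgeGraph, config: TransEConfig | None = None,
                 seed: int = 0) -> EmbeddingModel:
    """Train TransE on the graph's unique triples (deterministic per seed)."""
    config = config or TransEConfig()
    if g.n_edges() == 0:
        raise ValueError("cannot train on an empty graph")
    rng = np.random.default_rng(seed)
    model = _init_model(g, config, seed, rng)
    E, R = model.entities, model.relations
    n_ent = len(model.entity_ids)

    triples = np.array(
        [(model._eidx[h], model._ridx[p], model._eidx[t])
         for (h, p, t) in sorted(g.edges)], dtype=np.int64)
    n = len(triples)

    for epoch in range(config.epochs):
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = triples[perm[start:start + config.batch_size]]
            if config.n_negatives > 1:
                batch = np.repeat(batch, config.n_negatives, axis=0)
            h, r, t = batch[:, 0], batch[:, 1], batch[:, 2]
            corrupt_head = rng.random(len(batch)) < 0.5
            neg_ent = rng.integers(0, n_ent, size=len(batch))
            nh = np.where(corrupt_head, neg_ent, h)
            nt = np.where(corrupt_head, t, neg_ent)

            d_pos_vec = E[h] + R[r] - E[t]
            d_neg_vec = E[nh] + R[r] - E[nt]
            d_pos = np.linalg.norm(d_pos_vec, axis=1)
            d_neg = np.linalg.norm(d_neg_vec, axis=1)
            viol = config.margin + d_pos - d_neg > 0
            losses.append(np.maximum(0.0, config.margin + d_pos - d_neg).mean())
            if not viol.any():
                continue
            u_pos = d_pos_vec[viol] / np.maximum(d_pos[viol, None], 1e-12)
            u_neg = d_neg_vec[viol] / np.maximum(d_neg[viol, None], 1e-12)
            lr = config.lr
            np.add.at(E, h[viol], -lr * u_pos)
            np.add.at(E, t[viol], lr * u_pos)
            np.add.at(R, r[viol], -lr * (u_pos - u_neg))
            np.add.at(E, nh[viol], lr * u_neg)
            np.add.at(E, nt[viol], -lr * u_neg)
        model.loss_history.append(float(np.mean(losses)))
        log.debug("epoch %d mean loss %.4f", epoch, model.loss_history[-1])
    E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
    return model


def _minmax(raw: np.ndarray) -> np.ndarray:
    """Min-max to [0,1]; degenerate lists (single value) map to 1.0."""
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


def predict_entities(model: EmbeddingModel, g: KnowledgeGraph, head: str,
                     predicate: str, ntypes, top_k: int = 25,
                     ) -> list[PredictedLink]:
    """Rank unobserved tails for (head, predicate, ?) among allowed types.

    Candidates exclude the head itself and every observed tail for the
    query pair (filtered setting); results are ordered by ascending
    distance with norm_weight min-maxed over the full candidate list.
    """
    if head not in g.nodes:
        raise KeyError(f"unknown head {head!r}")
    if predicate not in model._ridx:
        raise KeyError(f"unknown predicate {predicate!r}")
    observed = {t for (h, p, t) in g.edges if h == head and p == predicate}
    cands = [c for c in g.nodes_of_type(ntypes)
             if c != head and c not in observed and c in model._eidx]
    if not cands:
        return []
    idx = np.array([model._eidx[c] for c in cands])
    q = model.entities[model._eidx[head]] + model.relations[model._ridx[predicate]]
    dist = np.linalg.norm(model.entities[idx] - q, ord=model.config.norm, axis=1)
    degs = np.array([g.weighted_degree(c) for c in cands])
    raw = np.exp(-dist) / (1.0 + np.log1p(degs))
    norm = _minmax(raw)
    order = sorted(range(len(cands)), key=lambda i: (dist[i], cands[i]))
    return [PredictedLink(head=head, predicate=predicate, tail=cands[i],
                          distance=float(dist[i]), raw_weight=float(raw[i]),
                          norm_weight=float(norm[i]))
            for i in order[:top_k]]


def evaluate_hits(model: EmbeddingModel, g: KnowledgeGraph,
                  heldout: list, k: int = 10) -> float:
    """Filtered hits@k over held-out triples.

    For each held-out (h, r, t), candidates are all entities sharing t's
    semantic type, minus h and minus observed training tails for (h, r);
    a hit is t ranking within the top k by distance.
    """
    if not heldout:
        raise ValueError("heldout set is empty")
    hits = 0
    for e in heldout:
        h, p, t = e.head, e.predicate, e.tail
        if (h, p, t) in g.edges:
            raise ValueError(f"heldout triple {(h, p, t)} present in training graph")
        observed = {tt for (hh, pp, tt) in g.edges if hh == h and pp == p}
        cands = [c for c in g.nodes_of_type([g.nodes[t].ntype])
                 if c != h and c not in observed]
        if t not in cands or p not in model._ridx:
            continue
        idx = np.array([model._eidx[c] for c in cands])
        q = model.entities[model._eidx[h]] + model.relations[model._ridx[p]]
        dist = np.linalg.norm(model.entities[idx] - q,
                              ord=model.config.norm, axis=1)
        order = sorted(range(len(cands)), key=lambda i: (dist[i], cands[i]))
        top = {cands[i] for i in order[:k]}
        hits += t in top
    return hits / len(heldout)
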