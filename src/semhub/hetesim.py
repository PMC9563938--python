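"""Metapath-based HeteSim relevance ranking over the predication graph.

For a length-2 schema metapath  s --(p1,d1)--> M --(p2,d2)--> t  with
middle layer M of one semantic type, the HeteSim similarity is the cosine
between the forward transition-probability vector from ``s`` (step 1) and
the backward transition-probability vector from ``t`` (step 2 traversed in
reverse), both supported on the middle-layer nodes.  Per-pair relevance is
the arithmetic mean over all schema metapaths supported (nonzero vector)
at both endpoints.

Scores are reported in the lower-is-stronger convention used for ranking
conditions against a target: ``score = 1 - similarity``.  A novelty score
discounts relevance by the source's literature frequency (its weighted
degree), flagging under-published but relevant connections:

    novelty = similarity / (1 + ln(1 + w(s)))
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .kgraph import KnowledgeGraph

log = logging.getLogger(__name__)

_FLIP = {"out": "in", "in": "out"}


@dataclass(frozen=True)
class Metapath:
    """Two (predicate, direction) steps through one middle semantic type.

    Directions are relative to the s -> middle -> t walk: step 1 "out"
    means an edge from s to the middle node; step 2 "out" means an edge
    from the middle node to t.
    """

    steps: tuple[tuple[str, str], tuple[str, str]]
    middle_type: str

    def __post_init__(self):
        for pred, d in self.steps:
            if d not in ("out", "in"):
                raise ValueError(f"bad step direction {d!r}")

    def reverse(self) -> "Metapath":
        (p1, d1), (p2, d2) = self.steps
        return Metapath(steps=((p2, _FLIP[d2]), (p1, _FLIP[d1])),
                        middle_type=self.middle_type)


@dataclass
class RankedNode:
    node: str
    score: float        # 1 - similarity; lower = stronger
    similarity: float   # mean cosine HeteSim; higher = stronger
    novelty: float
    n_metapaths: int


def step_vectors(g: KnowledgeGraph, node: str,
                 ) -> dict[tuple[str, str, str], dict[str, float]]:
    """Normalised transition vectors from ``node``, one per schema step.

    Keys are (predicate, direction, middle_ntype); values map middle-node
    ids to transition probabilities (weights normalised to sum 1 within
    each key).  Only nonzero vectors appear.
    """
    raw: dict[tuple[str, str, str], dict[str, float]] = {}
    for direction in ("out", "in"):
        for p, other, w in g._incident(node, direction):
            key = (p, direction, g.nodes[other].ntype)
            vec = raw.setdefault(key, {})
            vec[other] = vec.get(other, 0.0) + w
    for vec in raw.values():
        total = sum(vec.values())
        for m in vec:
            vec[m] /= total
    return raw


def _cosine(u: dict[str, float], v: dict[str, float]) -> float:
    if len(u) > len(v):
        u, v = v, u
    dot = sum(val * v[m] for m, val in u.items() if m in v)
    if dot == 0.0:
        return 0.0
    nu = math.sqrt(sum(val * val for val in u.values()))
    nv = math.sqrt(sum(val * val for val in v.values()))
    return dot / (nu * nv)


def hetesim_length2(g: KnowledgeGraph, s: str, t: str, mp: Metapath) -> float:
    """HeteSim similarity of ``s`` and ``t`` along one length-2 metapath.

    Returns 0 when either endpoint's transition vector is empty.
    """
    if s not in g.nodes or t not in g.nodes:
        raise KeyError(f"unknown node in pair ({s!r}, {t!r})")
    (p1, d1), (p2, d2) = mp.steps
    sv = step_vectors(g, s).get((p1, d1, mp.middle_type), {})
    tv = step_vectors(g, t).get((p2, _FLIP[d2], mp.middle_type), {})
    if not sv or not tv:
        return 0.0
    return _cosine(sv, tv)


def _pair_similarity(s_vecs, t_vecs) -> tuple[float, int] | None:
    """Mean cosine over all supported schema metapaths, given step vectors."""
    sims, count = 0.0, 0
    for (p1, d1, tau), sv in s_vecs.items():
        for (p2, d2t, tau2), tv in t_vecs.items():
            if tau2 != tau:
                continue
            sims += _cosine(sv, tv)
            count += 1
    if count == 0:
        return None
    return sims / count, count


def mean_hetesim(g: KnowledgeGraph, s: str, t: str) -> tuple[float, int] | None:
    """Mean HeteSim over all supported length-2 schema metapaths.

    Returns (similarity, n_metapaths), or ``None`` when no metapath has
    nonzero support at both endpoints (the pair is unranked, not scored 0).
    """
    if s not in g.nodes or t not in g.nodes:
        raise KeyError(f"unknown node in pair ({s!r}, {t!r})")
    return _pair_similarity(step_vectors(g, s), step_vectors(g, t))


def novelty_score(g: KnowledgeGraph, s: str, similarity: float) -> float:
    """Relevance discounted by the source's weighted degree (publication mass)."""
    if not (0.0 <= similarity <= 1.0 + 1e-12):
        raise ValueError("similarity must lie in [0, 1]")
    w = g.weighted_degree(s)
    return similarity / (1.0 + math.log1p(w))


def rank_sources(g: KnowledgeGraph, targets: list[str],
                 source_ntypes=("DSYN", "TOPP"),
                 order_by: str = "score") -> list[RankedNode]:
    """Rank candidate source nodes against one or more targets.

    Candidates are nodes of the allowed semantic types reachable from at
    least one target via a supported length-2 metapath; a candidate that
    itself appears among the targets is scored against the remaining
    targets (self-relevance is trivial and excluded).  Multi-target
    similarity is the mean across all (non-self) targets, an unsupported
    target contributing zero -- broad support across the target set is
    rewarded over a single incidental match.  Ordering is ascending score
    (lower = stronger) or descending novelty; ties break by node id.
    """
    if order_by not in ("score", "novelty"):
        raise ValueError(f"order_by must be 'score' or 'novelty', got {order_by!r}")
    for t in targets:
        if t not in g.nodes:
            raise KeyError(f"unknown target {t!r}")
    target_vecs = {t: step_vectors(g, t) for t in targets}
    results = []
    for cand in g.nodes_of_type(source_ntypes):
        own_targets = [t for t in targets if t != cand]
        if not own_targets:
            continue
        c_vecs = step_vectors(g, cand)
        sims, paths = [], 0
        for t in own_targets:
            pair = _pair_similarity(c_vecs, target_vecs[t])
            if pair is not None:
                sims.append(pair[0])
                paths += pair[1]
        if not sims:
            continue
        similarity = sum(sims) / len(own_targets)
        results.append(RankedNode(
            node=cand, score=1.0 - similarity, similarity=similarity,
            novelty=novelty_score(g, cand, similarity), n_metapaths=paths))
    if not results:
        log.warning("no candidate sources reachable from targets %s", targets)
    if order_by == "score":
        results.sort(key=lambda r: (r.score, r.node))
    else:
        results.sort(key=lambda r: (-r.novelty, r.node))
    return results
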