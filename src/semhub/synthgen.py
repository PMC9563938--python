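"""Synthetic corpora and knowledge graphs with known ground truth.

Every pipeline stage is testable without downloads: the corpus generator
plants drug-specific adverse-event term enrichment into a bag-of-words
abstract corpus, and the graph generator plants hub communities, a set of
"relevant" disease nodes sharing middle-layer neighbors with those
communities, and held-out true links for link-prediction evaluation.

Corpus model: each abstract belongs to one drug; its tokens are drawn from
a multinomial mixing a shared Zipf-weighted background vocabulary with the
drug's AE terms boosted by a multiplicative enrichment factor, and the
drug's own name boosted equally; the drug name is additionally guaranteed
present.  This is the simplest model under which TF-IDF/k-means provably
separates drug clusters at large enrichment.

Graph model: two anchor concepts share six high-degree hub neighbors (plus
lower-degree decoys); each hub owns a community of protein/gene/substance
members linked through a subset of the six causal/temporal predicates;
planted relevant DSYN nodes attach to the same bridge middles as community
members, background DSYN nodes attach to random middles; edge weights are
geometric (many weight-1 predications, few heavy ones); a fraction of the
hub-community edges is held out for link-prediction validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import AbstractRecord
from .kgraph import SIX_PREDICATES, Edge, KnowledgeGraph, Node

#: Association predicates for middle-layer (protein/substance) edges, as in
#: predication databases; distinct from the six causal hub predicates.
BRIDGE_PREDICATES = ("INTERACTS_WITH", "COEXISTS_WITH", "ASSOCIATED_WITH")


# ---------------------------------------------------------------------------
# corpus generation

@dataclass
class CorpusSpec:
    n_drugs: int = 5
    n_abstracts: int = 250
    vocab_size: int = 200           # background terms
    ae_terms_per_drug: int = 4
    enrichment: float = 5.0         # multiplicative boost, >= 1
    tokens_per_abstract: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.vocab_size < self.n_drugs * self.ae_terms_per_drug:
            raise ValueError("background vocabulary too small for AE term sets")
        if self.n_drugs < 1 or self.n_abstracts < self.n_drugs:
            raise ValueError("need at least one abstract per drug")


@dataclass
class CorpusTruth:
    labels: dict[str, int]                  # abstract id -> drug index
    drug_names: list[str]
    ae_terms: list[list[str]]               # per drug


def gen_corpus(spec: CorpusSpec) -> tuple[list[AbstractRecord], CorpusTruth]:
    """Generate drug-labelled abstracts with planted AE enrichment."""
    rng = np.random.default_rng(spec.seed)
    drugs = [f"drug{chr(ord('a') + i)}" for i in range(spec.n_drugs)]
    background = [f"term{i:04d}" for i in range(spec.vocab_size)]
    ae_terms = [[f"ae{i}x{j}" for j in range(spec.ae_terms_per_drug)]
                for i in range(spec.n_drugs)]

    # Zipf-weighted background; AE terms enter at the mean background weight.
    bg_w = 1.0 / (np.arange(spec.vocab_size) + 1.0)
    ae_base = bg_w.mean()

    vocab = background + [t for terms in ae_terms for t in terms] + drugs
    base = np.concatenate([
        bg_w,
        np.full(spec.n_drugs * spec.ae_terms_per_drug, ae_base),
        np.zeros(spec.n_drugs),
    ])

    records, labels = [], {}
    for i in range(spec.n_abstracts):
        drug = i % spec.n_drugs                 # balanced assignment
        w = base.copy()
        lo = spec.vocab_size + drug * spec.ae_terms_per_drug
        w[lo:lo + spec.ae_terms_per_drug] *= spec.enrichment
        w[spec.vocab_size + spec.n_drugs * spec.ae_terms_per_drug + drug] = \
            ae_base * spec.enrichment
        p = w / w.sum()
        counts = rng.multinomial(spec.tokens_per_abstract - 1, p)
        tokens = [drugs[drug]]
        for j in np.flatnonzero(counts):
            tokens.extend([vocab[j]] * int(counts[j]))
        doc_id = f"abs{i:04d}"
        records.append(AbstractRecord(id=doc_id, text=" ".join(tokens)))
        labels[doc_id] = drug
    return records, CorpusTruth(labels=labels, drug_names=drugs,
                                ae_terms=ae_terms)


def write_corpus_jsonl(records: list[AbstractRecord], path) -> None:
    import json
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps({"id": r.id, "title": "", "abstract": r.text})
                     + "\n")


# ---------------------------------------------------------------------------
# knowledge-graph generation

@dataclass
class KGSpec:
    n_dsyn: int = 200
    n_aapp: int = 40
    n_bacs: int = 40
    n_gngm: int = 40
    n_phsu: int = 40
    n_topp: int = 10
    n_hubs: int = 6
    n_decoys: int = 6               # low-degree shared anchor neighbors
    n_planted: int = 10             # relevant DSYN set size
    members_per_hub: int = 8
    predicates_per_member: int = 3  # hub->member edges use this many of the six
    n_bridges: int = 24
    bridges_per_member: int = 4
    bridges_per_planted: int = 8
    middles_per_background_dsyn: int = 2
    p_background: float = 0.004     # random noise edge probability
    weight_geom_p: float = 0.5      # geometric occurrence-count skew
    holdout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must lie in [0, 1)")
        if self.n_planted + self.n_hubs + self.n_decoys > self.n_dsyn:
            raise ValueError("DSYN pool too small for hubs+decoys+planted")
        if self.n_bridges > self.n_aapp + self.n_bacs + self.n_gngm + self.n_phsu:
            raise ValueError("middle-layer pool too small for bridges")


@dataclass
class KGTruth:
    anchors: tuple[str, str]
    hubs: list[str]
    decoys: list[str]
    planted: list[str]
    members: dict[str, list[str]] = field(default_factory=dict)
    holdout: list[Edge] = field(default_factory=list)


def _geom_weight(rng: np.random.Generator, p: float) -> float:
    return float(rng.geometric(p))


def gen_kg(spec: KGSpec) -> tuple[KnowledgeGraph, KGTruth]:
    """Generate a typed predication graph with planted hub structure.

    Returns the training graph (holdout edges removed) plus ground truth:
    anchor/hub/planted ids, per-hub community membership, and the held-out
    edge list (disjoint from the training edges).
    """
    rng = np.random.default_rng(spec.seed)
    g = KnowledgeGraph()

    pools = {
        "DSYN": [f"DSYN{i:04d}" for i in range(spec.n_dsyn)],
        "AAPP": [f"AAPP{i:04d}" for i in range(spec.n_aapp)],
        "BACS": [f"BACS{i:04d}" for i in range(spec.n_bacs)],
        "GNGM": [f"GNGM{i:04d}" for i in range(spec.n_gngm)],
        "PHSU": [f"PHSU{i:04d}" for i in range(spec.n_phsu)],
        "TOPP": [f"TOPP{i:04d}" for i in range(spec.n_topp)],
    }
    anchor1 = Node("ANCH0001", "chronic disease anchor", "DSYN")
    anchor2 = Node("ANCH0002", "kinase anchor", "AAPP")
    g.add_node(anchor1)
    g.add_node(anchor2)
    for ntype, ids in pools.items():
        for nid in ids:
            g.add_node(Node(nid, nid.lower(), ntype))

    dsyn = pools["DSYN"]
    picks = rng.permutation(len(dsyn))
    hubs = [dsyn[i] for i in picks[:spec.n_hubs]]
    decoys = [dsyn[i] for i in picks[spec.n_hubs:spec.n_hubs + spec.n_decoys]]
    planted = [dsyn[i] for i in
               picks[spec.n_hubs + spec.n_decoys:
                     spec.n_hubs + spec.n_decoys + spec.n_planted]]
    background_dsyn = [dsyn[i] for i in
                       picks[spec.n_hubs + spec.n_decoys + spec.n_planted:]]

    middles = pools["AAPP"] + pools["BACS"] + pools["GNGM"] + pools["PHSU"]
    bridges = list(rng.choice(middles, size=spec.n_bridges, replace=False))

    def w():
        return _geom_weight(rng, spec.weight_geom_p)

    # hubs: strongly tied to both anchors, plus a degree boost so they are
    # the top shared neighbors by construction
    for hub in hubs:
        g.add_edge(hub, "AFFECTS", anchor1.id, 5 + w())
        g.add_edge(hub, "AFFECTS", anchor2.id, 5 + w())
        for m in rng.choice(middles, size=10, replace=False):
            g.add_edge(hub, "AFFECTS", str(m), w())
    for d in decoys:
        g.add_edge(d, "AFFECTS", anchor1.id, 1.0)
        g.add_edge(d, "AFFECTS", anchor2.id, 1.0)

    # hub communities and their held-out-able structured edges; members come
    # from the protein layer (molecular neighborhoods of disease hubs)
    member_pool = pools["AAPP"]
    truth_members: dict[str, list[str]] = {}
    structured: list[tuple[str, str, str, float]] = []
    for hub in hubs:
        members = [str(m) for m in
                   rng.choice(member_pool, size=spec.members_per_hub,
                              replace=False)]
        truth_members[hub] = members
        for m in members:
            preds = rng.choice(len(SIX_PREDICATES),
                               size=spec.predicates_per_member, replace=False)
            for pi in preds:
                structured.append((hub, SIX_PREDICATES[pi], m, w()))
            for b in rng.choice(spec.n_bridges,
                                size=min(spec.bridges_per_member, spec.n_bridges),
                                replace=False):
                bid = str(bridges[b])
                if m != bid:
                    g.add_edge(m, BRIDGE_PREDICATES[int(b) % 3], bid, w())

    # planted relevant DSYN: share bridge middles with community members
    for r in planted:
        for b in rng.choice(spec.n_bridges,
                            size=min(spec.bridges_per_planted, spec.n_bridges),
                            replace=False):
            g.add_edge(r, BRIDGE_PREDICATES[int(b) % 3], str(bridges[b]), w())

    # background DSYN: sparse random middle attachment
    for r in background_dsyn:
        for m in rng.choice(middles, size=spec.middles_per_background_dsyn,
                            replace=False):
            g.add_edge(r, str(rng.choice(BRIDGE_PREDICATES)), str(m), w())

    # uniform background noise over all node pairs
    all_ids = sorted(g.nodes)
    n_noise = rng.binomial(len(all_ids) * (len(all_ids) - 1), spec.p_background)
    noise_preds = list(SIX_PREDICATES) + ["TREATS", "INHIBITS", "ISA"]
    for _ in range(int(n_noise)):
        h, t = rng.choice(len(all_ids), size=2, replace=False)
        g.add_edge(all_ids[h], str(rng.choice(noise_preds)), all_ids[t], w())

    # holdout: a fraction of the structured hub->member edges, never merged
    # into the training graph
    structured = [structured[i] for i in rng.permutation(len(structured))]
    n_hold = int(round(spec.holdout_fraction * len(structured)))
    holdout = [Edge(h, p, t, wt) for h, p, t, wt in structured[:n_hold]]
    for h, p, t, wt in structured[n_hold:]:
        g.add_edge(h, p, t, wt)
    holdout = [e for e in holdout
               if (e.head, e.predicate, e.tail) not in g.edges]

    return g, KGTruth(anchors=(anchor1.id, anchor2.id), hubs=hubs,
                      decoys=decoys, planted=planted, members=truth_members,
                      holdout=holdout)
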