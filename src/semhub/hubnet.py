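"""Hub-node network analysis: neighborhoods, simulations, tiers, foci.

Rather than expanding the metapath length (exponentially noisy), reach is
extended by ranking candidate conditions against the *neighborhoods* of a
few highly connected hub nodes.  Hubs are the top shared neighbors of two
anchor concepts; each hub's neighborhood is populated by TransE entity
prediction over six causal/temporal predicates, pruned by degree-normalised
weight.  Per-hub relevance simulations rank disease/syndrome sources with
HeteSim, min-max normalise scores to [0,1] (lower = stronger), and the
per-candidate results aggregate as

    composite = occurrence_rate * (1 - mean_normalized_score)

Candidates are tiered at the top 1% / 5% / 10% of the aggregate ranking and
mapped to physiology-based foci from a curated two-column file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .hetesim import rank_sources
from .kgraph import FIVE_NTYPES, SIX_PREDICATES, KnowledgeGraph
from .linkpred import EmbeddingModel, predict_entities

log = logging.getLogger(__name__)

VALID_VERDICTS = ("agrees", "disagrees", "missing")


@dataclass
class HubNeighborhood:
    hub: str
    members: list[tuple[str, float]]        # (node id, norm_weight), sorted
    provenance: dict[str, str] = field(default_factory=dict)  # node -> predicate

    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]


@dataclass
class HubSimResult:
    hub: str
    candidates: list[tuple[str, float]]     # (node id, normalized score in [0,1])


@dataclass
class AggregateEntry:
    node: str
    occurrence_rate: float
    mean_score: float
    composite: float
    rank: int = 0
    tier: str = "none"
    focus: str = "other"


def select_hubs(g: KnowledgeGraph, anchors: tuple[str, str],
                n: int = 6) -> list[str]:
    """Top-n shared neighbors of both anchors by total weighted degree."""
    a1, a2 = anchors
    shared = ({m for m, _ in g.neighbors(a1, direction="both")}
              & {m for m, _ in g.neighbors(a2, direction="both")})
    shared -= {a1, a2}
    if not shared:
        log.warning("anchors %s share no neighbors; supply hubs manually", anchors)
        return []
    ranked = sorted(shared, key=lambda m: (-g.weighted_degree(m), m))
    return ranked[:n]


def build_neighborhood(model: EmbeddingModel, g: KnowledgeGraph, hub: str,
                       predicates=SIX_PREDICATES, ntypes=FIVE_NTYPES,
                       cap: int = 25) -> HubNeighborhood:
    """Union of entity predictions over the predicates, deduplicated at each
    node's maximum norm_weight, sorted, truncated to ``cap``."""
    best: dict[str, tuple[float, str]] = {}
    for pred in predicates:
        if pred not in model._ridx:
            continue
        for link in predict_entities(model, g, hub, pred, ntypes, top_k=cap):
            cur = best.get(link.tail)
            if cur is None or link.norm_weight > cur[0]:
                best[link.tail] = (link.norm_weight, pred)
    ordered = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))[:cap]
    return HubNeighborhood(
        hub=hub,
        members=[(node, w) for node, (w, _) in ordered],
        provenance={node: pred for node, (_, pred) in ordered})


def run_hub_simulation(g: KnowledgeGraph, neighborhood: HubNeighborhood,
                       focal: str, source_ntypes=("DSYN",)) -> HubSimResult:
    """HeteSim-rank sources against the focal node plus the hub neighborhood.

    Raw lower-is-stronger scores are min-max normalised to [0,1]; a
    single-candidate (or all-tied) simulation normalises to 0, the
    strongest available value.
    """
    if not neighborhood.members:
        raise ValueError(f"neighborhood of hub {neighborhood.hub} is empty")
    targets = [focal] + neighborhood.member_ids()
    ranked = rank_sources(g, targets, source_ntypes=source_ntypes,
                          order_by="score")
    if not ranked:
        log.warning("hub %s simulation ranked no candidates", neighborhood.hub)
        return HubSimResult(hub=neighborhood.hub, candidates=[])
    scores = [r.score for r in ranked]
    lo, hi = min(scores), max(scores)
    if hi - lo <= 0:
        normed = [0.0] * len(ranked)
    else:
        normed = [(s - lo) / (hi - lo) for s in scores]
    return HubSimResult(hub=neighborhood.hub,
                        candidates=[(r.node, n) for r, n in zip(ranked, normed)])


def aggregate(sims: list[HubSimResult]) -> list[AggregateEntry]:
    """Aggregate per-hub simulations into a composite ranking.

    occurrence_rate o = fraction of simulations containing the candidate;
    mean_score = mean normalised score over those simulations;
    composite = o * (1 - mean_score), ranked descending (id tie-break).
    """
    non_empty = [s for s in sims if s.candidates]
    if not non_empty:
        raise ValueError("no non-empty simulations to aggregate")
    per_node: dict[str, list[float]] = {}
    for sim in non_empty:
        for node, score in sim.candidates:
            per_node.setdefault(node, []).append(score)
    n_sims = len(non_empty)
    entries = []
    for node in sorted(per_node):
        scores = sorted(per_node[node])   # order-insensitive summation
        o = len(scores) / n_sims
        s_bar = sum(scores) / len(scores)
        entries.append(AggregateEntry(node=node, occurrence_rate=o,
                                      mean_score=s_bar,
                                      composite=o * (1.0 - s_bar)))
    entries.sort(key=lambda e: (-e.composite, e.node))
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return entries


def assign_tiers(ranking: list[AggregateEntry],
                 cutoffs: tuple[float, float, float] = (0.01, 0.05, 0.10),
                 ) -> list[AggregateEntry]:
    """Tier 1/2/3 at the top cutoff fractions of the ranking (ceilings).

    Ceiling boundaries keep every tier non-empty for any N >= 1; tiers are
    nested, so tier 2 holds ranks after tier 1 up to ceil(c2*N), etc.
    """
    if not ranking:
        raise ValueError("ranking is empty")
    if not all(c1 < c2 for c1, c2 in zip(cutoffs, cutoffs[1:])) or \
            not all(0 < c <= 1 for c in cutoffs):
        raise ValueError(f"cutoffs must be strictly increasing in (0,1]: {cutoffs}")
    n = len(ranking)
    bounds = [math.ceil(c * n) for c in cutoffs]
    for e in ranking:
        if e.rank <= bounds[0]:
            e.tier = "1"
        elif e.rank <= bounds[1]:
            e.tier = "2"
        elif e.rank <= bounds[2]:
            e.tier = "3"
        else:
            e.tier = "none"
    return ranking


def read_foci_map(path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column node -> focus file; malformed lines raise with a number."""
    foci = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            foci[parts[0]] = parts[1]
    return foci


def apply_foci(ranking: list[AggregateEntry],
               foci_map: dict[str, str]) -> dict[str, list[AggregateEntry]]:
    """Label tiered candidates with foci; unmapped nodes become "other".

    Returns the per-focus grouping with at most the three highest-ranked
    candidates listed per focus (the report summary convention).
    """
    groups: dict[str, list[AggregateEntry]] = {}
    for e in ranking:
        e.focus = foci_map.get(e.node, "other")
        if e.tier != "none":
            groups.setdefault(e.focus, []).append(e)
    return {focus: sorted(members, key=lambda e: e.rank)[:3]
            for focus, members in sorted(groups.items())}


def export_curation_template(ranking: list[AggregateEntry], path,
                             delimiter: str = "\t") -> int:
    """Write one review row per tiered candidate with an empty verdict column.

    Returns the number of rows written.  Verdicts accepted on re-import are
    exactly {agrees, disagrees, missing}.
    """
    tiered = [e for e in ranking if e.tier != "none"]
    with open(path, "w") as fh:
        fh.write(delimiter.join(("rank", "node", "composite", "occurrence_rate",
                                 "mean_score", "tier", "focus", "verdict")) + "\n")
        for e in tiered:
            fh.write(delimiter.join((str(e.rank), e.node, f"{e.composite:.6f}",
                                     f"{e.occurrence_rate:.6f}",
                                     f"{e.mean_score:.6f}", e.tier, e.focus,
                                     "")) + "\n")
    return len(tiered)


def import_curation(path, delimiter: str = "\t") -> dict[str, int]:
    """Validate a filled curation template and return verdict counts."""
    counts = {v: 0 for v in VALID_VERDICTS}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        try:
            vcol = header.index("verdict")
        except ValueError:
            raise ValueError(f"{path}:1: missing 'verdict' column")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(delimiter)
            verdict = fields[vcol] if len(fields) > vcol else ""
            if verdict not in VALID_VERDICTS:
                raise ValueError(
                    f"{path}:{lineno}: invalid verdict {verdict!r}; "
                    f"expected one of {VALID_VERDICTS}")
            counts[verdict] += 1
    return counts
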