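"""Document clustering and per-cluster adverse-event term profiling.

Clusters the reduced TF-IDF representation with k-means, maps clusters to
drugs by in-cluster drug-name document frequency, and profiles adverse-event
terms per cluster: document-level presence frequencies, fold change against
the whole corpus, and pairwise chi-square tests of independence between
cluster AE profiles with a Bonferroni-corrected family-wise alpha.

All frequencies are document-presence fractions (a term counts once per
document), matching the interpretation of per-abstract occurrence rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2_contingency

from .corpus import ReducedMatrix, TfidfResult, TokenizedDoc

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    doc_ids: list[str]
    labels: np.ndarray
    k: int
    inertia: float

    def members(self, cluster: int) -> np.ndarray:
        """Document indices belonging to ``cluster``."""
        return np.flatnonzero(self.labels == cluster)


@dataclass
class DrugClusterEntry:
    cluster: int
    drugs: list[str]            # >1 entry only when the mapping is ambiguous
    frequency: dict[str, float]  # in-cluster document frequency per drug
    ambiguous: bool


@dataclass
class TermClusterStats:
    term: str
    cluster: int
    cluster_freq: float
    corpus_freq: float
    fold_change: float
    is_max: bool = False        # flagged when this cluster carries the term's maximum


@dataclass
class PairwiseChiSq:
    clusters: tuple[int, int]
    statistic: float
    dof: int
    p_value: float
    corrected_alpha: float
    significant: bool


def cluster(reduced: ReducedMatrix, k: int = 30, seed: int = 0) -> ClusterAssignment:
    """K-means clustering of the reduced document matrix (deterministic per seed)."""
    from sklearn.cluster import KMeans

    n_docs = reduced.components.shape[0]
    if k < 1 or k > n_docs:
        raise ValueError(f"k={k} must be in [1, n_docs={n_docs}]")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(reduced.components)
    return ClusterAssignment(doc_ids=list(reduced.doc_ids), labels=labels,
                             k=k, inertia=float(km.inertia_))


def top_terms(assignment: ClusterAssignment, tfidf: TfidfResult,
              cluster_id: int, n: int = 200) -> list[str]:
    """Terms ordered by mean in-cluster TF-IDF weight, ties lexicographic."""
    idx = assignment.members(cluster_id)
    if idx.size == 0:
        log.warning("cluster %d is empty; returning no terms", cluster_id)
        return []
    means = np.asarray(tfidf.matrix[idx].mean(axis=0)).ravel()
    # sort by (-mean, term): lexicographic tie-break
    order = sorted(range(len(tfidf.vocabulary)),
                   key=lambda j: (-means[j], tfidf.vocabulary[j]))
    return [tfidf.vocabulary[j] for j in order[:n]]


def _presence_freq(docs: list[TokenizedDoc], idx, term: str) -> float:
    """Fraction of the selected documents containing ``term`` at least once."""
    if len(idx) == 0:
        return 0.0
    return sum(1 for i in idx if term in docs[i]._token_set) / len(idx)


def _with_token_sets(docs: list[TokenizedDoc]) -> list[TokenizedDoc]:
    for d in docs:
        if not hasattr(d, "_token_set"):
            d._token_set = set(d.tokens)
    return docs


def map_clusters_to_drugs(assignment: ClusterAssignment,
                          docs: list[TokenizedDoc],
                          drug_lexicon: set[str],
                          min_frequency: float = 0.0) -> list[DrugClusterEntry]:
    """Map each drug to the cluster where its document frequency is maximal.

    A cluster is mapped only when the drug's in-cluster frequency exceeds
    ``min_frequency``.  When two drugs select the same cluster, both are
    reported and the cluster is flagged ambiguous rather than silently
    picking one.
    """
    if not drug_lexicon:
        raise ValueError("drug_lexicon must be non-empty")
    _with_token_sets(docs)
    best: dict[int, list[tuple[str, float]]] = {}
    for drug in sorted(drug_lexicon):
        freqs = [(c, _presence_freq(docs, assignment.members(c), drug))
                 for c in range(assignment.k)]
        c_best, f_best = max(freqs, key=lambda cf: (cf[1], -cf[0]))
        if f_best <= min_frequency:
            log.warning("drug %r absent or below frequency floor; unmapped", drug)
            continue
        best.setdefault(c_best, []).append((drug, f_best))
    entries = []
    for c in sorted(best):
        drugs = sorted(d for d, _ in best[c])
        entries.append(DrugClusterEntry(
            cluster=c, drugs=drugs,
            frequency={d: f for d, f in best[c]},
            ambiguous=len(drugs) > 1))
    return entries


def term_stats(assignment: ClusterAssignment, docs: list[TokenizedDoc],
               terms: list[str]) -> list[TermClusterStats]:
    """Per-cluster presence frequency and fold change for AE terms.

    fold_change = cluster_freq / corpus_freq; the per-term maximum across
    clusters is flagged (the boldface analogue of a frequency table).
    Terms absent from the corpus are excluded with a warning.
    """
    _with_token_sets(docs)
    all_idx = range(len(docs))
    out: list[TermClusterStats] = []
    for term in terms:
        corpus_freq = _presence_freq(docs, list(all_idx), term)
        if corpus_freq == 0:
            log.warning("term %r absent from corpus; excluded", term)
            continue
        rows = []
        for c in range(assignment.k):
            cf = _presence_freq(docs, assignment.members(c), term)
            rows.append(TermClusterStats(
                term=term, cluster=c, cluster_freq=cf,
                corpus_freq=corpus_freq, fold_change=cf / corpus_freq))
        best = max(rows, key=lambda r: r.cluster_freq)
        if best.cluster_freq > 0:
            best.is_max = True
        out.extend(rows)
    return out


def chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Plain Pearson chi-square of independence (no continuity correction)."""
    stat, p, dof, _ = chi2_contingency(np.asarray(table, dtype=float),
                                       correction=False)
    return float(stat), int(dof), float(p)


def pairwise_chisq(assignment: ClusterAssignment, docs: list[TokenizedDoc],
                   terms: list[str], clusters: list[int],
                   family_alpha: float = 0.05) -> list[PairwiseChiSq]:
    """Pairwise chi-square tests of AE-profile independence between clusters.

    For each unordered cluster pair the contingency table is AE-term x
    cluster document-presence counts.  Term rows whose pair total is zero
    (which would force an expected count of zero) are dropped with a
    warning.  ``corrected_alpha = family_alpha / C(m, 2)`` for ``m``
    selected clusters (Bonferroni).
    """
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for pairwise tests")
    _with_token_sets(docs)
    corrected_alpha = family_alpha / comb(len(clusters), 2)
    counts = {
        c: {t: sum(1 for i in assignment.members(c) if t in docs[i]._token_set)
            for t in terms}
        for c in clusters
    }
    results = []
    for a, b in combinations(sorted(clusters), 2):
        rows = []
        for t in terms:
            row = (counts[a][t], counts[b][t])
            if sum(row) == 0:
                log.warning("term %r has zero counts in clusters %d/%d; dropped",
                            t, a, b)
                continue
            rows.append(row)
        table = np.array(rows, dtype=float)
        if table.shape[0] < 2 or table.sum(axis=0).min() == 0:
            log.warning("degenerate table for clusters %d/%d; test skipped", a, b)
            continue
        stat, dof, p = chi_square(table)
        results.append(PairwiseChiSq(
            clusters=(a, b), statistic=stat, dof=dof, p_value=p,
            corrected_alpha=corrected_alpha,
            significant=p < corrected_alpha))
    return results
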