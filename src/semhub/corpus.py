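"""Abstract-corpus ingestion and bounded-vocabulary TF-IDF representation.

The corpus arm of the toolkit turns a set of abstracts (e.g., clinical
literature on a drug class) into a document-term matrix suitable for
clustering.  Terms are kept only when their document frequency lies in a
configurable band (default 1%--85% of documents), which removes both
hapax noise and boilerplate words that appear nearly everywhere.

The TF-IDF convention is fixed explicitly so that toy corpora can be
checked by hand:

    weight(d, t) = tf(d, t) * (ln((1 + N) / (1 + df_count(t))) + 1)

followed by L2 normalisation of each non-empty document row.  This is the
standard smoothed-idf convention of mainstream vectorizers.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

log = logging.getLogger(__name__)

LEMMATIZER_ID = "semhub-rule-noun-v1"

#: Fixed English stopword list (configurable at call sites).  Deliberately
#: compact: function words and a handful of ubiquitous academic fillers.
DEFAULT_STOPWORDS = frozenset("""
a about above after again against all am an and any are as at be because been
before being below between both but by could did do does doing down during
each few for from further had has have having he her here hers herself him
himself his how i if in into is it its itself just me more most my myself no
nor not now of off on once only or other our ours ourselves out over own same
she should so some such than that the their theirs them themselves then there
these they this those through to too under until up very was we were what when
where which while who whom why will with you your yours yourself yourselves
also may however although moreover therefore thus via versus respectively
et al eg ie
""".split())

_TOKEN_RE = re.compile(r"[a-z0-9][a-z0-9'\-]*")

# Irregular noun plurals the suffix rules cannot reach.
_LEMMA_EXCEPTIONS = {
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "people": "person",
    "analyses": "analysis", "diagnoses": "diagnosis", "prognoses": "prognosis",
    "metastases": "metastasis", "stenoses": "stenosis", "fibroses": "fibrosis",
    "criteria": "criterion", "phenomena": "phenomenon", "data": "data",
    "series": "series", "species": "species",
}

# Words ending in 's' that are not plurals.
_S_FINAL_KEEP = frozenset({
    "diabetes", "mellitus", "pancreas", "thrombus", "virus", "status",
    "bolus", "lupus", "fetus", "uterus", "sinus", "nucleus", "abscess",
    "diagnosis", "prognosis", "analysis", "fibrosis", "cirrhosis",
    "sclerosis", "stenosis", "sepsis", "dialysis", "emphasis", "basis",
    "pelvis", "iris", "arthritis", "hepatitis", "colitis", "gastritis",
    "nephritis", "dermatitis", "pancreatitis", "periodontitis", "bis",
})


def lemmatize(token: str) -> str:
    """Rule-based noun-plural lemmatization (exception table + suffix rules).

    Only noun plurals are folded; verb inflections are left untouched, so
    "patients reported rashes" lemmatizes to patient / reported / rash.
    """
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    if token in _S_FINAL_KEEP or len(token) < 4 or not token.endswith("s"):
        return token
    if token.endswith(("ss", "us", "is")):
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("ches", "shes", "xes", "zes", "sses")):
        return token[:-2]
    if token.endswith("oes") and len(token) > 4:
        return token[:-2]
    return token[:-1]


@dataclass
class AbstractRecord:
    """One retrieved abstract: opaque id plus title+abstract text."""

    id: str
    text: str


@dataclass
class TokenizedDoc:
    """Ordered lowercase lemmas of one abstract after cleaning."""

    id: str
    tokens: list[str]


@dataclass
class TfidfResult:
    doc_ids: list[str]
    vocabulary: list[str]
    matrix: sp.csr_matrix          # docs x terms, L2-normalised rows
    df: np.ndarray                 # per-term document frequency, fraction of docs

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class ReducedMatrix:
    doc_ids: list[str]
    components: np.ndarray         # docs x n_components
    n_components: int
    explained_variance_ratio: np.ndarray = field(default=None)


def preprocess(record: AbstractRecord,
               stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
               ) -> TokenizedDoc | None:
    """Tokenize, lowercase, strip punctuation, drop stopwords, lemmatize.

    Returns ``None`` (with a logged warning) for records whose text is empty
    after whitespace stripping; such records are rejected, not fatal.
    """
    if not record.text or not record.text.strip():
        log.warning("record %s has empty text; skipped", record.id)
        return None
    tokens = []
    for raw in _TOKEN_RE.findall(record.text.lower()):
        raw = raw.strip("'-")
        if not raw or raw in stopwords:
            continue
        lemma = lemmatize(raw)
        if lemma and lemma not in stopwords:
            tokens.append(lemma)
    return TokenizedDoc(id=record.id, tokens=tokens)


def preprocess_corpus(records, stopwords=DEFAULT_STOPWORDS) -> list[TokenizedDoc]:
    docs = (preprocess(r, stopwords) for r in records)
    return [d for d in docs if d is not None]


# ---------------------------------------------------------------------------
# readers / writers

def read_jsonl(path) -> list[AbstractRecord]:
    """JSON-lines corpus: one object per abstract with id, title, abstract."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{i}: malformed JSON ({exc})") from exc
            text = " ".join(s for s in (obj.get("title", ""), obj.get("abstract", "")) if s)
            records.append(AbstractRecord(id=str(obj["id"]), text=text))
    return records


def read_medline(path) -> list[AbstractRecord]:
    """MEDLINE-style flat text: PMID- / TI - / AB - tagged records."""
    records: list[AbstractRecord] = []
    pmid, title, abstract, current = None, [], [], None
    def flush():
        if pmid is not None:
            records.append(AbstractRecord(
                id=pmid, text=" ".join(title + abstract)))
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            tag, _, rest = line.partition("- ")
            tag = tag.strip()
            if tag == "PMID":
                flush()
                pmid, title, abstract, current = rest.strip(), [], [], None
            elif tag == "TI":
                title.append(rest.strip()); current = title
            elif tag == "AB":
                abstract.append(rest.strip()); current = abstract
            elif line.startswith("      ") and current is not None:
                current.append(line.strip())
            else:
                current = None
    flush()
    return records


def write_tfidf(result: TfidfResult, prefix: str) -> None:
    """TF-IDF as matrix-market plus vocabulary / doc-id sidecar files."""
    mmwrite(f"{prefix}.mtx", result.matrix)
    with open(f"{prefix}.vocab.txt", "w") as fh:
        fh.write("\n".join(result.vocabulary) + "\n")
    with open(f"{prefix}.docs.txt", "w") as fh:
        fh.write("\n".join(result.doc_ids) + "\n")


# ---------------------------------------------------------------------------
# vectorization

def build_tfidf(docs: list[TokenizedDoc],
                min_df: float = 0.01,
                max_df: float = 0.85) -> TfidfResult:
    """Bounded-vocabulary TF-IDF matrix over tokenized documents.

    Terms are retained when their document frequency (fraction of documents
    containing the term at least once) lies in the inclusive band
    ``[min_df, max_df]``.  Column order is lexicographic.
    """
    if len(docs) < 2:
        raise ValueError("build_tfidf requires at least 2 documents")
    if not (0 <= min_df < max_df <= 1):
        raise ValueError(f"require 0 <= min_df < max_df <= 1, got [{min_df}, {max_df}]")

    n_docs = len(docs)
    df_count: dict[str, int] = {}
    for doc in docs:
        for term in set(doc.tokens):
            df_count[term] = df_count.get(term, 0) + 1

    eps = 1e-12
    vocabulary = sorted(
        t for t, c in df_count.items()
        if min_df * n_docs - eps <= c <= max_df * n_docs + eps
    )
    if not vocabulary:
        raise ValueError(
            f"vocabulary empty after df filtering with bounds [{min_df}, {max_df}]")
    col = {t: j for j, t in enumerate(vocabulary)}

    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        counts: dict[int, int] = {}
        for term in doc.tokens:
            j = col.get(term)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i); cols.append(j); vals.append(c)

    tf = sp.csr_matrix((np.asarray(vals, dtype=float), (rows, cols)),
                       shape=(n_docs, len(vocabulary)))
    dfc = np.array([df_count[t] for t in vocabulary], dtype=float)
    idf = np.log((1.0 + n_docs) / (1.0 + dfc)) + 1.0
    mat = tf.multiply(idf).tocsr()

    # L2-normalise non-empty rows
    norms = np.sqrt(mat.multiply(mat).sum(axis=1)).A1
    scale = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
    mat = sp.diags(scale) @ mat

    return TfidfResult(doc_ids=[d.id for d in docs], vocabulary=vocabulary,
                       matrix=mat.tocsr(), df=dfc / n_docs)


def reduce_dimensions(tfidf: TfidfResult, n_components: int = 50,
                      seed: int = 0) -> ReducedMatrix:
    """Truncated-SVD projection of the TF-IDF matrix (deterministic per seed)."""
    from sklearn.decomposition import TruncatedSVD

    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_docs, n_terms = tfidf.matrix.shape
    if n_components > min(n_docs, n_terms):
        raise ValueError(
            f"n_components={n_components} exceeds min(docs, terms)="
            f"{min(n_docs, n_terms)}")
    svd = TruncatedSVD(n_components=n_components, random_state=seed,
                       algorithm="randomized", n_iter=7)
    comps = svd.fit_transform(tfidf.matrix)
    # uncentered energy fraction per component: s_i^2 / ||M||_F^2,
    # non-increasing since singular values are sorted
    total = tfidf.matrix.multiply(tfidf.matrix).sum()
    evr = svd.singular_values_ ** 2 / total if total > 0 else \
        np.zeros(n_components)
    return ReducedMatrix(doc_ids=list(tfidf.doc_ids), components=comps,
                         n_components=n_components,
                         explained_variance_ratio=evr)


def embed_2d(reduced: ReducedMatrix, seed: int = 0) -> np.ndarray:
    """Optional t-SNE 2D embedding for visualization; deterministic per seed."""
    from sklearn.manifold import TSNE

    n = reduced.components.shape[0]
    if n < 3:
        raise ValueError("embed_2d requires at least 3 documents")
    perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(reduced.components)


def config_snapshot() -> dict:
    """Reproducibility record for the preprocessing configuration."""
    return {
        "lemmatizer": LEMMATIZER_ID,
        "stopwords": len(DEFAULT_STOPWORDS),
        "token_pattern": _TOKEN_RE.pattern,
    }
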