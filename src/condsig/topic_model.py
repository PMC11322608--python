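"""Biterm topic model over per-bin co-occupancy documents.

Each segment bin is a document whose words are the member CAPs occupying it.
Documents are short (a handful of CAPs), which is exactly the regime where
modelling word co-occurrence pairs (biterms) directly outperforms standard
LDA. Inference is collapsed Gibbs sampling over biterm topic assignments;
the topic number is chosen automatically by a combination of a specificity
score (topics should occur with very different probabilities across
documents) and a purity score (each document should be dominated by few
topics).
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .segmentation import Segment

logger = logging.getLogger(__name__)

EPS_FLOOR = 1e-12  # floor inside the score logs; avoids -inf on degenerate fits


# ---------------------------------------------------------------------------
# corpus


@dataclass
class Corpus:
    """Documents (per-bin occupied-CAP sets) and their biterms.

    ``w1``/``w2`` are parallel arrays over biterm instances (word indices,
    w1 < w2 within a pair is not required but is how enumeration emits them);
    ``doc_id`` maps each biterm to its document. Duplicate biterms are kept:
    frequency matters.
    """

    vocab: list[str]
    documents: list[np.ndarray]
    w1: np.ndarray
    w2: np.ndarray
    doc_id: np.ndarray
    bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def n_biterms(self) -> int:
        return self.w1.size

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @classmethod
    def from_documents(
        cls, documents: Iterable[Sequence[int]], vocab: Sequence[str],
        bins: np.ndarray | None = None,
    ) -> "Corpus":
        docs = [np.asarray(sorted(d), dtype=np.int64) for d in documents]
        w1, w2, did = [], [], []
        for i, words in enumerate(docs):
            for a, b in itertools.combinations(words, 2):
                w1.append(a)
                w2.append(b)
                did.append(i)
        return cls(
            list(vocab),
            docs,
            np.asarray(w1, dtype=np.int64),
            np.asarray(w2, dtype=np.int64),
            np.asarray(did, dtype=np.int64),
            bins if bins is not None else np.empty(0, dtype=np.int64),
        )

    def document_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-word and pairwise document frequencies (for coherence)."""
        V = self.vocab_size
        dfreq = np.zeros(V, dtype=np.int64)
        cooc = np.zeros((V, V), dtype=np.int64)
        for words in self.documents:
            uniq = np.unique(words)
            dfreq[uniq] += 1
            for a, b in itertools.combinations(uniq, 2):
                cooc[a, b] += 1
                cooc[b, a] += 1
        return dfreq, cooc


def corpus_from_segment(segment: Segment, occ) -> Corpus:
    """One document per segment bin; words are occupied member CAPs."""
    cols = [occ.caps.index(c) for c in segment.member_caps]
    sub = occ.O[np.ix_(segment.bins, cols)]
    documents = [np.nonzero(row)[0].astype(np.int64) for row in sub]
    return Corpus.from_documents(documents, segment.member_caps, bins=segment.bins)


# ---------------------------------------------------------------------------
# collapsed Gibbs sampler


@njit(cache=False)
def _gibbs(w1, w2, n_topics, vocab_size, alpha, beta, n_iter, seed):  # pragma: no cover
    np.random.seed(seed)
    nb = w1.shape[0]
    z = np.empty(nb, dtype=np.int64)
    n_t = np.zeros(n_topics, dtype=np.float64)
    n_wt = np.zeros((n_topics, vocab_size), dtype=np.float64)
    for b in range(nb):
        t = np.random.randint(0, n_topics)
        z[b] = t
        n_t[t] += 1.0
        n_wt[t, w1[b]] += 1.0
        n_wt[t, w2[b]] += 1.0
    vb = vocab_size * beta
    cum = np.empty(n_topics, dtype=np.float64)
    for _ in range(n_iter):
        for b in range(nb):
            t = z[b]
            n_t[t] -= 1.0
            n_wt[t, w1[b]] -= 1.0
            n_wt[t, w2[b]] -= 1.0
            s = 0.0
            for tt in range(n_topics):
                p = (
                    (n_t[tt] + alpha)
                    * (n_wt[tt, w1[b]] + beta)
                    * (n_wt[tt, w2[b]] + beta)
                    / ((2.0 * n_t[tt] + vb) * (2.0 * n_t[tt] + 1.0 + vb))
                )
                s += p
                cum[tt] = s
            u = np.random.random() * s
            tnew = n_topics - 1
            for tt in range(n_topics):
                if u < cum[tt]:
                    tnew = tt
                    break
            z[b] = tnew
            n_t[tnew] += 1.0
            n_wt[tnew, w1[b]] += 1.0
            n_wt[tnew, w2[b]] += 1.0
    return n_t, n_wt


@dataclass
class TopicModel:
    """Point estimate of a fitted biterm topic model.

    ``phi`` is k x V (P(word | topic), rows sum to 1); ``theta_doc`` is
    p x k (P(topic | document)); ``theta_global`` the corpus-level topic
    proportions. Documents without biterms receive the global distribution.
    """

    k: int
    phi: np.ndarray
    theta_doc: np.ndarray
    theta_global: np.ndarray
    alpha_topic: float
    beta_word: float
    n_iter: int
    seed: int

    def top_words(self, topic: int, n: int = 5) -> list[int]:
        """Indices of the ``n`` highest-probability words (stable tie order)."""
        row = self.phi[topic]
        order = np.lexsort((np.arange(row.size), -row))
        return list(order[:n])


def fit_btm(
    corpus: Corpus,
    k: int,
    alpha_topic: float | None = None,
    beta_word: float = 0.01,
    n_iter: int = 500,
    seed: int = 0,
) -> TopicModel:
    """Fit a biterm topic model by collapsed Gibbs sampling.

    ``alpha_topic`` defaults to 50/k. The point estimate comes from the
    final counts (no burn-in averaging), so a fixed seed gives bit-identical
    output.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if corpus.n_biterms == 0:
        raise ValueError("corpus too sparse: no biterms")
    if alpha_topic is None:
        alpha_topic = 50.0 / k
    V = corpus.vocab_size
    n_t, n_wt = _gibbs(
        corpus.w1, corpus.w2, k, V,
        float(alpha_topic), float(beta_word), int(n_iter), int(seed) & 0x7FFFFFFF,
    )
    phi = (n_wt + beta_word) / (2.0 * n_t[:, None] + V * beta_word)
    theta_global = (n_t + alpha_topic) / (corpus.n_biterms + k * alpha_topic)
    theta_global = theta_global / theta_global.sum()

    # P(topic | biterm) ~ theta_global * phi[w1] * phi[w2], then average over
    # each document's biterms weighted by their frequency in the document.
    theta_doc = np.tile(theta_global, (corpus.n_docs, 1))
    if corpus.n_biterms:
        pt_b = theta_global[:, None] * phi[:, corpus.w1] * phi[:, corpus.w2]
        pt_b /= pt_b.sum(axis=0, keepdims=True)
        acc = np.zeros((corpus.n_docs, k))
        np.add.at(acc, corpus.doc_id, pt_b.T)
        counts = np.bincount(corpus.doc_id, minlength=corpus.n_docs).astype(float)
        has = counts > 0
        theta_doc[has] = acc[has] / counts[has, None]
    return TopicModel(k, phi, theta_doc, theta_global,
                      float(alpha_topic), float(beta_word), int(n_iter), int(seed))


# ---------------------------------------------------------------------------
# topic-number selection


def specificity_score(theta_doc: np.ndarray, eps: float = EPS_FLOOR) -> float:
    """log of the mean per-topic variance-to-squared-mean ratio.

    High when each topic's probability varies strongly across documents.
    Degenerate (zero-variance) inputs are floored at ``eps`` inside the log.
    """
    mu = theta_doc.mean(axis=0)
    var = theta_doc.var(axis=0)  # population variance
    ratio = np.where(mu > 0, var / mu**2, 0.0)
    return float(np.log(max(ratio.mean(), eps)))


def purity_score(theta_doc: np.ndarray, eps: float = EPS_FLOOR) -> float:
    """log of the mean per-document topic variance (high = few topics/doc)."""
    var = theta_doc.var(axis=1)  # population variance
    return float(np.log(max(var.mean(), eps)))


def combination_score(ss: float, ps: float) -> tuple[float, float]:
    """Weighted average of specificity and purity.

    alpha = PS/(SS+PS); when SS + PS == 0 the weight is defined as 0.5.
    Returns (alpha, CS).
    """
    total = ss + ps
    alpha = 0.5 if total == 0 else ps / total
    return alpha, alpha * ss + (1 - alpha) * ps


@dataclass
class ModelSelectionReport:
    table: pd.DataFrame  # columns: k, SS, PS, alpha, CS
    chosen_k: int


def derive_seed(*parts) -> int:
    """Stable 31-bit seed from arbitrary labelled parts (crc32-based)."""
    key = "|".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def select_topic_number(
    corpus: Corpus,
    k_range: Sequence[int] = tuple(range(2, 11)),
    seed: int = 0,
    seeds: Sequence[int] | None = None,
    reps: int = 1,
    alpha_topic: float | None = None,
    beta_word: float = 0.01,
    n_iter: int = 500,
) -> tuple[TopicModel, ModelSelectionReport]:
    """Fit each candidate k and keep the model maximizing the combination score.

    Ties prefer the smaller k. With ``reps`` > 1 the combination score per k
    is averaged over independent fits and the best-scoring fit at the chosen
    k is returned. Per-(k, rep) seeds derive deterministically from ``seed``
    unless explicit ``seeds`` (one per k) are given.
    """
    rows = []
    best: TopicModel | None = None
    best_cs = -np.inf
    chosen_k = None
    models_cs: dict[int, tuple[TopicModel, float]] = {}
    for i, k in enumerate(k_range):
        cs_vals = []
        best_fit_k = None
        best_fit_cs = -np.inf
        for rep in range(reps):
            if seeds is not None:
                fit_seed = seeds[i] if reps == 1 else derive_seed(seeds[i], rep)
            else:
                fit_seed = derive_seed(seed, "k", k, "rep", rep)
            model = fit_btm(corpus, k, alpha_topic=alpha_topic,
                            beta_word=beta_word, n_iter=n_iter, seed=fit_seed)
            ss = specificity_score(model.theta_doc)
            ps = purity_score(model.theta_doc)
            alpha, cs = combination_score(ss, ps)
            cs_vals.append((ss, ps, alpha, cs))
            if cs > best_fit_cs:
                best_fit_cs = cs
                best_fit_k = model
        ss, ps, alpha, cs = (float(np.mean([v[j] for v in cs_vals])) for j in range(4))
        rows.append({"k": k, "SS": ss, "PS": ps, "alpha": alpha, "CS": cs})
        models_cs[k] = (best_fit_k, cs)
        if cs > best_cs:  # strict: ties keep the earlier (smaller) k
            best_cs = cs
            best = best_fit_k
            chosen_k = k
    report = ModelSelectionReport(pd.DataFrame(rows), chosen_k)
    logger.debug("selected k=%d (CS=%.4f)", chosen_k, best_cs)
    return best, report


# ---------------------------------------------------------------------------
# coherence


def topic_coherence(model: TopicModel, corpus: Corpus, top_n: int = 5) -> np.ndarray:
    """UMass coherence of each topic's ``top_n`` words.

    For words ranked by phi, sum over ranked pairs i < j of
    log((D(w_i, w_j) + 1) / D(w_j)) where D counts documents. Words absent
    from every document use a denominator of 1.
    """
    dfreq, cooc = corpus.document_frequencies()
    scores = np.zeros(model.k)
    for t in range(model.k):
        words = model.top_words(t, top_n)
        total = 0.0
        for i in range(len(words)):
            for j in range(i + 1, len(words)):
                wi, wj = words[i], words[j]
                denom = max(dfreq[wj], 1)
                total += np.log((cooc[wi, wj] + 1) / denom)
        scores[t] = total
    return scores
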