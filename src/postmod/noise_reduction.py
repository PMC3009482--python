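"""Indirect-relationship noise reduction.

A query is first matched against the reference set by combined similarity
(top-alpha retrieval).  An indirect relationship matrix is then built: each
hit keeps only its own top-alpha reference neighbors.  Relationships between
same-label peptides count as signal (+), cross-label ones as noise (-), and
relationships whose partner is a positive peptide are up-weighted to offset
the 10:1 class imbalance.  Both endpoints of a relationship receive its
(signed, weighted) value, so reference peptides outside the initial hit list
can acquire indirect support.  The query is called positive when the top-beta
peptides by indirect score contain strictly more than gamma positives; the
confidence is the positive fraction of those top-beta hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import NoiseParams, Peptide, POSITIVE

logger = logging.getLogger("postmod")


@dataclass
class IndirectMatrix:
    """Sparse top-alpha neighbor relationships of the hit peptides.

    ``entries[(j, i)]`` holds the combined similarity between hit ``j`` and
    reference peptide ``i`` (indices into the reference list) whenever ``i``
    is among the top-alpha neighbors of ``j``; everything else is implicitly
    zero.  No self-relationships.
    """

    n: int
    hits: list
    entries: dict

    def __post_init__(self):
        for (j, i), v in self.entries.items():
            if j == i:
                raise ValueError("self-relationship in indirect matrix")
            if v < 0:
                raise ValueError("indirect matrix entries must be >= 0")


@dataclass
class PredictionResult:
    query: Peptide | None
    predicted_positive: bool
    confidence: float
    n_pos_in_top_beta: int
    beta: int
    gamma: int
    indirect_scores: np.ndarray | None = None
    direct_ranks: list = field(default_factory=list)
    indirect_ranks: list = field(default_factory=list)
    #: mean combined similarity of the top-alpha direct hits; deterministic
    #: tie-break when ranking queries by confidence (e.g. for ROC curves).
    tiebreak: float = 0.0


def _ordered(scores: np.ndarray, keys: list, secondary: np.ndarray | None = None):
    """Indices sorted by score desc, then secondary desc, then key asc."""
    idx = list(range(len(keys)))
    if secondary is None:
        idx.sort(key=lambda i: (-scores[i], keys[i]))
    else:
        idx.sort(key=lambda i: (-scores[i], -secondary[i], keys[i]))
    return idx


def top_hits(query_scores: np.ndarray, keys: list, alpha: int) -> list[int]:
    """Indices of the alpha reference peptides most similar to the query,
    descending; ties broken by ascending peptide key."""
    n = len(keys)
    if alpha > n:
        logger.warning("alpha=%d exceeds reference size %d; clamping", alpha, n)
        alpha = n
    return _ordered(np.asarray(query_scores, dtype=float), keys)[:alpha]


def build_indirect_matrix(
    hits: list[int], ref_scores: np.ndarray, keys: list, alpha: int
) -> IndirectMatrix:
    """For each hit, keep its top-alpha reference neighbors (self excluded)."""
    ref_scores = np.asarray(ref_scores, dtype=float)
    n = len(keys)
    entries: dict = {}
    for j in hits:
        order = _ordered(ref_scores[j], keys)
        kept = 0
        for i in order:
            if i == j:
                continue
            entries[(j, i)] = float(ref_scores[j, i])
            kept += 1
            if kept == min(alpha, n - 1):
                break
    return IndirectMatrix(n=n, hits=list(hits), entries=entries)


def indirect_scores(M: IndirectMatrix, labels: list, weight: float) -> np.ndarray:
    """Signed, weighted indirect score of every reference peptide.

    Each relationship ``(j, i)`` contributes ``sign * w(partner) * value`` to
    both endpoints, where ``sign`` is +1 for same-label pairs and -1
    otherwise, and ``w(partner)`` is ``weight`` when the partner peptide is
    positive and 1 when it is negative.  Peptides with no relationships
    score 0.
    """
    if len(labels) != M.n:
        raise ValueError(f"{M.n} peptides in matrix but {len(labels)} labels")
    scores = np.zeros(M.n)
    for (j, i), v in M.entries.items():
        sign = 1.0 if labels[j] == labels[i] else -1.0
        scores[j] += sign * (weight if labels[i] == POSITIVE else 1.0) * v
        scores[i] += sign * (weight if labels[j] == POSITIVE else 1.0) * v
    return scores


def _decide(order, labels, params: NoiseParams, n: int):
    beta = params.beta
    if beta > n:
        logger.warning("beta=%d exceeds reference size %d; clamping", beta, n)
        beta = n
    top_beta = order[:beta]
    n_pos = sum(1 for i in top_beta if labels[i] == POSITIVE)
    return beta, n_pos, n_pos > params.gamma, n_pos / beta


def classify(
    query: Peptide | None,
    reference: list[Peptide],
    query_scores: np.ndarray,
    ref_scores: np.ndarray,
    params: NoiseParams,
) -> PredictionResult:
    """Noise-reducing classification of one query against the reference set.

    ``query_scores`` are the combined similarities of the query to each
    reference peptide; ``ref_scores`` the all-pairs combined similarities
    among reference peptides.  The query itself must not be in the reference.
    """
    if not reference:
        raise ValueError("reference set is empty")
    keys = [p.key for p in reference]
    labels = [p.label for p in reference]
    query_scores = np.asarray(query_scores, dtype=float)

    hits = top_hits(query_scores, keys, params.alpha)
    M = build_indirect_matrix(hits, ref_scores, keys, params.alpha)
    ind = indirect_scores(M, labels, params.weight)

    order = _ordered(ind, keys, secondary=query_scores)
    beta, n_pos, positive, confidence = _decide(order, labels, params, len(reference))
    return PredictionResult(
        query=query,
        predicted_positive=positive,
        confidence=confidence,
        n_pos_in_top_beta=n_pos,
        beta=beta,
        gamma=params.gamma,
        indirect_scores=ind,
        direct_ranks=_ordered(query_scores, keys),
        indirect_ranks=order,
        tiebreak=float(np.mean(query_scores[hits])) if hits else 0.0,
    )


def classify_direct(
    query: Peptide | None,
    reference: list[Peptide],
    query_scores: np.ndarray,
    params: NoiseParams,
) -> PredictionResult:
    """Baseline classifier: same top-beta/gamma decision, but ranking the
    reference by a direct similarity score instead of the indirect score."""
    if not reference:
        raise ValueError("reference set is empty")
    keys = [p.key for p in reference]
    labels = [p.label for p in reference]
    query_scores = np.asarray(query_scores, dtype=float)

    order = _ordered(query_scores, keys)
    beta, n_pos, positive, confidence = _decide(order, labels, params, len(reference))
    hits = order[: min(params.alpha, len(reference))]
    return PredictionResult(
        query=query,
        predicted_positive=positive,
        confidence=confidence,
        n_pos_in_top_beta=n_pos,
        beta=beta,
        gamma=params.gamma,
        indirect_scores=None,
        direct_ranks=order,
        indirect_ranks=order,
        tiebreak=float(np.mean(query_scores[hits])) if len(hits) else 0.0,
    )
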