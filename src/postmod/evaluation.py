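"""Cross-validation harness and metrics.

Leave-one-out and stratified k-fold cross-validation over a reference set,
accuracy/precision/recall, ROC machinery (classic normalized AUC plus the
cumulative true-matches-vs-false-matches readout) and the four-level
feature ablation (window score, profile score, combined score,
noise-reducing classifier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    NEGATIVE,
    POSITIVE,
    NoiseParams,
    SubstitutionMatrix,
    default_noise_params,
)
from .io_formats import ReferenceSet
from .noise_reduction import PredictionResult, classify, classify_direct
from .similarity import AlignmentParams, ScoreMatrix, score_matrix

logger = logging.getLogger("postmod")

FEATURES = ("blosum", "profile", "combined", "noise")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Accuracy, precision and recall with their underlying counts.

    ``precision_defined`` is False when no positives were predicted, in
    which case precision is reported as 0 and flagged.
    """

    counts: ConfusionCounts
    acc: float
    precision: float
    recall: float
    precision_defined: bool
    feature: str = "noise"

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, feature: str = "noise") -> "MetricReport":
        acc = (counts.tp + counts.tn) / counts.total if counts.total else 0.0
        denom = counts.tp + counts.fp
        precision = counts.tp / denom if denom else 0.0
        rec_denom = counts.tp + counts.fn
        recall = counts.tp / rec_denom if rec_denom else 0.0
        return cls(
            counts=counts,
            acc=acc,
            precision=precision,
            recall=recall,
            precision_defined=denom > 0,
            feature=feature,
        )

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "acc": self.acc,
            "precision": self.precision,
            "recall": self.recall,
            "precision_defined": self.precision_defined,
            "counts": {
                "tp": self.counts.tp, "tn": self.counts.tn,
                "fp": self.counts.fp, "fn": self.counts.fn,
            },
        }


def evaluate_predictions(labels: list, predicted: list, feature: str = "noise") -> MetricReport:
    """Confusion counts and metrics for per-query boolean predictions."""
    if len(labels) != len(predicted):
        raise ValueError("labels and predictions differ in length")
    tp = sum(1 for l, p in zip(labels, predicted) if p and l == POSITIVE)
    fp = sum(1 for l, p in zip(labels, predicted) if p and l == NEGATIVE)
    fn = sum(1 for l, p in zip(labels, predicted) if not p and l == POSITIVE)
    tn = sum(1 for l, p in zip(labels, predicted) if not p and l == NEGATIVE)
    return MetricReport.from_counts(ConfusionCounts(tp, tn, fp, fn), feature=feature)


@dataclass
class QueryResult:
    key: str
    label: str
    predicted: bool
    confidence: float
    tiebreak: float


def _query_feature_scores(scores: ScoreMatrix, feature: str) -> np.ndarray:
    if feature == "blosum":
        return scores.s_blosum
    if feature == "profile":
        return scores.s_profile
    if feature in ("combined", "noise"):
        return scores.s_combined
    raise ValueError(f"unknown feature {feature!r}; choose from {FEATURES}")


def _classify_left_out(
    q: int,
    keep: list[int],
    peptides: list,
    scores: ScoreMatrix,
    feature: str,
    params: NoiseParams | None,
    force_weight: float | None,
) -> PredictionResult:
    reference = [peptides[i] for i in keep]
    if params is None:
        n_pos = sum(1 for p in reference if p.label == POSITIVE)
        n_neg = len(reference) - n_pos
        fold_params = default_noise_params(n_pos, n_neg, force_weight=force_weight)
    else:
        fold_params = params
    direct = _query_feature_scores(scores, feature)[q][keep]
    if feature == "noise":
        ref_scores = scores.s_combined[np.ix_(keep, keep)]
        return classify(peptides[q], reference, direct, ref_scores, fold_params)
    return classify_direct(peptides[q], reference, direct, fold_params)


def loocv(
    refset: ReferenceSet,
    feature: str = "noise",
    params: NoiseParams | None = None,
    matrix: SubstitutionMatrix | None = None,
    align_params: AlignmentParams | None = None,
    force_weight: float | None = None,
    scores: ScoreMatrix | None = None,
):
    """Leave-one-out cross-validation.

    Each peptide in turn becomes the query: it is removed from the reference
    (and from all top-alpha computations) and classified against the rest.
    Unless ``params`` is given, noise parameters are rederived from the
    remaining label counts for every fold.

    Returns ``(MetricReport, list[QueryResult])``.
    """
    peptides = refset.peptides
    if sum(1 for p in peptides if p.label == POSITIVE) < 2:
        raise ValueError("LOOCV needs at least 2 positive peptides")
    if scores is None:
        matrix = matrix or SubstitutionMatrix.blosum62()
        scores = score_matrix(peptides, refset.profiles, matrix, align_params)
    n = len(peptides)
    results = []
    for q in range(n):
        keep = [i for i in range(n) if i != q]
        res = _classify_left_out(q, keep, peptides, scores, feature, params, force_weight)
        results.append(
            QueryResult(
                key=peptides[q].key,
                label=peptides[q].label,
                predicted=res.predicted_positive,
                confidence=res.confidence,
                tiebreak=res.tiebreak,
            )
        )
    report = evaluate_predictions(
        [r.label for r in results], [r.predicted for r in results], feature=feature
    )
    return report, results


def kfold(
    refset: ReferenceSet,
    k: int = 10,
    feature: str = "noise",
    params: NoiseParams | None = None,
    seed: int = 0,
    matrix: SubstitutionMatrix | None = None,
    align_params: AlignmentParams | None = None,
    force_weight: float | None = None,
    scores: ScoreMatrix | None = None,
):
    """Stratified k-fold cross-validation.

    Folds are stratified by label so each preserves the negative:positive
    ratio up to rounding (fold sizes differ by at most one per class).
    Returns ``(mean MetricReport, per-fold MetricReports, QueryResults)``.
    With ``k`` equal to the number of peptides this reduces to LOOCV.
    """
    peptides = refset.peptides
    n = len(peptides)
    pos_idx = [i for i in range(n) if peptides[i].label == POSITIVE]
    neg_idx = [i for i in range(n) if peptides[i].label == NEGATIVE]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of peptides ({n})")
    if k > min(len(pos_idx), len(neg_idx)):
        logger.warning("k=%d exceeds the smaller class size; some folds will "
                       "miss one class", k)
    rng = np.random.default_rng(seed)
    rng.shuffle(pos_idx)
    rng.shuffle(neg_idx)
    # deal classes consecutively with a continuing cursor: per-class fold
    # sizes differ by at most one, and k == n reduces to leave-one-out
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for i in pos_idx + neg_idx:
        folds[cursor % k].append(i)
        cursor += 1

    if scores is None:
        matrix = matrix or SubstitutionMatrix.blosum62()
        scores = score_matrix(peptides, refset.profiles, matrix, align_params)

    fold_reports, results = [], []
    for fold in folds:
        if not fold:
            continue
        in_fold = set(fold)
        keep = [i for i in range(n) if i not in in_fold]
        fold_results = []
        for q in sorted(fold):
            res = _classify_left_out(q, keep, peptides, scores, feature, params, force_weight)
            fold_results.append(
                QueryResult(
                    key=peptides[q].key,
                    label=peptides[q].label,
                    predicted=res.predicted_positive,
                    confidence=res.confidence,
                    tiebreak=res.tiebreak,
                )
            )
        fold_reports.append(
            evaluate_predictions(
                [r.label for r in fold_results],
                [r.predicted for r in fold_results],
                feature=feature,
            )
        )
        results.extend(fold_results)

    counts = ConfusionCounts(
        tp=sum(r.counts.tp for r in fold_reports),
        tn=sum(r.counts.tn for r in fold_reports),
        fp=sum(r.counts.fp for r in fold_reports),
        fn=sum(r.counts.fn for r in fold_reports),
    )
    mean_report = MetricReport(
        counts=counts,
        acc=float(np.mean([r.acc for r in fold_reports])),
        precision=float(np.mean([r.precision for r in fold_reports])),
        recall=float(np.mean([r.recall for r in fold_reports])),
        precision_defined=any(r.precision_defined for r in fold_reports),
        feature=feature,
    )
    return mean_report, fold_reports, results


@dataclass
class RocCurve:
    """Cumulative (false-match, true-match) counts, descending score order."""

    points: np.ndarray  # (m, 2) columns: fp count, tp count
    auc: float
    thresholds: np.ndarray

    def true_matches(self, max_false: int) -> int:
        """True matches accumulated up to ``max_false`` false matches."""
        ok = self.points[self.points[:, 0] <= max_false]
        return int(ok[-1, 1]) if len(ok) else 0


def roc_curve(scores, labels, tiebreak=None) -> RocCurve:
    """ROC as cumulative true positives against false positives.

    Queries are sorted by score descending (optionally refined by a
    deterministic ``tiebreak``); exactly tied queries step all at once, which
    makes the normalized area equal the Mann-Whitney statistic with ties
    counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if l == POSITIVE else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    tb = np.zeros_like(scores) if tiebreak is None else np.asarray(tiebreak, dtype=float)

    order = np.lexsort((-tb, -scores))
    points, thresholds = [(0, 0)], []
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while (
            j < len(order)
            and scores[order[j]] == scores[order[i]]
            and tb[order[j]] == tb[order[i]]
        ):
            j += 1
        block = order[i:j]
        tp += int(y[block].sum())
        fp += len(block) - int(y[block].sum())
        points.append((fp, tp))
        thresholds.append(scores[order[i]])
        i = j
    pts = np.array(points)
    # trapezoid over the tie blocks == Mann-Whitney with half ties
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]) / (n_pos * n_neg))
    return RocCurve(points=pts, auc=auc, thresholds=np.array(thresholds))


def roc_from_results(results) -> RocCurve:
    """ROC over classifier outputs, ranking by confidence with the mean
    top-alpha combined similarity as tie-break."""
    return roc_curve(
        [r.confidence for r in results],
        [r.label for r in results],
        tiebreak=[r.tiebreak for r in results],
    )


def ablation_report(
    refset: ReferenceSet,
    params: NoiseParams | None = None,
    matrix: SubstitutionMatrix | None = None,
    align_params: AlignmentParams | None = None,
    force_weight: float | None = None,
) -> dict[str, MetricReport]:
    """LOOCV metrics for each of the four feature levels.

    The all-pairs score matrix is computed once and shared across levels.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    scores = score_matrix(refset.peptides, refset.profiles, matrix, align_params)
    reports = {}
    for feature in FEATURES:
        report, _ = loocv(
            refset, feature=feature, params=params, force_weight=force_weight,
            scores=scores,
        )
        reports[feature] = report
    return reports
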