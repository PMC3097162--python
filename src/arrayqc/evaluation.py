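"""Quality-assessment harness: bottom-line Q functions and array-removal
experiments.

Quality of array j is quantified by its influence on a bottom-line result:
Delta_j = Q(A_-j) - Q(A), where Q scores the result of the full analysis f
(differential-expression AUC, negated mean replicate distance, or
prediction MCC) and A_-j is the data with array j removed and the
probe-level model refitted.  Delta_j > 0 means removing the array improves
the bottom line — the signature of a poor-quality array.  All Q are
oriented "higher is better" so that convention holds uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ExpressionSet, ProbeLevelData, ValidationError
from .plm import preprocess

# Q function signature: (fit, kept_array_ids) -> float, or None if the
# subset is too small for this Q (e.g. a group reduced below 2 arrays).
QFunction = Callable[[ExpressionSet, Sequence[str]], "float | None"]


@dataclass
class EvaluationResult:
    """Outcome of a leave-one-out or removal-curve experiment."""

    metric_name: str
    q_full: float
    delta: dict[str, float] = field(default_factory=dict)
    removal_curve: list[tuple[int, float]] = field(default_factory=list)
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    undefined: list[str] = field(default_factory=list)

    @property
    def worst_array(self) -> str | None:
        """Array with the largest Delta_j (most harmful), if any defined."""
        if not self.delta:
            return None
        return max(self.delta, key=lambda a: self.delta[a])

    def write(self, path: str | Path) -> None:
        doc = {
            "metric_name": self.metric_name,
            "q_full": self.q_full,
            "delta": self.delta,
            "removal_curve": self.removal_curve,
            "roc": self.roc,
            "auc": self.auc,
            "undefined": self.undefined,
            "worst_array": self.worst_array,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def ttest_fdr(expr: ExpressionSet, groups: dict[str, str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t-test per probeset with BH q-values.

    ``groups`` maps array id to one of exactly two labels; each group needs
    >= 2 arrays.  Degenerate probesets with zero variance in both groups
    get p = 0 if the group means differ and p = 1 otherwise.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValidationError("ttest_fdr needs exactly two group labels")
    idx = {lab: [j for j, a in enumerate(expr.array_ids) if groups.get(a) == lab]
           for lab in labels}
    n1, n2 = len(idx[labels[0]]), len(idx[labels[1]])
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 arrays")
    X1 = expr.theta_hat[:, idx[labels[0]]]
    X2 = expr.theta_hat[:, idx[labels[1]]]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1 = X1.var(axis=1, ddof=1)
    v2 = X2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = denom == 0
    diff = m1 != m2
    t[degenerate & diff] = np.sign(m1 - m2)[degenerate & diff] * np.inf
    p[degenerate & diff] = 0.0
    t[degenerate & ~diff] = 0.0
    p[degenerate & ~diff] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    return t, p, q


def _de_ranking(expr: ExpressionSet, groups: dict[str, str]) -> list[int]:
    """Probeset indices from most to least significant: ascending q, ties
    broken by descending |t| then probeset id (deterministic)."""
    t, _, q = ttest_fdr(expr, groups)
    order = sorted(range(len(q)),
                   key=lambda i: (q[i], -abs(t[i]) if np.isfinite(t[i]) else -np.inf,
                                  expr.probeset_ids[i]))
    return order


def roc_curve_from_ranking(order: Sequence[int], truth_idx: set[int]) -> tuple[list[tuple[float, float]], float]:
    """Stepwise ROC over all thresholds of a total ranking; AUC by the
    trapezoidal rule (equals Mann-Whitney U / (n1*n2) for a total order)."""
    n_pos = len(truth_idx)
    n_neg = len(order) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both positives and negatives")
    tp = fp = 0
    roc = [(0.0, 0.0)]
    auc = 0.0
    for i in order:
        if i in truth_idx:
            tp += 1
        else:
            fp += 1
            auc += tp
        roc.append((fp / n_neg, tp / n_pos))
    return roc, auc / (n_pos * n_neg)


def q_differential_expression(expr: ExpressionSet, groups: dict[str, str],
                              truth: Iterable[str]) -> tuple[list[tuple[float, float]], float]:
    """ROC and AUC for recovering the known spiked probesets from the
    t-test/FDR ranking; Q is the AUC."""
    truth = set(truth)
    if not truth:
        raise ValidationError("empty truth set")
    truth_idx = {i for i, g in enumerate(expr.probeset_ids) if g in truth}
    order = _de_ranking(expr, groups)
    return roc_curve_from_ranking(order, truth_idx)


def make_q_de(groups: dict[str, str], truth: Iterable[str]) -> QFunction:
    """Q = spike-detection AUC; undefined when a group drops below 2 arrays."""
    truth = set(truth)

    def q(fit: ExpressionSet, kept: Sequence[str]) -> float | None:
        sub = {a: groups[a] for a in kept if a in groups}
        counts: dict[str, int] = {}
        for lab in sub.values():
            counts[lab] = counts.get(lab, 0) + 1
        if len(counts) != 2 or min(counts.values()) < 2:
            return None
        _, auc = q_differential_expression(fit, sub, truth)
        return auc

    return q


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def q_clustering(expr: ExpressionSet,
                 replicate_pairs: Sequence[tuple[str, str]]) -> tuple[dict[tuple[str, str], float], float]:
    """Euclidean distance between replicate arrays' expression vectors.

    Returns per-pair distances and Q = mean distance (lower is better; the
    leave-one-out wrapper negates it so Delta_j > 0 still means improvement).
    """
    if not replicate_pairs:
        raise ValidationError("need >= 1 replicate pair")
    dists: dict[tuple[str, str], float] = {}
    for a, b in replicate_pairs:
        if a not in expr.array_ids or b not in expr.array_ids:
            raise ValidationError(f"pair member missing: ({a}, {b})")
        va = expr.theta_hat[:, expr.array_ids.index(a)]
        vb = expr.theta_hat[:, expr.array_ids.index(b)]
        dists[(a, b)] = float(np.linalg.norm(va - vb))
    return dists, float(np.mean(list(dists.values())))


def make_q_clustering(replicate_pairs: Sequence[tuple[str, str]]) -> QFunction:
    """Q = negated mean replicate distance over pairs fully present."""

    def q(fit: ExpressionSet, kept: Sequence[str]) -> float | None:
        kept_set = set(kept)
        pairs = [(a, b) for a, b in replicate_pairs
                 if a in kept_set and b in kept_set]
        if not pairs:
            return None
        _, mean_dist = q_clustering(fit, pairs)
        return -mean_dist

    return q


# ---------------------------------------------------------------------------
# prediction (nearest shrunken centroids, MCC)
# ---------------------------------------------------------------------------

def soft_threshold(d: np.ndarray, s: float) -> np.ndarray:
    """sign(d) * max(|d| - s, 0)."""
    return np.sign(d) * np.maximum(np.abs(d) - s, 0.0)


def pam_train_predict(train: np.ndarray, train_labels: Sequence[str],
                      test: np.ndarray, shrinkage: float = 0.0) -> list[str]:
    """Nearest-shrunken-centroid (PAM-style) classification.

    ``train``/``test`` are gene x sample matrices.  Per-class centroid
    deviations from the overall centroid are standardized by the pooled
    within-class deviation (plus a median offset s0), soft-thresholded by
    ``shrinkage``, and samples go to the class minimizing the discriminant
    score with log-prior correction; priors are training frequencies.  As
    shrinkage -> infinity every deviation vanishes and prediction falls
    back to the majority class.
    """
    if shrinkage < 0:
        raise ValidationError("shrinkage must be >= 0")
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    labels = sorted(set(train_labels))
    if len(labels) < 2:
        raise ValidationError("need >= 2 classes in training data")
    n = train.shape[1]
    overall = train.mean(axis=1)
    cent, mk, priors = {}, {}, {}
    within_ss = np.zeros(train.shape[0])
    for lab in labels:
        cols = [j for j, l in enumerate(train_labels) if l == lab]
        if not cols:
            raise ValidationError(f"class absent from training: {lab}")
        Xk = train[:, cols]
        cent[lab] = Xk.mean(axis=1)
        within_ss += ((Xk - cent[lab][:, None]) ** 2).sum(axis=1)
        mk[lab] = np.sqrt(max(1.0 / len(cols) - 1.0 / n, 0.0))
        priors[lab] = len(cols) / n
    s = np.sqrt(within_ss / max(n - len(labels), 1))
    s0 = float(np.median(s))
    denom = s + s0
    denom = np.where(denom > 0, denom, 1e-12)

    shrunken = {}
    for lab in labels:
        d = (cent[lab] - overall) / (mk[lab] * denom) if mk[lab] > 0 else \
            np.zeros_like(overall)
        dprime = soft_threshold(d, shrinkage)
        shrunken[lab] = overall + mk[lab] * denom * dprime

    preds = []
    for j in range(test.shape[1]):
        x = test[:, j]
        scores = {
            lab: float((((x - shrunken[lab]) / denom) ** 2).sum()
                       - 2.0 * np.log(priors[lab]))
            for lab in labels
        }
        preds.append(min(labels, key=lambda lab: (scores[lab], lab)))
    return preds


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    if min(tp, tn, fp, fn) < 0:
        raise ValidationError("confusion counts must be nonnegative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def make_q_pam(train_labels: dict[str, str], test_matrix: np.ndarray,
               test_labels: Sequence[str], positive: str,
               shrinkage: float = 1.0) -> QFunction:
    """Q = MCC of nearest-shrunken-centroid predictions on a fixed test set.

    The classifier is retrained on the current training subset's refitted
    expression estimates at every evaluation; the test expression matrix is
    preprocessed once and held fixed, mirroring a train/validation split.
    Undefined when a training class drops below 2 arrays.
    """

    def q(fit: ExpressionSet, kept: Sequence[str]) -> float | None:
        labs = [train_labels[a] for a in kept if a in train_labels]
        counts: dict[str, int] = {}
        for lab in labs:
            counts[lab] = counts.get(lab, 0) + 1
        if len(counts) < 2 or min(counts.values()) < 2:
            return None
        cols = [j for j, a in enumerate(fit.array_ids) if a in train_labels]
        preds = pam_train_predict(fit.theta_hat[:, cols],
                                  [train_labels[fit.array_ids[j]] for j in cols],
                                  test_matrix, shrinkage)
        return mcc_from_labels(test_labels, preds, positive)

    return q


def mcc_from_labels(true_labels: Sequence[str], pred_labels: Sequence[str],
                    positive: str) -> float:
    tp = sum(1 for t, p in zip(true_labels, pred_labels) if t == positive and p == positive)
    tn = sum(1 for t, p in zip(true_labels, pred_labels) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(true_labels, pred_labels) if t != positive and p == positive)
    fn = sum(1 for t, p in zip(true_labels, pred_labels) if t == positive and p != positive)
    return mcc(tp, tn, fp, fn)


# ---------------------------------------------------------------------------
# leave-one-out and removal curves
# ---------------------------------------------------------------------------

def leave_one_out(data: ProbeLevelData, q_function: QFunction,
                  metric_name: str = "Q") -> EvaluationResult:
    """Delta_j = Q(A_-j) - Q(A) for every array, refitting the full
    preprocessing (quantile normalization + robust fit) on each subset.

    Arrays whose removal makes Q uncomputable (e.g. a comparison group
    reduced below 2) are recorded as undefined rather than assigned a
    Delta.
    """
    fit_full = preprocess(data)
    q_full = q_function(fit_full, data.array_ids)
    if q_full is None:
        raise ValidationError("Q undefined on the full array set")
    result = EvaluationResult(metric_name=metric_name, q_full=q_full)
    for j, aid in enumerate(data.array_ids):
        kept = [a for a in data.array_ids if a != aid]
        fit_j = preprocess(data.subset_arrays(kept))
        q_j = q_function(fit_j, kept)
        if q_j is None:
            result.undefined.append(aid)
        else:
            result.delta[aid] = q_j - q_full
    return result


def removal_curve(data: ProbeLevelData, q_function: QFunction,
                  rank_metric: Callable[[ExpressionSet, ProbeLevelData], dict[str, float]],
                  n_max: int, metric_name: str = "metric") -> EvaluationResult:
    """Worst-first removal: iteratively drop the array the metric ranks
    worst (highest score), refit, and record Q after each removal.

    ``rank_metric`` maps (fit, data subset) to per-array scores where higher
    means worse quality; it is recomputed after every refit, as relative
    metrics like NUSE change when the batch changes.
    """
    if n_max >= data.n_arrays - 1:
        raise ValidationError("n_max leaves no viable array set")
    kept = list(data.array_ids)
    current = data
    fit = preprocess(current)
    q0 = q_function(fit, kept)
    if q0 is None:
        raise ValidationError("Q undefined on the full array set")
    result = EvaluationResult(metric_name=metric_name, q_full=q0,
                              removal_curve=[(0, q0)])
    for step in range(1, n_max + 1):
        scores = rank_metric(fit, current)
        worst = max(kept, key=lambda a: (scores[a], a))
        kept = [a for a in kept if a != worst]
        current = current.subset_arrays(kept)
        fit = preprocess(current)
        q = q_function(fit, kept)
        if q is None:
            break
        result.removal_curve.append((step, q))
    return result
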