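"""Metrics and the two evaluation protocols.

ACC here is the *balanced* accuracy — the average of sensitivity and
specificity — and AUC is computed exactly as the Mann–Whitney rank statistic
P[score_pos > score_neg] + ½ P[tie], so no threshold grid is involved.

:func:`compare_label_sources` reproduces the annotator-recommendation
protocol: fit the consensus model on a 40% training split, pick the
best-scoring annotator per mixture component, then compare downstream
logistic-regression classifiers trained on (a) a random annotator's labels,
(b) the recommended annotator's labels, and (c) the true labels, by 5-fold
cross-validation on the remaining 60%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .aggregators import AnnotatorProfile, run_aefn
from .annotations_io import MISSING, AnnotationMatrix, FeatureMatrix
from .config import RunConfig
from .errors import InputError, UndefinedMetricError
from .mixture import MixtureModel, hard_component, responsibilities
from .simulator import SimulationTruth


@dataclass(frozen=True)
class EvalReport:
    """Evaluation summary: balanced accuracy, exact AUC and the ROC polyline."""

    acc: float
    auc: float
    roc_points: tuple
    n_eval: int


def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity) / 2; requires both classes in the truth."""
    t = np.asarray(y_true, bool)
    p = np.asarray(y_pred, bool)
    if t.shape != p.shape:
        raise InputError("y_true and y_pred must have the same length")
    if t.all() or (~t).all():
        raise UndefinedMetricError("balanced accuracy needs both classes in y_true")
    sens = (p & t).sum() / t.sum()
    spec = (~p & ~t).sum() / (~t).sum()
    return float((sens + spec) / 2.0)


def roc_auc(y_true, scores, y_pred=None) -> EvalReport:
    """Exact rank-statistic AUC with tie correction, plus the ROC polyline.

    ``acc`` is the balanced accuracy of *y_pred* when given, else of the
    scores thresholded at 0.5 (scores are posterior probabilities throughout
    this package).
    """
    t = np.asarray(y_true, bool)
    s = np.asarray(scores, float)
    if t.shape != s.shape:
        raise InputError("y_true and scores must have the same length")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes in y_true")
    ranks = rankdata(s)  # average ranks implement the half-credit tie rule
    auc = (ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(t.astype(int), s)
    pred = np.asarray(y_pred, bool) if y_pred is not None else s > 0.5
    return EvalReport(acc=balanced_accuracy(t, pred), auc=float(auc),
                      roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
                      n_eval=int(t.size))


def recommend_annotator(model: MixtureModel, profile: AnnotatorProfile,
                        x_new: np.ndarray) -> int:
    """Best annotator (0-based index) for a new instance.

    The instance is assigned to its most responsible mixture component q and
    the active annotator with the highest ranking score S_q^j is returned;
    ties resolve to the lowest index.
    """
    x = np.atleast_2d(np.asarray(x_new, float))
    q = int(hard_component(responsibilities(model, x))[0])
    scores = np.where(profile.active[q], profile.score[q], -np.inf)
    return int(np.argmax(scores))


def best_annotator_per_component(profile: AnnotatorProfile) -> np.ndarray:
    """argmax_j S_k^j over each component's active set (ties → lowest index)."""
    scores = np.where(profile.active, profile.score, -np.inf)
    return np.argmax(scores, axis=1)


def _cv_auc(x: np.ndarray, labels: np.ndarray, y_true: np.ndarray,
            n_folds: int, seed: int) -> EvalReport:
    """Pooled cross-validated scores of a logistic classifier vs. the truth."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.full(len(y_true), np.nan)
    for train_idx, test_idx in skf.split(x, y_true.astype(int)):
        fold_labels = labels[train_idx]
        if len(np.unique(fold_labels)) < 2:
            warnings.warn("training fold has a single label class; fold skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        clf = LogisticRegression(max_iter=1000)
        clf.fit(x[train_idx], fold_labels)
        scores[test_idx] = clf.predict_proba(x[test_idx])[:, 1]
    ok = ~np.isnan(scores)
    if not ok.any():
        raise UndefinedMetricError("every cross-validation fold was skipped")
    return roc_auc(y_true[ok], scores[ok])


def compare_label_sources(truth_sim: SimulationTruth,
                          config: RunConfig | None = None,
                          train_fraction: float = 0.4,
                          n_folds: int = 5) -> dict[str, EvalReport]:
    """Compare downstream classifiers trained on three label sources.

    Splits the simulated data into a *train_fraction* / remainder partition
    stratified by the true label, runs the filtering consensus algorithm on
    the training part to learn per-component annotator recommendations, then
    evaluates three logistic classifiers on the held-out part by stratified
    ``n_folds``-fold cross-validation:

    - ``random``    — labels from a uniformly drawn annotator per instance,
    - ``indicated`` — labels from the recommended annotator of the
      instance's component,
    - ``truth``     — the true labels (the supervised ceiling).
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    x = truth_sim.features.values
    y = np.asarray(truth_sim.y_true, bool)
    labels = truth_sim.annotations.labels
    idx = np.arange(truth_sim.n)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y.astype(int),
        random_state=config.seed % (2 ** 31))

    ann_train = AnnotationMatrix(
        labels[train_idx],
        tuple(truth_sim.annotations.instance_ids[i] for i in train_idx),
        truth_sim.annotations.annotator_ids)
    feat_train = FeatureMatrix(x[train_idx], truth_sim.features.feature_names)
    _, profile, model = run_aefn(ann_train, feat_train, config)
    best = best_annotator_per_component(profile)

    x_test = x[test_idx]
    y_test = y[test_idx]
    labels_test = labels[test_idx]
    q_test = hard_component(responsibilities(model, x_test))

    def observed_or_random(i: int, j: int) -> int:
        if labels_test[i, j] != MISSING:
            return int(labels_test[i, j])
        observed = np.flatnonzero(labels_test[i] != MISSING)
        return int(labels_test[i, rng.choice(observed)])

    random_labels = np.array([
        observed_or_random(i, int(rng.integers(labels_test.shape[1])))
        for i in range(len(test_idx))])
    indicated_labels = np.array([
        observed_or_random(i, int(best[q_test[i]])) for i in range(len(test_idx))])

    cv_seed = int(rng.integers(2 ** 31))
    return {
        "random": _cv_auc(x_test, random_labels, y_test, n_folds, cv_seed),
        "indicated": _cv_auc(x_test, indicated_labels, y_test, n_folds, cv_seed),
        "truth": _cv_auc(x_test, y_test.astype(int), y_test, n_folds, cv_seed),
    }


def region_component_table(positions, lengths, components, k: int | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency counts of sequence region × mixture component.

    *positions* are 1-based residue positions, *lengths* the matching protein
    lengths, *components* the 0-based hard assignments. Returns (counts,
    row-normalized proportions) with regions as rows and components
    1..K as columns.
    """
    from .disorder_meta import region_of_position

    positions = np.asarray(positions, int)
    lengths = np.asarray(lengths, int)
    components = np.asarray(components, int)
    if not (positions.shape == lengths.shape == components.shape):
        raise InputError("positions, lengths and components must align")
    k = int(k if k is not None else components.max() + 1)
    regions = ("N-terminus", "internal", "C-terminus")
    counts = pd.DataFrame(0, index=list(regions),
                          columns=[f"component_{c + 1}" for c in range(k)])
    for pos, ln, comp in zip(positions, lengths, components):
        counts.loc[region_of_position(int(pos), int(ln)), f"component_{comp + 1}"] += 1
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0, 1), axis=0)
    return counts, props
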