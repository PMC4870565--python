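"""ROC evaluation of single-marker biomarkers.

Two modes mirror how candidate markers are assessed:

* ``classic`` — univariate AUC on all samples, computed by the
  Mann-Whitney pair-counting rule with half-credit for ties, oriented so
  AUC >= 0.5 (the direction is reported).
* ``cv5`` — stratified 5-fold cross-validation of a *linear threshold
  model*: for a single marker this reduces to an oriented threshold on the
  marker value, with the orientation learned from the training folds' group
  means and the held-out samples scored out-of-fold.  The reported AUC is
  the mean over folds.

A marker is called significant when its AUC strictly exceeds 0.70.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RocResult",
    "univariate_auc",
    "cv_threshold_auc",
    "classify_significant",
    "AUC_CUTOFF",
]

AUC_CUTOFF = 0.70


@dataclass
class RocResult:
    marker_id: str
    curve: np.ndarray  # ordered (FPR, TPR) points from (0,0) to (1,1)
    auc: float
    mode: str  # "classic" | "cv5"
    orientation: str  # "higher_in_case" | "lower_in_case"
    fold_aucs: tuple[float, ...] = ()
    fold_assignments: dict[int, tuple[str, ...]] = field(default_factory=dict)
    significant: bool = False


def _check_labels(labels: np.ndarray) -> np.ndarray:
    is_case = np.asarray([lab == "case" for lab in labels])
    if is_case.all() or (~is_case).all():
        raise ValueError("both classes must be present")
    return is_case


def _mw_auc(values: np.ndarray, is_case: np.ndarray) -> float:
    """AUC for 'case has higher values', ties at half credit.

    Equals the normalized Mann-Whitney U statistic:
    (concordant + 0.5 * tied) / (n_case * n_control), computed via midranks.
    """
    n1 = int(is_case.sum())
    n0 = int((~is_case).sum())
    ranks = stats.rankdata(values)  # midranks handle ties
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def univariate_auc(values, labels, marker_id: str = "marker") -> RocResult:
    """Classic univariate ROC: threshold sweep over all samples.

    The orientation is chosen so the reported AUC is >= 0.5 and the
    direction (marker higher or lower in cases) is recorded.
    """
    values = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("marker values must be finite")
    is_case = _check_labels(np.asarray(pd.Series(labels).to_numpy()))
    auc_raw = _mw_auc(values, is_case)
    if auc_raw >= 0.5:
        orientation, auc, scores = "higher_in_case", auc_raw, values
    else:
        orientation, auc, scores = "lower_in_case", 1.0 - auc_raw, -values
    fpr, tpr, _ = roc_curve(is_case.astype(int), scores)
    result = RocResult(
        marker_id=marker_id,
        curve=np.column_stack([fpr, tpr]),
        auc=auc,
        mode="classic",
        orientation=orientation,
    )
    result.significant = classify_significant(result)
    return result


def cv_threshold_auc(values, labels, k: int = 5, seed: int = 0,
                     marker_id: str = "marker") -> RocResult:
    """Stratified k-fold cross-validated AUC of the linear threshold model.

    Per fold, the orientation (sign) is fit on the training samples from the
    group means; held-out samples are scored as oriented marker values and
    the fold AUC is computed on them alone.  Folds containing a single class
    are excluded with a warning.  The reported AUC is the mean of fold AUCs;
    the pooled out-of-fold scores provide the plotted curve.
    """
    ser = pd.Series(values)
    sample_ids = np.asarray(ser.index.astype(str))
    values = np.asarray(ser.to_numpy(), dtype=float)
    is_case = _check_labels(np.asarray(pd.Series(labels).to_numpy()))
    min_class = min(int(is_case.sum()), int((~is_case).sum()))
    if min_class < 2:
        raise ValueError("each class needs at least 2 samples for cross-validation")
    if min_class < k:
        warnings.warn(f"reducing k from {k} to {min_class} (smallest class size)")
        k = max(2, min_class)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    fold_assignments: dict[int, tuple[str, ...]] = {}
    pooled_scores = np.empty_like(values)
    pooled_mask = np.zeros(len(values), dtype=bool)
    skipped = 0
    for fold, (tr, te) in enumerate(skf.split(values.reshape(-1, 1), is_case)):
        fold_assignments[fold] = tuple(sample_ids[te])
        sign = 1.0 if values[tr][is_case[tr]].mean() >= values[tr][~is_case[tr]].mean() else -1.0
        scores = sign * values[te]
        pooled_scores[te] = scores
        pooled_mask[te] = True
        if is_case[te].all() or (~is_case[te]).all():
            skipped += 1
            continue
        fold_aucs.append(_mw_auc(scores, is_case[te]))
    if skipped:
        warnings.warn(f"{skipped} fold(s) had a single class; excluded from the mean AUC")
    if not fold_aucs:
        raise ValueError("no fold contained both classes")

    fpr, tpr, _ = roc_curve(is_case[pooled_mask].astype(int), pooled_scores[pooled_mask])
    overall_sign = 1.0 if values[is_case].mean() >= values[~is_case].mean() else -1.0
    result = RocResult(
        marker_id=marker_id,
        curve=np.column_stack([fpr, tpr]),
        auc=float(np.mean(fold_aucs)),
        mode="cv5",
        orientation="higher_in_case" if overall_sign > 0 else "lower_in_case",
        fold_aucs=tuple(fold_aucs),
        fold_assignments=fold_assignments,
    )
    result.significant = classify_significant(result)
    return result


def classify_significant(r: RocResult, cutoff: float = AUC_CUTOFF) -> bool:
    """Biomarker call: AUC strictly in excess of the cutoff (default 0.70)."""
    return bool(r.auc > cutoff)
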