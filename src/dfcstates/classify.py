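"""Per-state group discrimination with elastic-net logistic regression.

For each connectivity state, subjects' windowed connectivity features are
assembled into a labeled dataset (one row per subject by default: the
elementwise median of that subject's windows assigned to the state).  A
logistic model with elastic-net regularization is fit under 10-fold nested
cross-validation (train-test 9:1 in both loops); the regularization
strength is swept across 100 logarithmically spaced values between 1e-5
and 1e5 and tuned to minimize inner-fold CV error.  Separability is
summarized by the pooled-outer-fold ROC AUC, and feature importance by the
retention proportion: the fraction of inner-fold models along the sweep in
which a feature's coefficient stays nonzero.  A one-way ANOVA with Tukey
multiple comparisons groups the equally important top features, whose
group differences are then tested (Welch t, Benjamini-Hochberg FDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._enet import default_lambda_grid, logistic_enet_path
from .association import bh_fdr

__all__ = [
    "ClassificationDataset",
    "ENRPath",
    "ClassificationReport",
    "build_state_dataset",
    "enr_path",
    "nested_cv_classify",
    "group_top_features",
    "group_difference_test",
]


@dataclass
class ClassificationDataset:
    """Feature matrix and binary labels for one state's SZ-vs-HC contrast.

    ``y`` codes the clinical group as 1 and controls as 0.  When the sample
    unit is the window, ``subject_ids`` repeat and cross-validation folds
    must never split one subject across train and test.
    """

    state_id: int
    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    sample_unit: str  # "subject-median" | "window"
    feature_names: list[str] = field(default_factory=list)
    excluded_subjects: list[str] = field(default_factory=list)


@dataclass
class ENRPath:
    """Elastic-net regularization path over the lambda grid (ascending)."""

    lambda_grid: np.ndarray
    alpha: float
    intercepts: np.ndarray  # (n_lambda,)
    coefficients: np.ndarray  # (n_lambda, n_features)

    @property
    def retained(self) -> np.ndarray:
        """Boolean (n_lambda, n_features): coefficient strictly nonzero."""
        return self.coefficients != 0.0


@dataclass
class ClassificationReport:
    state_id: int
    auc: float
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    importance: np.ndarray  # mean retention proportion per feature
    importance_per_fold: np.ndarray  # (outer_folds, n_features)
    lambda_selected: np.ndarray  # per outer fold
    feature_names: list[str]
    top_group: list[int] | None = None
    group_diff: pd.DataFrame | None = None


def build_state_dataset(
    dfc_list: list,
    state_sequences: list,
    state_id: int,
    labels: dict[str, str],
    sample_unit: str = "subject-median",
    positive_group: str = "SZ",
) -> ClassificationDataset:
    """Assemble the per-state dataset from windowed features and sequences.

    ``sample_unit="subject-median"`` (default) takes, per subject, the
    elementwise median of the windows assigned to ``state_id`` (1-based);
    subjects with no window in the state are excluded and listed.
    ``sample_unit="window"`` keeps one row per window, with repeated
    subject ids so folds can be grouped by subject.

    Raises
    ------
    ValueError
        If a class is absent after exclusions.
    """
    if sample_unit not in ("subject-median", "window"):
        raise ValueError(f"unknown sample_unit {sample_unit!r}")
    seq_by_id = {s.subject_id: s for s in state_sequences}
    rows, ys, sids, excluded = [], [], [], []
    names = [f"C{i + 1}" for i in range(dfc_list[0].n_features)]
    for d in dfc_list:
        seq = seq_by_id[d.subject_id]
        mask = np.asarray(seq.states) == state_id
        if not mask.any():
            excluded.append(d.subject_id)
            continue
        lab = 1 if labels[d.subject_id] == positive_group else 0
        if sample_unit == "subject-median":
            rows.append(np.median(d.features[mask], axis=0))
            ys.append(lab)
            sids.append(d.subject_id)
        else:
            for row in d.features[mask]:
                rows.append(row)
                ys.append(lab)
                sids.append(d.subject_id)
    y = np.asarray(ys, dtype=int)
    if len(y) == 0 or y.min() == y.max():
        raise ValueError(
            f"state {state_id}: a class is absent after excluding subjects "
            f"with no windows in the state ({len(excluded)} excluded)"
        )
    return ClassificationDataset(
        state_id=state_id,
        X=np.vstack(rows),
        y=y,
        subject_ids=sids,
        sample_unit=sample_unit,
        feature_names=names,
        excluded_subjects=excluded,
    )


def enr_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
) -> ENRPath:
    """Elastic-net logistic regularization path (intercept unpenalized).

    Features are expected to be standardized (z-scored on the training
    split) by the caller.  At the largest default grid point (1e5) every
    penalized coefficient is exactly zero.
    """
    grid, b0, coefs = logistic_enet_path(X, y, alpha=alpha, lambda_grid=lambda_grid)
    return ENRPath(grid, alpha, b0, coefs)


def _zscore_train(Xtr: np.ndarray, X: np.ndarray) -> np.ndarray:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def nested_cv_classify(
    ds: ClassificationDataset,
    outer_folds: int = 10,
    inner_folds: int = 9,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> ClassificationReport:
    """Nested cross-validated elastic-net logistic classification.

    The outer loop holds out one fold (train-test 9:1 with 10 folds); the
    inner loop sweeps the lambda grid on each inner split of the outer
    training set and selects the lambda minimizing mean inner-fold
    misclassification error (ties toward the more regularized model).  The
    outer model is refit at the selected lambda and its held-out
    probabilities pooled across folds into a single ROC/AUC.  Retention
    proportions aggregate coefficient-nonzero flags over inner folds x grid
    points.  Folds are stratified and grouped by subject so no subject is
    split across train and test.  Deterministic given ``seed``.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    X, y = ds.X, ds.y
    groups = np.asarray(ds.subject_ids)
    n_class_min = min(np.bincount(y))
    if len(set(ds.subject_ids)) < outer_folds or n_class_min < outer_folds:
        raise ValueError(
            f"need at least {outer_folds} subjects per class for "
            f"{outer_folds}-fold stratified grouped CV (smallest class has "
            f"{n_class_min} samples)"
        )
    rng = np.random.default_rng(seed)
    outer = StratifiedGroupKFold(
        n_splits=outer_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    p = X.shape[1]
    scores = np.empty(len(y))
    importance_per_fold = np.zeros((outer_folds, p))
    lambda_selected = np.zeros(outer_folds)
    for fold, (tr, te) in enumerate(outer.split(X, y, groups)):
        assert not set(groups[tr]) & set(groups[te])
        Xtr, ytr = X[tr], y[tr]
        inner = StratifiedGroupKFold(
            n_splits=inner_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        err = np.zeros(len(lambda_grid))
        retain = np.zeros((len(lambda_grid), p))
        n_inner = 0
        for itr, iva in inner.split(Xtr, ytr, groups[tr]):
            Xi = _zscore_train(Xtr[itr], Xtr[itr])
            Xv = _zscore_train(Xtr[itr], Xtr[iva])
            path = enr_path(Xi, ytr[itr], alpha=alpha, lambda_grid=lambda_grid)
            eta = path.intercepts[:, None] + path.coefficients @ Xv.T
            pred = (eta > 0).astype(int)
            err += (pred != ytr[iva][None, :]).mean(axis=1)
            retain += path.retained
            n_inner += 1
        err /= n_inner
        # ties toward the larger lambda (more regularized)
        best = len(err) - 1 - int(np.argmin(err[::-1]))
        lambda_selected[fold] = lambda_grid[best]
        importance_per_fold[fold] = retain.mean(axis=0) / n_inner
        Xtr_z = _zscore_train(Xtr, Xtr)
        Xte_z = _zscore_train(Xtr, X[te])
        path = enr_path(Xtr_z, ytr, alpha=alpha, lambda_grid=lambda_grid)
        eta_te = path.intercepts[best] + Xte_z @ path.coefficients[best]
        scores[te] = 1.0 / (1.0 + np.exp(-eta_te))
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return ClassificationReport(
        state_id=ds.state_id,
        auc=auc,
        roc_points=roc_points,
        importance=importance_per_fold.mean(axis=0),
        importance_per_fold=importance_per_fold,
        lambda_selected=lambda_selected,
        feature_names=list(ds.feature_names),
    )


def group_top_features(
    importance_per_fold: np.ndarray, family_alpha: float = 0.05
) -> list[int]:
    """Indices of the group of equally important top features.

    A one-way ANOVA across features on per-fold retention proportions,
    followed by Tukey pairwise multiple comparisons at family level
    ``family_alpha``, returns every feature whose retention is not
    significantly different from the feature with maximal mean retention.
    With zero variance everywhere all features are returned with a warning.
    """
    imp = np.asarray(importance_per_fold, dtype=float)
    if imp.ndim != 2 or imp.shape[0] < 2:
        raise ValueError("need per-fold retention with >= 2 folds")
    folds, p = imp.shape
    means = imp.mean(axis=0)
    best = int(np.argmax(means))
    within_sd = imp.std(axis=0)
    if np.allclose(imp, imp[0][None, :]):
        if np.ptp(means) == 0:
            warnings.warn("retention has zero variance everywhere; "
                          "returning all features", stacklevel=2)
            return list(range(p))
        # No within-feature variance but distinct means: the comparison is
        # exact -- the top group is the set of features tied with the best.
        return [j for j in range(p) if np.isclose(means[j], means[best])]
    values = imp.T.reshape(-1)
    labels = np.repeat(np.arange(p), folds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tk = pairwise_tukeyhsd(values, labels, alpha=family_alpha)
    reject = np.asarray(tk.reject)
    g1 = np.asarray(tk.groupsunique)[tk._multicomp.pairindices[0]]
    g2 = np.asarray(tk.groupsunique)[tk._multicomp.pairindices[1]]
    top = {best}
    for a, b, rej in zip(g1, g2, reject):
        if rej:
            continue
        if a == best:
            top.add(int(b))
        elif b == best:
            top.add(int(a))
    return sorted(top)


def group_difference_test(
    ds: ClassificationDataset, features: list[int]
) -> pd.DataFrame:
    """Welch two-sample tests on the selected features, BH-corrected.

    Direction is ``sign(mean_HC - mean_SZ)``: positive means stronger
    connectivity in controls, negative stronger in the clinical group.
    Features constant within both groups get p = 1 by convention (noted).
    """
    rows = []
    hc = ds.X[ds.y == 0]
    sz = ds.X[ds.y == 1]
    for j in features:
        a, b = hc[:, j], sz[:, j]
        note = ""
        if a.std() == 0 and b.std() == 0:
            pval = 1.0
            note = "constant within both groups"
        else:
            pval = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append({
            "feature": ds.feature_names[j] if ds.feature_names else str(j),
            "feature_idx": j,
            "mean_hc": float(a.mean()),
            "mean_sz": float(b.mean()),
            "direction": float(np.sign(a.mean() - b.mean())),
            "p": pval,
            "note": note,
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
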