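"""Covariate-adjusted symptom association of transition features.

Each transition-probability feature is correlated with each symptom scale
(e.g. PANSS positive/negative/total) across clinical subjects by Pearson's
partial correlation accounting for covariates (age, gender, site), with
Benjamini-Hochberg FDR correction within the K^2-feature family of each
scale.  Missing scores and features from unvisited states are handled by
pairwise deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transitions import TransitionMatrix, feature_names

__all__ = [
    "AssociationReport",
    "partial_correlation",
    "bh_fdr",
    "associate_transitions",
]


@dataclass
class AssociationReport:
    """Partial-correlation results per (transition feature, symptom scale)."""

    table: pd.DataFrame  # columns: scale, feature, r, n, p, q
    covariates: list[str]
    excluded: dict[str, list[str]] = field(default_factory=dict)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson partial correlation of x and y given covariate columns.

    Both variables are residualized on [intercept | covariates] by least
    squares; r is the Pearson correlation of the residuals and the p-value
    comes from t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees
    of freedom (two-sided), k = number of covariate columns.  With no
    covariates this reduces exactly to the plain Pearson correlation.

    Returns ``(nan, nan)`` when either residual is (numerically) constant,
    e.g. when a variable is an exact linear function of the covariates.

    Raises
    ------
    ValueError
        If lengths differ, inputs are non-finite, or n <= k + 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.shape[0]
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
        if z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError(
            f"partial correlation needs n > k + 2 observations (n={n}, k={k})"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("inputs must be finite (apply pairwise deletion first)")
    design = np.column_stack([np.ones(n), z])
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if rx.std() <= 1e-12 * scale or ry.std() <= 1e-12 * scale:
        return float("nan"), float("nan")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = min(1.0, max(-1.0, r))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped
    to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def associate_transitions(
    tms: list[TransitionMatrix],
    symptoms: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    scales: list[str] | None = None,
) -> AssociationReport:
    """Partial-correlate every transition feature with every symptom scale.

    Parameters
    ----------
    tms : list of TransitionMatrix
        One per clinical (SZ) subject.
    symptoms : DataFrame indexed by subject id
        One column per scale; missing scores as NaN (pairwise deletion).
    covariates : DataFrame indexed by subject id, optional
        Numeric columns enter as-is; categorical/object columns are
        expanded to indicator columns.
    scales : list of str, optional
        Defaults to all symptom columns.

    For each scale, the partial correlation is computed per transition
    feature over subjects with a non-missing score and a visited
    originating state (flagged rows are deleted pairwise); BH correction
    is applied within the K^2 features of that scale.  Scales with no
    usable scores are skipped with a warning.
    """
    if not tms:
        raise ValueError("need at least one subject")
    k = tms[0].matrix.shape[0]
    names = feature_names(k)
    ids = [tm.subject_id for tm in tms]
    flat = np.stack([tm.matrix.reshape(-1) for tm in tms])
    visited = np.stack([np.repeat(~tm.unvisited_mask, k) for tm in tms])

    if covariates is not None and len(covariates.columns):
        cov = pd.get_dummies(covariates.loc[ids], drop_first=True).astype(float)
        cov_names = list(covariates.columns)
    else:
        cov = pd.DataFrame(index=pd.Index(ids))
        cov_names = []

    if scales is None:
        scales = list(symptoms.columns)
    rows = []
    excluded: dict[str, list[str]] = {}
    for scale in scales:
        if scale not in symptoms.columns:
            warnings.warn(f"scale {scale!r} missing from symptoms; skipped",
                          stacklevel=2)
            continue
        score = symptoms.reindex(ids)[scale].to_numpy(dtype=float)
        have_score = np.isfinite(score)
        if not have_score.any():
            warnings.warn(f"all scores missing for scale {scale!r}; skipped",
                          stacklevel=2)
            continue
        excluded[scale] = [i for i, ok in zip(ids, have_score) if not ok]
        scale_rows = []
        for f in range(k * k):
            mask = have_score & visited[:, f]
            n = int(mask.sum())
            kc = cov.shape[1]
            if n <= kc + 2:
                scale_rows.append({"scale": scale, "feature": names[f],
                                   "r": np.nan, "n": n, "p": np.nan})
                continue
            r, p = partial_correlation(
                flat[mask, f], score[mask],
                cov.to_numpy()[mask] if kc else None,
            )
            scale_rows.append({"scale": scale, "feature": names[f],
                               "r": r, "n": n, "p": p})
        sub = pd.DataFrame(scale_rows)
        ok = np.isfinite(sub["p"].to_numpy())
        q = np.full(len(sub), np.nan)
        if ok.any():
            q[ok] = bh_fdr(sub["p"].to_numpy()[ok])
        sub["q"] = q
        rows.append(sub)
    if not rows:
        raise ValueError("no usable symptom scales")
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(["scale", "q", "p"], kind="stable").reset_index(drop=True)
    return AssociationReport(table=table, covariates=cov_names, excluded=excluded)
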