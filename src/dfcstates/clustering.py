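"""Connectivity-state clustering of pooled dFC windows.

Windows from all subjects (both groups) are pooled and partitioned into K
recurring connectivity states with k-means under the correlation distance
d(x, c) = 1 - Pearson(x, c).  Centroids are arithmetic means of member
windows (not renormalized), as is common practice in dynamic-connectivity
state analysis.  K is chosen by the elbow criterion on the ratio of
within-cluster to between-centroid distance, and state sets from different
datasets are matched by maximizing total centroid correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "StateModel",
    "StateSequence",
    "ClusterResult",
    "cluster_states",
    "select_k_elbow",
    "match_states",
    "state_summary",
    "fit_state_model",
]


@dataclass
class StateSequence:
    """Per-subject sequence of assigned state labels (1-based)."""

    subject_id: str
    states: np.ndarray  # int vector, values in 1..K


@dataclass
class ClusterResult:
    """One k-means fit on pooled windows."""

    n_states: int
    centroids: np.ndarray  # (K, P) arithmetic means of member windows
    labels: np.ndarray  # pooled window labels, 0-based
    inertia: float  # total within-cluster correlation distance
    n_iter: int


@dataclass
class StateModel:
    """Fitted state decomposition: centroids plus per-subject sequences."""

    n_states: int
    centroids: np.ndarray
    assignments: list[StateSequence]
    inertia: float
    inertia_curve: pd.DataFrame | None = None  # per-k elbow diagnostics
    selected_k: int | None = None
    knee_strength: float | None = None
    replicate_seed: int | None = None
    distance: str = "correlation"
    feature_index: list[tuple[str, str]] = field(default_factory=list, repr=False)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit L2 norm, so that
    1 - Pearson(a, b) = 1 - <a_std, b_std>."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError(
            "window(s) with zero variance across features are incompatible "
            "with the correlation distance; drop or jitter them first"
        )
    return xc / norms


def _kmeanspp_init(u: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under correlation distance; returns row indices."""
    n = u.shape[0]
    idx = np.empty(k, dtype=int)
    idx[0] = rng.integers(n)
    d2 = np.maximum(1.0 - u @ u[idx[0]], 0.0) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx[j] = rng.integers(n)
        else:
            idx[j] = rng.choice(n, p=d2 / total)
        d_new = np.maximum(1.0 - u @ u[idx[j]], 0.0) ** 2
        d2 = np.minimum(d2, d_new)
    return idx


def _lloyd(
    windows: np.ndarray,
    u: np.ndarray,
    k: int,
    max_iter: int,
    rng: np.random.Generator,
) -> ClusterResult:
    n = windows.shape[0]
    centroids = windows[_kmeanspp_init(u, k, rng)].copy()
    labels = np.full(n, -1, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        v = _standardize_rows(centroids)
        sim = u @ v.T  # Pearson(window, centroid)
        new_labels = np.argmax(sim, axis=1)
        # Re-seed empty clusters from the window farthest from its centroid.
        for j in range(k):
            if not np.any(new_labels == j):
                dist_assigned = 1.0 - sim[np.arange(n), new_labels]
                far = int(np.argmax(dist_assigned))
                centroids[j] = windows[far]
                v[j] = _standardize_rows(centroids[j : j + 1])[0]
                sim[:, j] = u @ v[j]
                new_labels = np.argmax(sim, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = windows[labels == j].mean(axis=0)
    v = _standardize_rows(centroids)
    sim = u @ v.T
    inertia = float(np.sum(1.0 - sim[np.arange(n), labels]))
    return ClusterResult(k, centroids, labels, inertia, n_iter)


def cluster_states(
    windows: np.ndarray,
    k: int,
    n_replicates: int = 50,
    max_iter: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Correlation-distance k-means on pooled windows, best of replicates.

    Lloyd iterations alternate nearest-centroid assignment under
    d(x, c) = 1 - Pearson(x, c) with arithmetic-mean centroid updates;
    convergence is declared when assignments stop changing.  Each replicate
    starts from k-means++-style seeding; the replicate with the lowest total
    within-cluster distance wins.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If any window has zero variance across features, or k < 1.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[0] < 1:
        raise ValueError("windows must be a non-empty 2-D array")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > windows.shape[0]:
        raise ValueError(f"k={k} exceeds the number of windows {windows.shape[0]}")
    u = _standardize_rows(windows)
    if k == 1:
        centroid = windows.mean(axis=0, keepdims=True)
        v = _standardize_rows(centroid)
        inertia = float(np.sum(1.0 - u @ v[0]))
        return ClusterResult(1, centroid, np.zeros(windows.shape[0], dtype=int), inertia, 0)
    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(n_replicates):
        res = _lloyd(windows, u, k, max_iter, rng)
        if best is None or res.inertia < best.inertia:
            best = res
    assert best is not None
    return best


def _within_between_ratio(windows: np.ndarray, res: ClusterResult) -> float:
    """Mean within-cluster distance over mean between-centroid distance."""
    u = _standardize_rows(windows)
    v = _standardize_rows(res.centroids)
    n = windows.shape[0]
    within = float(np.mean(1.0 - (u @ v.T)[np.arange(n), res.labels]))
    k = res.n_states
    if k < 2:
        return np.inf
    sim = v @ v.T
    iu, ju = np.triu_indices(k, k=1)
    between = float(np.mean(1.0 - sim[iu, ju]))
    return within / between


def select_k_elbow(
    windows: np.ndarray,
    k_range: range | list[int] = range(2, 11),
    n_replicates: int = 10,
    max_iter: int = 1000,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of states by the elbow criterion.

    For each candidate k the ratio R(k) = (mean within-cluster distance) /
    (mean between-centroid distance) is computed.  The knee is the interior
    k lying furthest below the chord joining the curve's endpoints (the
    point of maximal bend), ties resolved toward the smallest k; this
    detector is robust to the gradual, uneven per-k drops that make the
    discrete second difference fire one k early.  With fewer than three
    candidates there is no interior: the k with the smallest ratio is
    returned with a warning.

    Returns
    -------
    (selected_k, curve) where ``curve`` has columns ``k``, ``ratio``,
    ``inertia``, ``chord_dist`` (distance below the endpoint chord) and
    carries the knee strength (max chord distance normalized by the ratio
    range, clipped at 0) in ``curve.attrs["knee_strength"]``; a weak knee
    (< 0.1) indicates little cluster structure, e.g. a concave or flat
    ratio curve on structureless data.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    rng = np.random.default_rng(seed)
    ratios, inertias = [], []
    for k in ks:
        res = cluster_states(
            windows, k, n_replicates=n_replicates, max_iter=max_iter,
            seed=int(rng.integers(2**31 - 1)),
        )
        ratios.append(_within_between_ratio(windows, res))
        inertias.append(res.inertia)
    ratios_arr = np.asarray(ratios)
    ks_arr = np.asarray(ks, dtype=float)
    knee = np.full(len(ks), np.nan)
    if len(ks) >= 3:
        slope = (ratios_arr[-1] - ratios_arr[0]) / (ks_arr[-1] - ks_arr[0])
        chord = ratios_arr[0] + slope * (ks_arr - ks_arr[0])
        knee = chord - ratios_arr  # positive where the curve dips below
        best_i = 1 + int(np.argmax(knee[1:-1]))
        selected = ks[best_i]
        span = float(ratios_arr.max() - ratios_arr.min())
        strength = float(max(knee[best_i], 0.0) / span) if span > 0 else 0.0
    else:
        warnings.warn(
            "k_range has fewer than 3 candidates; no interior knee exists -- "
            "returning the k with the smallest within/between ratio",
            stacklevel=2,
        )
        best_i = int(np.argmin(ratios_arr))
        selected = ks[best_i]
        strength = 0.0
    curve = pd.DataFrame({"k": ks, "ratio": ratios, "inertia": inertias,
                          "chord_dist": knee})
    curve.attrs["knee_strength"] = strength
    curve.attrs["selected_k"] = selected
    return selected, curve


def match_states(
    centroids_a: np.ndarray, centroids_b: np.ndarray
) -> tuple[dict[int, int], np.ndarray]:
    """Match two centroid sets by maximal total Pearson correlation.

    Returns the optimal one-to-one assignment (0-based row of A -> row of B,
    Hungarian algorithm) and the full K_a x K_b correlation matrix so weak
    matches remain visible.  With unequal K the best partial matching is
    returned and the extra states are left unmatched.
    """
    a = np.asarray(centroids_a, dtype=float)
    b = np.asarray(centroids_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("centroid sets must be 2-D with equal feature counts")
    ua = _standardize_rows(a)
    ub = _standardize_rows(b)
    sim = ua @ ub.T
    rows, cols = linear_sum_assignment(-sim)
    return {int(i): int(j) for i, j in zip(rows, cols)}, sim


def state_summary(
    centroids: np.ndarray,
    feature_index: list[tuple[str, str]],
    node_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-state mean centroid connectivity within and between node groups.

    For each state the centroid features are averaged within each group
    block (both nodes in the group) and between each pair of groups, e.g.
    within-PCu / within-ACC / within-PCC and PCu/ACC, PCu/PCC, ACC/PCC.

    Raises
    ------
    KeyError
        If a node in ``feature_index`` is absent from ``node_groups``.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    node_to_group: dict[str, str] = {}
    for g, nodes in node_groups.items():
        for n in nodes:
            node_to_group[n] = g
    groups = list(node_groups)
    # within-group blocks first, then between-group pairs (table convention)
    blocks: list[tuple[str, str]] = [(g, g) for g in groups]
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            blocks.append((g1, g2))
    block_cols: dict[tuple[str, str], list[int]] = {b: [] for b in blocks}
    for col, (ni, nj) in enumerate(feature_index):
        for n in (ni, nj):
            if n not in node_to_group:
                raise KeyError(f"node {n!r} missing from the node-group map")
        gi, gj = node_to_group[ni], node_to_group[nj]
        key = (gi, gj) if (gi, gj) in block_cols else (gj, gi)
        block_cols[key].append(col)
    data = {}
    for (g1, g2), cols in block_cols.items():
        name = g1 if g1 == g2 else f"{g1}/{g2}"
        data[name] = centroids[:, cols].mean(axis=1) if cols else np.full(len(centroids), np.nan)
    return pd.DataFrame(data, index=[f"state {i + 1}" for i in range(len(centroids))])


def fit_state_model(
    dfc_list: list,
    k: int | None = None,
    k_range: range | list[int] = range(2, 11),
    n_replicates: int = 50,
    max_iter: int = 1000,
    seed: int | None = None,
) -> StateModel:
    """Pool windows from all subjects, optionally select K, and cluster.

    ``dfc_list`` is a list of :class:`~dfcstates.windows.DFCSeries`.  With
    ``k=None`` the elbow criterion picks K over ``k_range`` first (with a
    lighter replicate count), then the final model is fit at that K with the
    full ``n_replicates``.
    """
    if not dfc_list:
        raise ValueError("need at least one subject")
    pooled = np.vstack([d.features for d in dfc_list])
    rng = np.random.default_rng(seed)
    curve = None
    strength = None
    if k is None:
        k, curve = select_k_elbow(
            pooled, k_range, n_replicates=max(2, n_replicates // 5),
            max_iter=max_iter, seed=int(rng.integers(2**31 - 1)),
        )
        strength = curve.attrs["knee_strength"]
    fit_seed = int(rng.integers(2**31 - 1))
    res = cluster_states(pooled, k, n_replicates=n_replicates,
                         max_iter=max_iter, seed=fit_seed)
    assignments = []
    start = 0
    for d in dfc_list:
        stop = start + d.n_windows
        assignments.append(
            StateSequence(d.subject_id, res.labels[start:stop] + 1)
        )
        start = stop
    return StateModel(
        n_states=k,
        centroids=res.centroids,
        assignments=assignments,
        inertia=res.inertia,
        inertia_curve=curve,
        selected_k=k,
        knee_strength=strength,
        replicate_seed=fit_seed,
        feature_index=list(dfc_list[0].feature_index),
    )
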