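"""Markov transition-probability features from state sequences.

Each subject's window-level state sequence is summarized by the empirical
first-order transition matrix P[j, i] = Pr(next state = i | current = j),
the maximum-likelihood estimate given the observed sequence.  Flattened
row-major, a K-state model yields K^2 named features ("P(j->i)", 1-based);
K = 5 gives the 25 transition features used downstream.  Occupancy and mean
dwell time are provided as auxiliary summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "flatten_features",
    "unflatten_features",
    "feature_names",
    "occupancy_and_dwell",
]


@dataclass
class TransitionMatrix:
    """Empirical transition probabilities for one subject.

    ``matrix[j, i]`` (0-based) is the estimated probability of moving to
    state ``i + 1`` at time t+1 given state ``j + 1`` at time t.  Rows of
    states never occupied before the final time point are all-zero and
    flagged in ``unvisited_mask``; visited rows sum to 1.
    """

    subject_id: str
    matrix: np.ndarray  # (K, K), indexed [from, to]
    visit_counts: np.ndarray  # (K,) number of times each state had a successor
    unvisited_mask: np.ndarray  # (K,) True where visit_counts == 0


def transition_matrix(seq, k: int, subject_id: str = "") -> TransitionMatrix:
    """Empirical ML transition matrix of a 1-based state sequence.

    ``matrix[j, i] = #{t : s(t) = j+1, s(t+1) = i+1} / #{t < T : s(t) = j+1}``.

    Raises
    ------
    ValueError
        If the sequence is shorter than 2 or contains labels outside 1..k.
    """
    states = getattr(seq, "states", seq)
    s = np.asarray(states, dtype=int)
    if s.ndim != 1 or s.shape[0] < 2:
        raise ValueError("state sequence must be 1-D with length >= 2")
    if s.min() < 1 or s.max() > k:
        raise ValueError(f"state labels must lie in 1..{k}")
    counts = np.zeros((k, k), dtype=float)
    np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1.0)
    visits = counts.sum(axis=1)
    mat = np.zeros_like(counts)
    visited = visits > 0
    mat[visited] = counts[visited] / visits[visited, None]
    sid = subject_id or str(getattr(seq, "subject_id", ""))
    return TransitionMatrix(sid, mat, visits, ~visited)


def feature_names(k: int) -> list[str]:
    """Row-major transition feature names, 1-based: P(1->1), P(1->2), ..."""
    return [f"P({j + 1}->{i + 1})" for j in range(k) for i in range(k)]


def flatten_features(tm: TransitionMatrix) -> tuple[np.ndarray, list[str]]:
    """Row-major [from, to] flattening of the transition matrix: K^2 values
    with names "P(j->i)".  K = 5 yields 25 features."""
    k = tm.matrix.shape[0]
    return tm.matrix.reshape(-1).copy(), feature_names(k)


def unflatten_features(
    vec: np.ndarray, subject_id: str = ""
) -> TransitionMatrix:
    """Inverse of :func:`flatten_features` (visit counts are not recoverable
    from probabilities; rows summing to 0 are flagged unvisited)."""
    vec = np.asarray(vec, dtype=float)
    k = int(round(np.sqrt(vec.shape[0])))
    if k * k != vec.shape[0]:
        raise ValueError(f"vector length {vec.shape[0]} is not a perfect square")
    mat = vec.reshape(k, k).copy()
    visited = mat.sum(axis=1) > 0
    return TransitionMatrix(subject_id, mat, visited.astype(float), ~visited)


def occupancy_and_dwell(seq, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Fractional occupancy and mean dwell time (in windows) per state.

    Occupancy sums to 1.  Mean dwell is the average length of consecutive
    runs in each state; never-visited states get dwell 0.
    """
    states = getattr(seq, "states", seq)
    s = np.asarray(states, dtype=int)
    if s.ndim != 1 or s.shape[0] < 1:
        raise ValueError("state sequence must be 1-D with length >= 1")
    if s.min() < 1 or s.max() > k:
        raise ValueError(f"state labels must lie in 1..{k}")
    occupancy = np.bincount(s - 1, minlength=k) / s.shape[0]
    # Run-length encoding: run starts where the label changes.
    change = np.flatnonzero(np.diff(s) != 0)
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [s.shape[0]])))
    run_states = s[starts] - 1
    dwell = np.zeros(k)
    n_runs = np.bincount(run_states, minlength=k)
    np.add.at(dwell, run_states, lengths.astype(float))
    visited = n_runs > 0
    dwell[visited] /= n_runs[visited]
    return occupancy, dwell
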