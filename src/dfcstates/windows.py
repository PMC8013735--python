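"""Tapered sliding-window dynamic functional connectivity.

A subject's node time courses (time x nodes) are scanned with a tapered
window -- a rectangle smoothed by a Gaussian kernel -- and the weighted
covariance (or correlation) of the z-scored signals is computed inside each
window.  Each windowed connectivity matrix is vectorized to its strict upper
triangle, giving C(C-1)/2 pairwise features per window (21 features for
C = 7 nodes).

Window-count convention
-----------------------
A nominal window of ``L`` TRs (e.g. 20 TRs = 40 s at TR = 2 s) covers
``L + 1`` consecutive samples inclusive, and windows advance by one sample,
so an ``N``-timepoint series yields exactly ``T = N - L`` windows
(144 -> 124, 157 -> 137).  This inclusive-support reading is also the only
one under which the taper weight vector is exactly symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TaperSpec",
    "DFCSeries",
    "build_taper",
    "sliding_dfc",
    "vectorize_fc",
    "devectorize_fc",
    "pair_index",
]


@dataclass(frozen=True)
class TaperSpec:
    """Tapered window weights: a rectangle convolved with a Gaussian.

    Attributes
    ----------
    window_trs : int
        Nominal window length ``L`` in TRs; the support is ``L + 1`` samples.
    sigma_seconds : float
        Standard deviation of the Gaussian smoothing kernel, in seconds.
    tr_seconds : float
        Sampling interval (repetition time), in seconds.
    weights : ndarray, shape (L + 1,)
        Nonnegative, symmetric, unit-sum window weights.
    """

    window_trs: int
    sigma_seconds: float
    tr_seconds: float
    weights: np.ndarray

    @property
    def support(self) -> int:
        return self.window_trs + 1


@dataclass
class DFCSeries:
    """Windowed connectivity features for one subject.

    ``features`` has one row per window start (T = n_timepoints - L rows)
    and one column per node pair, ordered by the strict upper triangle of
    the connectivity matrix taken row-wise (i < j, nodes in input column
    order).  ``feature_index`` maps each column to its (node_i, node_j)
    label pair.
    """

    subject_id: str
    features: np.ndarray
    feature_index: list[tuple[str, str]] = field(repr=False)

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def build_taper(
    window_trs: int = 20,
    sigma_seconds: float = 3.0,
    tr_seconds: float = 2.0,
) -> TaperSpec:
    """Construct the tapered window weights.

    A unit rectangle spanning the window's ``L + 1``-sample support is
    convolved with a unit-mass discrete Gaussian of standard deviation
    ``sigma_seconds / tr_seconds`` samples (kernel truncated at +-4 sigma,
    where truncation error is below 1e-4 of the mass).  The full convolution
    is cropped to its central ``L + 1`` samples and renormalized to unit sum.

    Raises
    ------
    ValueError
        If ``window_trs < 2`` or a duration is not positive.
    """
    if window_trs < 2:
        raise ValueError(f"window_trs must be >= 2, got {window_trs}")
    if sigma_seconds <= 0:
        raise ValueError(f"sigma_seconds must be positive, got {sigma_seconds}")
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")

    support = window_trs + 1
    sigma_samples = sigma_seconds / tr_seconds
    half = max(1, int(np.ceil(4.0 * sigma_samples)))
    offsets = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (offsets / sigma_samples) ** 2)
    kernel /= kernel.sum()

    rect = np.ones(support)
    full = np.convolve(rect, kernel, mode="full")  # length support + 2*half
    start = half
    w = full[start : start + support].copy()
    # Enforce the exact symmetry the construction implies (guards against
    # summation-order rounding in np.convolve).
    w = 0.5 * (w + w[::-1])
    w /= w.sum()
    return TaperSpec(window_trs, sigma_seconds, tr_seconds, weights=w)


def pair_index(node_labels: list[str]) -> list[tuple[str, str]]:
    """Ordered (node_i, node_j) pairs for the strict upper triangle."""
    c = len(node_labels)
    iu, ju = np.triu_indices(c, k=1)
    return [(node_labels[i], node_labels[j]) for i, j in zip(iu, ju)]


def vectorize_fc(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-wise order."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju].copy()


def devectorize_fc(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`; the diagonal is set to 0."""
    vec = np.asarray(vec)
    p = vec.shape[0]
    c = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if c * (c - 1) // 2 != p:
        raise ValueError(f"vector length {p} is not a triangular number")
    out = np.zeros((c, c), dtype=vec.dtype)
    iu, ju = np.triu_indices(c, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def sliding_dfc(
    signal: np.ndarray,
    taper: TaperSpec,
    step: int = 1,
    *,
    stat: str = "covariance",
    standardize: bool = True,
    subject_id: str = "",
    node_labels: list[str] | None = None,
) -> DFCSeries:
    """Tapered sliding-window connectivity of one subject's signals.

    The signal is z-scored per node over the whole series (so feature
    scales are comparable across subjects), then for each window start the
    taper-weighted covariance over the window's ``L + 1``-sample support is
    computed (weighted mean removed, normalized by the weight sum) and its
    strict upper triangle vectorized.  ``stat="correlation"`` rescales each
    windowed covariance to a correlation; ``standardize=False`` skips the
    whole-series z-scoring and computes the statistic on the raw signal.

    Parameters
    ----------
    signal : ndarray, shape (n_timepoints, n_nodes)
    taper : TaperSpec
    step : int
        Window-start increment in samples (default 1, giving T = N - L).

    Raises
    ------
    ValueError
        If the series is shorter than the taper support or contains
        non-finite values.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError("signal must be a 2-D (time x node) array")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    n, c = signal.shape
    support = taper.support
    if n < support:
        raise ValueError(
            f"signal has {n} timepoints but the taper needs at least {support}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    if stat not in ("covariance", "correlation"):
        raise ValueError(f"unknown window statistic {stat!r}")

    if standardize:
        mu = signal.mean(axis=0)
        sd = signal.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        z = (signal - mu) / sd_safe
        z[:, sd == 0] = 0.0
    else:
        z = signal

    w = taper.weights
    # (T_full, c, support) view of all windows, then subsample by step.
    segs = sliding_window_view(z, support, axis=0)[::step]
    wmean = np.einsum("l,tcl->tc", w, segs)
    centered = segs - wmean[:, :, None]
    cov = np.einsum("l,til,tjl->tij", w, centered, centered)

    if stat == "correlation":
        d = np.sqrt(np.einsum("tii->ti", cov))
        d_safe = np.where(d > 0, d, 1.0)
        cov = cov / (d_safe[:, :, None] * d_safe[:, None, :])
        zero = d == 0
        if zero.any():
            mask = zero[:, :, None] | zero[:, None, :]
            cov[mask] = 0.0

    iu, ju = np.triu_indices(c, k=1)
    feats = cov[:, iu, ju]
    labels = node_labels if node_labels is not None else [f"n{i + 1}" for i in range(c)]
    return DFCSeries(
        subject_id=subject_id,
        features=np.ascontiguousarray(feats),
        feature_index=pair_index(list(labels)),
    )
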