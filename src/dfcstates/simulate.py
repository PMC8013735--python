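"""Synthetic cohort generator: hidden-Markov covariance-switching signals.

Stands in for resting-state fMRI subnode time courses.  Each subject
carries a hidden first-order Markov chain over K connectivity states
(uniform initial distribution, group-specific transition matrix); at every
time point the C-node signal vector is drawn from a zero-mean Gaussian
with the active state's covariance.  The model is the simplest one under
which the tapered-window covariance + k-means state pipeline is consistent,
so every downstream stage can be validated by parameter recovery.

Plantable effects:

* group contrasts in chosen covariance cells (the default preset raises
  precuneus/posterior-cingulate coupling and lowers anterior-cingulate
  coupling in the clinical group, in specific states);
* a symptom score for clinical subjects built as an affine function of the
  subject's realized transition probability for one chosen state pair
  (default 2 -> 4) plus Gaussian noise, calibrated so the score-feature
  correlation hits a target r in expectation;
* an optional fraction of clinical subjects with missing symptom scores.

Ground truth (hidden sequences, configured matrices, symptom latents) is
embedded in the returned cohort so tests can score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .transitions import transition_matrix

__all__ = [
    "SymptomLink",
    "CovariateModel",
    "CohortConfig",
    "Subject",
    "GroundTruth",
    "TimeCourseSet",
    "generate_cohort",
    "cobre_like_config",
    "default_state_covariances",
    "default_transition_matrices",
    "planted_window_labels",
    "DEFAULT_NODE_LABELS",
    "DEFAULT_NODE_GROUPS",
]

# Node order of the default 7-subnode default-mode-network parcellation:
# three precuneus, two anterior-cingulate and two posterior-cingulate
# subnodes, interleaved in acquisition-template order.
DEFAULT_NODE_LABELS = ["PCu1", "PCu2", "ACC1", "PCC1", "ACC2", "PCu3", "PCC2"]
DEFAULT_NODE_GROUPS = {
    "PCu": ["PCu1", "PCu2", "PCu3"],
    "ACC": ["ACC1", "ACC2"],
    "PCC": ["PCC1", "PCC2"],
}

# Per-state block connectivity values (within-PCu, within-ACC, within-PCC,
# PCu/ACC, PCu/PCC, ACC/PCC), unit diagonal.  Chosen so all five matrices
# are positive definite (min eigenvalue > 0.14) and the vectorized
# centroids are well separated: max pairwise Pearson correlation 0.24,
# making state-count and state-label recovery tests meaningful.
_STATE_BLOCKS = np.array([
    [-0.394, -0.430,  0.442,  0.014,  0.062, -0.217],  # state 1
    [ 0.440,  0.327,  0.420,  0.363, -0.449, -0.416],  # state 2
    [-0.329,  0.415, -0.372, -0.007, -0.047, -0.360],  # state 3
    [ 0.410, -0.447,  0.022,  0.200,  0.222, -0.089],  # state 4
    [ 0.263,  0.400,  0.426, -0.429,  0.364, -0.344],  # state 5
])

# Clinical-group contrast: higher PCu/PCC coupling in states 1 and 4 and
# lower within-ACC coupling in states 1, 2 and 4 (block index -> delta).
_SZ_BLOCK_DELTAS: dict[int, dict[int, float]] = {
    0: {4: +0.10, 1: -0.10},
    1: {1: -0.10},
    3: {4: +0.10, 1: -0.10},
}




@dataclass(frozen=True)
class SymptomLink:
    """Planted coupling between one transition probability and a score.

    The clinical score is a * P_true(from -> to) + noise, with the gain a
    calibrated against ``noise_sd`` and the cohort's spread of realized
    transition probabilities so the correlation equals ``target_r`` in
    expectation.  States are 1-based.

    The latent P_true is the subject's realized transition probability of
    the hidden chain (TR resolution).  ``window_trs`` and ``sigma_seconds``
    set the window geometry of the majority-state window sequences stored
    in the ground truth for diagnostics; note that at window resolution the
    same transition cell retains only about half of the TR-level
    between-subject signal (windowing absorbs short state runs), so
    end-to-end recovery of the planted r through the full pipeline is
    intrinsically attenuated at realistic scan lengths.
    """

    from_state: int = 2
    to_state: int = 4
    target_r: float = 0.40
    noise_sd: float = 1.0
    scale: str = "panss_total"
    window_trs: int = 20
    sigma_seconds: float = 3.0


@dataclass(frozen=True)
class CovariateModel:
    """Distributions for subject covariates, independent of symptoms."""

    age_mean: float = 38.0
    age_sd: float = 12.0
    age_min: float = 18.0
    age_max: float = 65.0
    p_male: float = 0.75
    sites: tuple[str, ...] = ("site1",)
    # Optional planted site confound: per-site additive shift applied to
    # symptom scores, used to exercise covariate adjustment.
    site_score_shift: tuple[float, ...] | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``state_covariances`` and ``transition_matrices`` map group label
    ("HC"/"SZ") to, respectively, a list of K node x node positive
    semidefinite matrices and a K x K row-stochastic matrix.
    """

    n_hc: int
    n_sz: int
    n_nodes: int = 7
    n_states: int = 5
    n_timepoints: int = 144
    tr_seconds: float = 2.0
    node_labels: tuple[str, ...] = tuple(DEFAULT_NODE_LABELS)
    state_covariances: dict[str, list[np.ndarray]] = field(default_factory=dict)
    transition_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    symptom_link: SymptomLink | None = None
    symptom_scales: tuple[str, ...] = ("panss_positive", "panss_negative", "panss_total")
    missing_symptom_fraction: float = 0.06
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int | None = None

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass
class Subject:
    id: str
    group: str  # "HC" | "SZ"
    signal: np.ndarray  # (n_timepoints, n_nodes)
    covariates: dict[str, object]
    symptoms: dict[str, float]  # NaN = missing


@dataclass
class GroundTruth:
    """Generator-side latent quantities, retained for recovery scoring."""

    state_sequences: dict[str, np.ndarray]  # 1-based hidden chains (TR level)
    transition_matrices: dict[str, np.ndarray]  # configured, per group
    empirical_transitions: dict[str, np.ndarray]  # realized per subject, TR level
    # majority hidden state per sliding window (populated when a symptom
    # link defines the window geometry)
    window_state_sequences: dict[str, np.ndarray] = field(default_factory=dict)
    symptom_latents: dict[str, float] = field(default_factory=dict)
    config: CohortConfig | None = None


@dataclass
class TimeCourseSet:
    """Cohort of per-subject node time courses with labels and metadata."""

    subjects: list[Subject]
    node_labels: list[str]
    tr_seconds: float
    ground_truth: GroundTruth | None = None

    def __len__(self) -> int:
        return len(self.subjects)

    def labels(self) -> dict[str, str]:
        return {s.id: s.group for s in self.subjects}

    def symptoms_frame(self, group: str | None = "SZ") -> pd.DataFrame:
        subs = [s for s in self.subjects if group is None or s.group == group]
        return pd.DataFrame([s.symptoms for s in subs],
                            index=[s.id for s in subs])

    def covariates_frame(self, group: str | None = None) -> pd.DataFrame:
        subs = [s for s in self.subjects if group is None or s.group == group]
        return pd.DataFrame([s.covariates for s in subs],
                            index=[s.id for s in subs])


def _cov_from_blocks(blocks: np.ndarray, node_labels: list[str]) -> np.ndarray:
    groups = {g: [node_labels.index(n) for n in nodes]
              for g, nodes in DEFAULT_NODE_GROUPS.items()}
    r = np.eye(len(node_labels))

    def setb(idx1, idx2, v):
        for i in idx1:
            for j in idx2:
                if i != j:
                    r[i, j] = r[j, i] = v

    pcu, acc, pcc = groups["PCu"], groups["ACC"], groups["PCC"]
    setb(pcu, pcu, blocks[0])
    setb(acc, acc, blocks[1])
    setb(pcc, pcc, blocks[2])
    setb(pcu, acc, blocks[3])
    setb(pcu, pcc, blocks[4])
    setb(acc, pcc, blocks[5])
    return r


def default_state_covariances(
    group_contrast: bool = True,
) -> dict[str, list[np.ndarray]]:
    """The frozen well-separated 5-state covariance preset.

    ``group_contrast=False`` returns identical matrices for both groups
    (a null cohort for type-I-error checks).
    """
    labels = DEFAULT_NODE_LABELS
    hc = [_cov_from_blocks(b, labels) for b in _STATE_BLOCKS]
    if not group_contrast:
        return {"HC": hc, "SZ": [c.copy() for c in hc]}
    sz = []
    for si, b in enumerate(_STATE_BLOCKS):
        b = b.copy()
        for bi, delta in _SZ_BLOCK_DELTAS.get(si, {}).items():
            b[bi] += delta
        sz.append(_cov_from_blocks(b, labels))
    return {"HC": hc, "SZ": sz}


def default_transition_matrices(
    k: int = 5,
    p_stay: float = 0.95,
    sz_link_boost: float = 0.025,
    link: tuple[int, int] = (2, 4),
) -> dict[str, np.ndarray]:
    """Row-stochastic chains with quasi-stable states.

    Both groups share a uniform-off-diagonal matrix with self-transition
    probability ``p_stay`` (mean dwell 1/(1-p_stay) TRs; the default 0.95
    gives ~40 s dwell at TR = 2 s, in line with reported connectivity-state
    dwell times).  The clinical matrix additionally moves ``sz_link_boost``
    of the linked row's self-transition mass onto the linked transition
    (default 2 -> 4), the planted dynamical group effect.
    """
    off = (1.0 - p_stay) / (k - 1)
    base = np.full((k, k), off)
    np.fill_diagonal(base, p_stay)
    sz = base.copy()
    j, i = link[0] - 1, link[1] - 1
    sz[j, i] += sz_link_boost
    sz[j, j] -= sz_link_boost
    return {"HC": base, "SZ": sz}


def cobre_like_config(
    n_hc: int = 89,
    n_sz: int = 68,
    seed: int | None = 0,
    group_contrast: bool = True,
    symptom_link: SymptomLink | None = SymptomLink(),
) -> CohortConfig:
    """Frozen default preset mirroring the public eyes-open dataset design.

    89 controls vs 68 clinical subjects; 7 default-mode subnodes; 144
    retained time points (149 acquired volumes minus 5 discarded dummy
    scans) at TR = 2 s; five well-separated connectivity states; clinical
    contrasts in PCu/PCC and ACC coupling; a 2 -> 4 transition/symptom link
    at target r = 0.40; ~6% of clinical subjects missing symptom scores.
    """
    return CohortConfig(
        n_hc=n_hc,
        n_sz=n_sz,
        state_covariances=default_state_covariances(group_contrast),
        transition_matrices=default_transition_matrices(
            sz_link_boost=0.025 if group_contrast else 0.0
        ),
        symptom_link=symptom_link,
        seed=seed,
    )


def _validate(config: CohortConfig) -> None:
    k, c = config.n_states, config.n_nodes
    if config.n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if len(config.node_labels) != c:
        raise ValueError("node_labels length must equal n_nodes")
    for group in ("HC", "SZ"):
        covs = config.state_covariances.get(group)
        if covs is None or len(covs) != k:
            raise ValueError(f"state_covariances[{group!r}] must list {k} matrices")
        for si, cov in enumerate(covs):
            cov = np.asarray(cov)
            if cov.shape != (c, c):
                raise ValueError(
                    f"{group} state {si + 1} covariance has shape {cov.shape}, "
                    f"expected ({c}, {c})"
                )
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"{group} state {si + 1} covariance is not symmetric")
            ev = np.linalg.eigvalsh(cov).min()
            if ev < -1e-8:
                raise ValueError(
                    f"{group} state {si + 1} covariance is not positive "
                    f"semidefinite (min eigenvalue {ev:.3g})"
                )
        tm = np.asarray(config.transition_matrices.get(group))
        if tm.shape != (k, k):
            raise ValueError(f"transition_matrices[{group!r}] must be {k}x{k}")
        if np.any(tm < 0) or np.max(np.abs(tm.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError(
                f"transition_matrices[{group!r}] rows must be nonnegative and "
                "sum to 1 within 1e-12"
            )
    link = config.symptom_link
    if link is not None:
        if not -1.0 < link.target_r < 1.0:
            raise ValueError(f"target_r must lie in (-1, 1), got {link.target_r}")
        if link.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (1 <= link.from_state <= k and 1 <= link.to_state <= k):
            raise ValueError("symptom link states must lie in 1..K")
        if config.n_timepoints < link.window_trs + 2:
            raise ValueError(
                "n_timepoints must exceed the symptom link's window length "
                f"({link.window_trs} TRs) by at least 2"
            )
    if not 0.0 <= config.missing_symptom_fraction < 1.0:
        raise ValueError("missing_symptom_fraction must lie in [0, 1)")


def _sample_chain(tm: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """1-based Markov chain of length n, uniform initial distribution."""
    k = tm.shape[0]
    cum = np.cumsum(tm, axis=1)
    seq = np.empty(n, dtype=int)
    seq[0] = rng.integers(k)
    u = rng.random(n - 1)
    for t in range(1, n):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t - 1], side="right")
    return seq + 1


def generate_cohort(config: CohortConfig) -> TimeCourseSet:
    """Draw a cohort from the hidden-Markov covariance-switching model.

    Fully reproducible from ``config.seed``.  For each subject a hidden
    state sequence is drawn from the group's chain (uniform initial state)
    and each time point's node vector from a zero-mean Gaussian with the
    active state's covariance.  Clinical symptom scores are generated so
    the configured transition probability correlates with the linked scale
    at the target r in expectation; unlinked scales are independent noise
    on a PANSS-like scale (mean 15, SD 5).  Ground truth is embedded.

    Raises
    ------
    ValueError
        For non-PSD covariances (naming the offending group/state),
        non-stochastic transition rows, or an infeasible symptom link.
    """
    _validate(config)
    rng = np.random.default_rng(config.seed)
    k, c, n = config.n_states, config.n_nodes, config.n_timepoints
    chol = {
        g: [np.linalg.cholesky(
            np.asarray(cov) + 1e-12 * np.eye(c)) for cov in covs]
        for g, covs in config.state_covariances.items()
    }
    cm = config.covariate_model

    subjects: list[Subject] = []
    seqs: dict[str, np.ndarray] = {}
    emp: dict[str, np.ndarray] = {}
    plan = [("HC", i) for i in range(config.n_hc)] + [
        ("SZ", i) for i in range(config.n_sz)]
    for group, i in plan:
        sid = f"{group.lower()}{i + 1:03d}"
        tm = np.asarray(config.transition_matrices[group])
        seq = _sample_chain(tm, n, rng)
        eps = rng.standard_normal((n, c))
        signal = np.empty((n, c))
        for st in range(1, k + 1):
            mask = seq == st
            if mask.any():
                signal[mask] = eps[mask] @ chol[group][st - 1].T
        age = float(np.clip(rng.normal(cm.age_mean, cm.age_sd), cm.age_min, cm.age_max))
        gender = "M" if rng.random() < cm.p_male else "F"
        site = cm.sites[rng.integers(len(cm.sites))]
        subjects.append(Subject(
            id=sid, group=group, signal=signal,
            covariates={"age": round(age, 1), "gender": gender, "site": site},
            symptoms={s: float("nan") for s in config.symptom_scales},
        ))
        seqs[sid] = seq
        emp[sid] = transition_matrix(seq, k, subject_id=sid).matrix

    # --- clinical symptom scores -----------------------------------------
    latents: dict[str, float] = {}
    window_seqs: dict[str, np.ndarray] = {}
    sz_subjects = [s for s in subjects if s.group == "SZ"]
    link = config.symptom_link
    if link is not None:
        from .windows import build_taper
        w = build_taper(link.window_trs, link.sigma_seconds,
                        config.tr_seconds).weights
        for s in subjects:
            window_seqs[s.id] = planted_window_labels(seqs[s.id], w,
                                                      dominance=0.0)
    if link is not None and sz_subjects:
        j, i = link.from_state - 1, link.to_state - 1
        lat = np.array([
            emp[s.id][j, i] if emp[s.id][j].sum() > 0 else np.nan
            for s in sz_subjects
        ])
        finite = np.isfinite(lat)
        s_p = float(np.nanstd(lat))
        if finite.sum() >= 2 and s_p > 0:
            gain = link.noise_sd * link.target_r / (
                s_p * np.sqrt(1.0 - link.target_r**2))
        elif abs(link.target_r) > 0:
            raise ValueError(
                "symptom link target_r is infeasible: the realized "
                f"P({link.from_state}->{link.to_state}) has no spread "
                "across clinical subjects"
            )
        else:
            gain = 0.0
        lat_filled = np.where(finite, lat, np.nanmean(lat))
        u = gain * lat_filled + rng.normal(0.0, link.noise_sd, len(sz_subjects))
        u_sd = u.std() if u.std() > 0 else 1.0
        linked_scores = 15.0 + 5.0 * (u - u.mean()) / u_sd
        for s, latv in zip(sz_subjects, lat):
            latents[s.id] = float(latv)
    else:
        linked_scores = None

    site_index = {name: idx for idx, name in enumerate(cm.sites)}
    for si, s in enumerate(sz_subjects):
        for scale in config.symptom_scales:
            if linked_scores is not None and scale == link.scale:
                val = float(linked_scores[si])
            else:
                val = float(rng.normal(15.0, 5.0))
            if cm.site_score_shift is not None:
                val += cm.site_score_shift[site_index[s.covariates["site"]]]
            s.symptoms[scale] = val
    if config.missing_symptom_fraction > 0 and sz_subjects:
        n_missing = int(round(config.missing_symptom_fraction * len(sz_subjects)))
        miss = rng.choice(len(sz_subjects), size=n_missing, replace=False)
        for mi in miss:
            for scale in config.symptom_scales:
                sz_subjects[mi].symptoms[scale] = float("nan")

    gt = GroundTruth(
        state_sequences=seqs,
        transition_matrices={g: np.asarray(m) for g, m in
                             config.transition_matrices.items()},
        empirical_transitions=emp,
        window_state_sequences=window_seqs,
        symptom_latents=latents,
        config=config,
    )
    return TimeCourseSet(
        subjects=subjects,
        node_labels=list(config.node_labels),
        tr_seconds=config.tr_seconds,
        ground_truth=gt,
    )


def planted_window_labels(
    seq: np.ndarray, taper_weights: np.ndarray, dominance: float = 0.8
) -> np.ndarray:
    """Ground-truth state label per sliding window of a hidden chain.

    A window's planted label is the hidden state carrying the largest share
    of the taper weight over the window's support, provided that share is
    at least ``dominance`` (default 0.8); windows straddling a state change
    without a dominant state have no well-defined planted identity and get
    label 0.  Returns a 1-based label vector of length
    ``len(seq) - len(taper_weights) + 1``.
    """
    seq = np.asarray(seq, dtype=int)
    w = np.asarray(taper_weights, dtype=float)
    support = w.shape[0]
    t_windows = seq.shape[0] - support + 1
    if t_windows < 1:
        raise ValueError("sequence shorter than the taper support")
    k = int(seq.max())
    onehot = np.zeros((seq.shape[0], k))
    onehot[np.arange(seq.shape[0]), seq - 1] = 1.0
    segs = np.lib.stride_tricks.sliding_window_view(onehot, support, axis=0)
    votes = np.einsum("l,tkl->tk", w, segs)  # taper-weighted share per state
    out = np.argmax(votes, axis=1) + 1
    out[votes.max(axis=1) < dominance * w.sum()] = 0
    return out
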