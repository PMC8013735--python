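"""Cohort manifest and matrix I/O plus run configuration.

A cohort on disk is a JSON manifest listing subjects (id, group, TR,
covariates, symptom scores, relative path to the time-course file) next to
one tab-delimited time-course matrix per subject (header row of node
labels, one row per time point).  Synthetic cohorts additionally write a
ground-truth JSON sidecar with the hidden state sequences and generating
parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, Subject, TimeCourseSet

log = logging.getLogger("dfcstates")

__all__ = ["RunConfig", "write_cohort", "read_cohort"]

MANIFEST_NAME = "manifest.json"
GROUND_TRUTH_NAME = "ground_truth.json"


@dataclass
class RunConfig:
    """End-to-end pipeline settings; JSON round-trippable.

    Every stochastic stage derives its own seed deterministically from
    ``seed`` and the stage name, so one master seed reproduces a full run.
    """

    window_trs: int = 20
    sigma_seconds: float = 3.0
    window_stat: str = "covariance"  # or "correlation"
    k: int | None = None  # None -> elbow selection over k_range
    k_min: int = 2
    k_max: int = 8
    n_replicates: int = 50
    max_iter: int = 1000
    alpha: float = 0.5
    outer_folds: int = 10
    inner_folds: int = 9
    sample_unit: str = "subject-median"
    covariates: tuple[str, ...] = ("age", "gender")
    symptom_scales: tuple[str, ...] | None = None  # None -> all present
    seed: int = 0
    verbosity: str = "INFO"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        for key in ("covariates", "symptom_scales"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        import zlib
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _json_scalar(v):
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def write_cohort(cohort: TimeCourseSet, out_dir: str | Path) -> Path:
    """Write a cohort as manifest JSON + per-subject TSV time courses.

    Returns the manifest path.  Ground truth, when present, goes to a
    separate JSON sidecar so analysis stages cannot accidentally read it.
    """
    out = Path(out_dir)
    (out / "timecourses").mkdir(parents=True, exist_ok=True)
    entries = []
    for s in cohort.subjects:
        rel = f"timecourses/{s.id}.tsv"
        header = "\t".join(cohort.node_labels)
        np.savetxt(out / rel, s.signal, delimiter="\t", header=header,
                   comments="", fmt="%.10g")
        entries.append({
            "id": s.id,
            "group": s.group,
            "path": rel,
            "covariates": s.covariates,
            "symptoms": {k: _json_scalar(v) for k, v in s.symptoms.items()},
        })
    manifest = {
        "tr_seconds": cohort.tr_seconds,
        "node_labels": cohort.node_labels,
        "subjects": entries,
    }
    mpath = out / MANIFEST_NAME
    mpath.write_text(json.dumps(manifest, indent=2))
    gt = cohort.ground_truth
    if gt is not None:
        gt_data = {
            "state_sequences": {k: v.tolist() for k, v in gt.state_sequences.items()},
            "window_state_sequences": {k: v.tolist() for k, v in
                                       gt.window_state_sequences.items()},
            "transition_matrices": {g: m.tolist() for g, m in
                                    gt.transition_matrices.items()},
            "empirical_transitions": {k: v.tolist() for k, v in
                                      gt.empirical_transitions.items()},
            "symptom_latents": {k: _json_scalar(v) for k, v in
                                gt.symptom_latents.items()},
        }
        (out / GROUND_TRUTH_NAME).write_text(json.dumps(gt_data))
    return mpath


def read_cohort(manifest_path: str | Path) -> TimeCourseSet:
    """Load and validate a cohort from its manifest.

    Checks that every time-course file exists, is rectangular and finite,
    and that the node order (header row) is identical across subjects;
    a node-order mismatch is a hard error.  Missing symptom values are
    allowed and tallied in the log.

    Raises
    ------
    FileNotFoundError, ValueError
        Naming the offending subject.
    """
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    root = mpath.parent
    node_labels = list(manifest["node_labels"])
    tr = float(manifest["tr_seconds"])
    subjects: list[Subject] = []
    n_missing = 0
    n_time = None
    for entry in manifest["subjects"]:
        sid = entry["id"]
        fpath = root / entry["path"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"subject {sid}: time-course file {fpath} does not exist")
        df = pd.read_csv(fpath, sep="\t")
        if list(df.columns) != node_labels:
            raise ValueError(
                f"subject {sid}: node order {list(df.columns)} does not match "
                f"the manifest node order {node_labels}")
        signal = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(signal)):
            raise ValueError(f"subject {sid}: non-finite values in time courses")
        if n_time is None:
            n_time = signal.shape[0]
        elif signal.shape[0] != n_time:
            raise ValueError(
                f"subject {sid}: {signal.shape[0]} timepoints, expected {n_time}")
        symptoms = {k: (float("nan") if v is None else float(v))
                    for k, v in entry.get("symptoms", {}).items()}
        n_missing += sum(1 for v in symptoms.values() if math.isnan(v))
        subjects.append(Subject(
            id=sid, group=entry["group"], signal=signal,
            covariates=dict(entry.get("covariates", {})), symptoms=symptoms,
        ))
    # Canonical subject order: downstream stages (window pooling, CV folds)
    # see the same cohort regardless of manifest ordering.
    subjects.sort(key=lambda s: s.id)
    groups = {s.group for s in subjects}
    if len(groups) > 2:
        raise ValueError(f"expected at most two group labels, found {sorted(groups)}")
    gt = None
    gt_path = root / GROUND_TRUTH_NAME
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        gt = GroundTruth(
            state_sequences={k: np.asarray(v) for k, v in
                             raw["state_sequences"].items()},
            transition_matrices={g: np.asarray(m) for g, m in
                                 raw["transition_matrices"].items()},
            empirical_transitions={k: np.asarray(v) for k, v in
                                   raw["empirical_transitions"].items()},
            window_state_sequences={k: np.asarray(v) for k, v in
                                    raw.get("window_state_sequences", {}).items()},
            symptom_latents={k: (float("nan") if v is None else float(v))
                             for k, v in raw["symptom_latents"].items()},
            config=None,
        )
    counts = {g: sum(1 for s in subjects if s.group == g) for g in sorted(groups)}
    log.info("read cohort: %d subjects %s, %d nodes, %d missing symptom values",
             len(subjects), counts, len(node_labels), n_missing)
    return TimeCourseSet(subjects=subjects, node_labels=node_labels,
                         tr_seconds=tr, ground_truth=gt)
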