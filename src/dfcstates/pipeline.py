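"""End-to-end orchestration: dFC -> states -> features -> reports.

``run_pipeline`` executes every stage on a cohort, writes all intermediates
(windowed features, centroids, state sequences, transition features,
classification and association reports) as delimited text / JSON under an
output directory, and records configuration, derived stage seeds and the
package version in a provenance file.  Reruns with the same configuration
and master seed are reproducible: integer outputs bit-identically, floating
point within 1e-10.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationReport, associate_transitions
from .classify import (
    ClassificationReport,
    build_state_dataset,
    group_difference_test,
    group_top_features,
    nested_cv_classify,
)
from .clustering import StateModel, fit_state_model
from .io import RunConfig, read_cohort
from .simulate import TimeCourseSet
from .transitions import TransitionMatrix, feature_names, flatten_features, \
    occupancy_and_dwell, transition_matrix
from .windows import DFCSeries, build_taper, sliding_dfc

log = logging.getLogger("dfcstates")

__all__ = ["PipelineResult", "run_pipeline",
           "stage_dfc", "stage_cluster", "stage_features",
           "stage_classify", "stage_associate"]


@dataclass
class PipelineResult:
    dfc: list[DFCSeries]
    state_model: StateModel
    transition_matrices: list[TransitionMatrix]
    transition_table: pd.DataFrame
    classification: dict[int, ClassificationReport]
    classification_skipped: dict[int, str]
    association: AssociationReport | None
    out_dir: Path | None


def stage_dfc(cohort: TimeCourseSet, config: RunConfig) -> list[DFCSeries]:
    """Tapered sliding-window connectivity for every subject."""
    taper = build_taper(config.window_trs, config.sigma_seconds, cohort.tr_seconds)
    return [
        sliding_dfc(s.signal, taper, stat=config.window_stat,
                    subject_id=s.id, node_labels=cohort.node_labels)
        for s in cohort.subjects
    ]


def stage_cluster(dfc: list[DFCSeries], config: RunConfig) -> StateModel:
    """Pool windows, select K if requested, and fit the state model."""
    return fit_state_model(
        dfc, k=config.k, k_range=range(config.k_min, config.k_max + 1),
        n_replicates=config.n_replicates, max_iter=config.max_iter,
        seed=config.stage_seed("cluster"),
    )


def stage_features(
    model: StateModel,
) -> tuple[list[TransitionMatrix], pd.DataFrame]:
    """Per-subject transition matrices plus a flat feature table
    (K^2 transition features + occupancy + mean dwell per state)."""
    k = model.n_states
    tms, rows = [], []
    for seq in model.assignments:
        tm = transition_matrix(seq, k)
        tms.append(tm)
        vec, names = flatten_features(tm)
        occ, dwell = occupancy_and_dwell(seq, k)
        row = dict(zip(names, vec))
        row.update({f"occupancy_{s + 1}": occ[s] for s in range(k)})
        row.update({f"dwell_{s + 1}": dwell[s] for s in range(k)})
        rows.append(row)
    table = pd.DataFrame(rows, index=[t.subject_id for t in tms])
    return tms, table


def stage_classify(
    dfc: list[DFCSeries],
    model: StateModel,
    labels: dict[str, str],
    config: RunConfig,
) -> tuple[dict[int, ClassificationReport], dict[int, str]]:
    """Per-state nested-CV elastic-net classification with feature grouping.

    States where a dataset cannot be formed (a class absent, or too few
    subjects per class for the folds) are skipped with the reason recorded.
    """
    reports: dict[int, ClassificationReport] = {}
    skipped: dict[int, str] = {}
    for state_id in range(1, model.n_states + 1):
        try:
            ds = build_state_dataset(dfc, model.assignments, state_id,
                                     labels, sample_unit=config.sample_unit)
            rep = nested_cv_classify(
                ds, outer_folds=config.outer_folds,
                inner_folds=config.inner_folds, alpha=config.alpha,
                seed=config.stage_seed(f"classify-{state_id}"),
            )
            rep.top_group = group_top_features(rep.importance_per_fold)
            rep.group_diff = group_difference_test(ds, rep.top_group)
            reports[state_id] = rep
        except ValueError as exc:
            skipped[state_id] = str(exc)
            log.warning("state %d classification skipped: %s", state_id, exc)
    return reports, skipped


def stage_associate(
    tms: list[TransitionMatrix],
    cohort: TimeCourseSet,
    config: RunConfig,
    clinical_group: str = "SZ",
) -> AssociationReport | None:
    """Covariate-adjusted symptom association over clinical subjects."""
    clin_ids = {s.id for s in cohort.subjects if s.group == clinical_group}
    clin_tms = [t for t in tms if t.subject_id in clin_ids]
    symptoms = cohort.symptoms_frame(clinical_group)
    if symptoms.empty or not clin_tms:
        log.warning("no clinical symptom scores; association skipped")
        return None
    cov = cohort.covariates_frame(clinical_group)
    cov = cov[[c for c in config.covariates if c in cov.columns]]
    scales = list(config.symptom_scales) if config.symptom_scales else None
    return associate_transitions(clin_tms, symptoms, cov, scales)


def _write_outputs(result: PipelineResult, model: StateModel,
                   config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "dfc").mkdir(exist_ok=True)
    pair_names = ["-".join(p) for p in model.feature_index]
    for d in result.dfc:
        np.savetxt(out / "dfc" / f"{d.subject_id}.tsv", d.features,
                   delimiter="\t", header="\t".join(pair_names),
                   comments="", fmt="%.10g")
    np.savetxt(out / "centroids.tsv", model.centroids, delimiter="\t",
               header="\t".join(pair_names), comments="", fmt="%.10g")
    if model.inertia_curve is not None:
        model.inertia_curve.to_csv(out / "inertia_curve.tsv", sep="\t",
                                   index=False)
    with open(out / "assignments.tsv", "w") as fh:
        for seq in model.assignments:
            fh.write(seq.subject_id + "\t" +
                     "\t".join(str(int(v)) for v in seq.states) + "\n")
    result.transition_table.to_csv(out / "transition_features.tsv", sep="\t",
                                   index_label="subject")
    for sid, rep in result.classification.items():
        payload = {
            "state": sid,
            "auc": rep.auc,
            "importance": dict(zip(rep.feature_names, rep.importance.tolist())),
            "lambda_selected": rep.lambda_selected.tolist(),
            "top_group": [rep.feature_names[j] for j in (rep.top_group or [])],
            "group_differences": rep.group_diff.to_dict(orient="records")
            if rep.group_diff is not None else None,
        }
        (out / f"classification_state{sid}.json").write_text(
            json.dumps(payload, indent=2))
        rep.roc_points.to_csv(out / f"roc_state{sid}.tsv", sep="\t", index=False)
    if result.association is not None:
        result.association.table.to_csv(out / "association.tsv", sep="\t",
                                        index=False)
    provenance = {
        "package": "dfcstates",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {
            s: config.stage_seed(s)
            for s in ["cluster"] + [f"classify-{i}"
                                    for i in range(1, model.n_states + 1)]
        },
        "selected_k": model.selected_k,
        "knee_strength": model.knee_strength,
        "classification_skipped": result.classification_skipped,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))


def run_pipeline(
    cohort: TimeCourseSet | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute simulate/ingest -> dFC -> cluster -> features -> classify ->
    associate on a cohort (in memory or a manifest path).

    Raises on stage failure with the stage named; outputs produced before
    the failure are kept on disk when ``out_dir`` is given.
    """
    config = config or RunConfig()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    if not isinstance(cohort, TimeCourseSet):
        cohort = read_cohort(cohort)
    log.info("stage dfc: %d subjects", len(cohort))
    dfc = stage_dfc(cohort, config)
    log.info("stage cluster: %d pooled windows, seed %d",
             sum(d.n_windows for d in dfc), config.stage_seed("cluster"))
    model = stage_cluster(dfc, config)
    log.info("stage features: K=%d", model.n_states)
    tms, table = stage_features(model)
    log.info("stage classify")
    reports, skipped = stage_classify(dfc, model, cohort.labels(), config)
    log.info("stage associate")
    assoc = stage_associate(tms, cohort, config)
    result = PipelineResult(
        dfc=dfc, state_model=model, transition_matrices=tms,
        transition_table=table, classification=reports,
        classification_skipped=skipped, association=assoc,
        out_dir=Path(out_dir) if out_dir else None,
    )
    if out_dir is not None:
        _write_outputs(result, model, config, Path(out_dir))
        log.info("outputs written to %s", out_dir)
    return result
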