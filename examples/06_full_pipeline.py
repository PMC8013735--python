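"""Run the whole pipeline from a cohort manifest on disk.

Equivalent to the CLI:
    dfcstates simulate --out cohort_dir --n-hc 15 --n-sz 15 --seed 6
    dfcstates run-all --manifest cohort_dir/manifest.json --out run_dir --seed 0
"""

from dfcstates import (RunConfig, cobre_like_config, generate_cohort,
                       run_pipeline, write_cohort)

cohort = generate_cohort(cobre_like_config(n_hc=15, n_sz=15, seed=6))
manifest = write_cohort(cohort, "example_cohort_full")

cfg = RunConfig(k=None, k_min=2, k_max=8, n_replicates=20, seed=0,
                outer_folds=5, inner_folds=4, verbosity="WARNING")
result = run_pipeline(manifest, cfg, out_dir="example_run")

model = result.state_model
print(f"selected K = {model.n_states} (knee strength "
      f"{model.knee_strength:.2f})")
for sid, rep in sorted(result.classification.items()):
    print(f"state {sid}: AUC = {rep.auc:.3f}, "
          f"top features = {[rep.feature_names[j] for j in rep.top_group]}")
for sid, reason in result.classification_skipped.items():
    print(f"state {sid}: skipped ({reason.splitlines()[0]})")
if result.association is not None:
    best = result.association.table.iloc[0]
    print(f"top association: {best['feature']} vs {best['scale']} "
          f"(r = {best['r']:.2f}, q = {best['q']:.3f})")
print("all intermediates and reports written under example_run/")
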