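"""Link state-transition probabilities to symptom severity.

Each clinical subject's state sequence is summarized by its 5x5
transition-probability matrix (25 features); each feature is
partial-correlated with each symptom scale, adjusting for age and gender,
with Benjamini-Hochberg FDR within the 25-feature family per scale.

Two runs are shown.  First, features computed from the generator's own
hidden state sequences recover the planted 2->4 link at its target r.
Second, features estimated by the full pipeline (windowed covariance ->
k-means sequences, matched back to the generating states) illustrate how
much of that signal survives window-resolution state estimation at a
realistic scan length -- windowing absorbs state runs shorter than about
half a window, which costs roughly half the between-subject signal in a
transition cell before the association stage even starts.
"""

import numpy as np

from dfcstates import (associate_transitions, build_taper, cobre_like_config,
                       fit_state_model, generate_cohort, match_states,
                       sliding_dfc, transition_matrix, vectorize_fc)
from dfcstates.clustering import StateSequence

cohort = generate_cohort(cobre_like_config(n_hc=30, n_sz=120, seed=5))
symptoms = cohort.symptoms_frame("SZ")
covariates = cohort.covariates_frame("SZ")[["age", "gender"]]
sz_ids = {s.id for s in cohort.subjects if s.group == "SZ"}

# --- oracle run: generator-truth state sequences -------------------------
tms_true = [transition_matrix(cohort.ground_truth.state_sequences[i], 5,
                              subject_id=i) for i in sorted(sz_ids)]
rep_true = associate_transitions(tms_true, symptoms, covariates,
                                 scales=["panss_total"])
best = rep_true.table.iloc[0]
print("generator-truth features (planted 2->4 link, target r = 0.40):")
print(f"  top hit: {best['feature']} r = {best['r']:.2f}, "
      f"q = {best['q']:.4f}, n = {int(best['n'])}")

# --- pipeline run: estimated sequences, states matched to the generator --
taper = build_taper(20, 3.0, 2.0)
dfc = [sliding_dfc(s.signal, taper, subject_id=s.id,
                   node_labels=cohort.node_labels) for s in cohort.subjects]
model = fit_state_model(dfc, k=5, n_replicates=20, seed=0)
true_patterns = np.stack([
    vectorize_fc(c) for c in
    cohort.ground_truth.config.state_covariances["HC"]])
perm, sim = match_states(model.centroids, true_patterns)
relabel = np.array([perm[c] + 1 for c in range(5)])
print(f"\nfitted states matched to generating patterns "
      f"(centroid correlations {np.round([sim[c, perm[c]] for c in range(5)], 2)})")

tms_est = [transition_matrix(
    StateSequence(seq.subject_id, relabel[seq.states - 1]), 5)
    for seq in model.assignments if seq.subject_id in sz_ids]
rep_est = associate_transitions(tms_est, symptoms, covariates,
                                scales=["panss_total"])
row = rep_est.table[rep_est.table["feature"] == "P(2->4)"].iloc[0]
print("pipeline-estimated features:")
print(f"  P(2->4): r = {row['r']:.2f}, q = {row['q']:.4f}, n = {int(row['n'])}")
print("the drop from the oracle r reflects window-resolution state "
      "estimation, not the association statistics")
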