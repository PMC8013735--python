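# Methods

`dfcstates` implements a dynamic functional connectivity (dFC) state
analysis for small brain-network parcellations — here a 7-subnode default
mode network (DMN) with three precuneus (PCu), two anterior cingulate
(ACC) and two posterior cingulate (PCC) subnodes — together with a
generative simulator that makes every stage testable by parameter
recovery. This note records the model, the estimation choices, and the
reasoning behind the places where the design was genuinely open.

## Pipeline model

Per subject, the observed data are node time courses `X ∈ R^{N×C}`
(N time points at repetition time TR, C nodes). The analysis assumes the
signal visits a small number K of recurring *connectivity states*: periods
in which the instantaneous C×C covariance is quasi-stable. The stages are:

1. **Tapered sliding-window connectivity.** A nominal L-TR window
   (default L = 20, i.e. 40 s at TR = 2 s) is smoothed by a Gaussian
   (σ = 3 s): the weight vector is the convolution of a rectangle over the
   window's inclusive L+1-sample support with a unit-mass discrete
   Gaussian of σ/TR samples (kernel truncated at ±4σ, truncation error
   < 1e-4), cropped to the central L+1 samples and renormalized.
   The inclusive L+1-sample reading is deliberate: it is the only
   convention under which (a) the weight vector is exactly symmetric and
   (b) unit-step windowing yields T = N − L windows, matching both
   standard scan lengths used in this literature (144 → 124, 157 → 137).
   Signals are z-scored per node over the whole series (so feature scales
   are comparable across subjects), and each window's taper-weighted
   covariance (weighted mean removed, normalized by the weight sum) is
   vectorized to its strict upper triangle, row-wise — 21 node-pair
   features for C = 7. A weighted correlation variant is available
   (`stat="correlation"`), as is unstandardized input (`standardize=False`).
   Note the windowed estimator has expectation (1 − Σw²)·Σ; tests undo
   this factor when comparing against generating covariances.

2. **State clustering.** Windows from all subjects and both groups are
   pooled and partitioned by k-means under the correlation distance
   d(x, c) = 1 − Pearson(x, c), with arithmetic-mean centroid updates (not
   renormalized), k-means++-style seeding, and convergence declared when
   assignments stop changing (cap 1000 Lloyd iterations). Empty clusters
   are re-seeded from the window farthest from its assigned centroid. The
   best of `n_replicates` (default 50) restarts by total within-cluster
   distance is kept. Correlation distance with mean centroids is standard
   in dFC state analysis; since 1 − r is invariant to the affine scale of
   the centroid, Lloyd steps reduce to cosine similarity between
   row-standardized windows and standardized centroids, which keeps the
   implementation a dense matrix product.

3. **Number of states (elbow).** For each candidate k, the ratio
   R(k) = mean within-cluster distance / mean between-centroid distance is
   computed. The selected k is the interior point of the R curve lying
   furthest *below the chord* joining the curve's endpoints, ties toward
   smaller k. We initially used the discrete second difference of R, but
   found it unreliable on our own well-separated preset: when the per-k
   drops decay gradually and unevenly, curvature peaks one k early (it
   chose k = 4 in 2/10 cohorts at one seed base). The chord rule selected
   the planted K = 5 in 30/30 cohorts across three seed bases, and has a
   useful side effect: on structureless data the R curve is concave, every
   interior point lies *above* the chord, and the reported knee strength
   (max chord distance / R range, clipped at 0) is exactly 0. A knee
   strength below 0.1 should be read as "no convincing cluster structure".
   With fewer than three candidate k there is no interior; the k with the
   smallest ratio is returned with a warning.

4. **State matching across fits/datasets.** Centroid sets are aligned by
   the Hungarian assignment maximizing total pairwise Pearson correlation;
   the full similarity matrix is returned so weak matches stay visible.
   Per-state summaries average centroid features within/between the
   PCu/ACC/PCC blocks (six columns: PCu, ACC, PCC, PCu/ACC, PCu/PCC,
   ACC/PCC).

5. **Transition features.** Each subject's window-level state sequence is
   summarized by the empirical maximum-likelihood first-order transition
   matrix P[j, i] = #{s(t)=j, s(t+1)=i} / #{t<T : s(t)=j} — exactly the
   conditional frequency a hidden-Markov transition probability reduces to
   when the state sequence is observed; no Baum–Welch fitting is done.
   Rows of states never visited before the final time point are zero and
   flagged; downstream analyses delete flagged features pairwise (no
   Laplace smoothing by default). Row-major flattening gives K² named
   features ("P(j→i)", 1-based); K = 5 gives 25. Fractional occupancy and
   mean dwell (mean run length) are provided as auxiliary summaries.

6. **Group discrimination.** Per state, the default sample is one row per
   subject — the elementwise median of that subject's windows in the state
   (subjects with no window in the state are excluded and listed). This
   avoids within-subject leakage across CV folds; a window-level mode with
   subject-grouped folds is retained for sensitivity analyses. A logistic
   model with elastic-net penalty
   λ·(α|β|₁ + (1−α)/2·‖β‖₂²), α default 0.5, intercept unpenalized, is
   fit along 100 logarithmically spaced λ from 1e−5 to 1e5 by warm-started
   IRLS + cyclic coordinate descent (soft-thresholding updates on the
   working weighted least-squares problem; tolerance 1e−7 on the maximum
   coefficient update; IRLS weights floored at 1e-5 so quasi-separated
   fits stay finite). The fitter agrees with scikit-learn's saga
   elastic-net logistic regression at matched C = 1/(Nλ) to ~1e−3 and is
   roughly five times faster over a full path, which is what makes the
   nested sweep affordable: 10 outer × 9 inner stratified subject-grouped
   folds (train:test 9:1 in both loops), λ chosen to minimize mean
   inner-fold misclassification (ties toward the more regularized model),
   features z-scored with training-split statistics only. Outer held-out
   probabilities are pooled into a single ROC/AUC. Feature importance is
   the *retention proportion*: the fraction of inner-fold models across
   the λ sweep in which a feature's coefficient is strictly nonzero. The
   "equally important top group" is found by one-way ANOVA across features
   on per-outer-fold retention followed by Tukey pairwise comparisons at
   family level 0.05: every feature not significantly below the
   best-retained feature. Group differences on those features use Welch
   two-sample t tests with Benjamini–Hochberg correction within the
   selected set; direction is sign(mean_HC − mean_SZ); features constant
   in both groups get p = 1 by convention.

7. **Symptom association.** For clinical subjects only, each transition
   feature is related to each symptom scale (PANSS positive/negative/
   total) by Pearson partial correlation: x and y are residualized on
   [intercept | covariates] by least squares (categorical covariates as
   indicator columns), r is the Pearson correlation of residuals, and
   p comes from t = r·√((n−2−k)/(1−r²)) on n−2−k df, two-sided. Missing
   scores and flagged features are deleted pairwise; a feature needs
   n > k+2 usable subjects or it is reported as missing, as is any
   correlation whose residuals are numerically constant (e.g. a perfect
   confound). BH q-values are computed within the K²-feature family of
   each scale separately (whether scales should be pooled into one family
   is a judgment call; per-scale matches correcting "over the HMM
   features" and is the default).

## The synthetic cohort generator

Real resting-state fMRI for this design is restricted, so validation runs
on synthetic cohorts from a hidden-Markov covariance-switching model: per
subject a hidden first-order Markov chain over K = 5 states (uniform
initial state, group-specific row-stochastic transition matrix), and at
each TR a zero-mean Gaussian draw with the active state's C×C covariance.
This is the simplest generative model under which the windowed-covariance
+ k-means pipeline is consistent, which is exactly what makes parameter
recovery a meaningful test.

Key defaults (the `cobre_like_config` preset):

| parameter | default | rationale |
|---|---|---|
| n_hc / n_sz | 89 / 68 | group sizes of the public eyes-open dataset |
| N time points | 144 | 149 acquired volumes − 5 discarded dummy scans |
| TR | 2.0 s | acquisition protocol of both source datasets |
| C nodes | 7 | PCu1, PCu2, ACC1, PCC1, ACC2, PCu3, PCC2 |
| K states | 5 | the state count the analysis is expected to recover |
| self-transition | 0.95 | mean dwell 20 TRs = 40 s, mid-range of reported connectivity-state dwell times |
| SZ 2→4 boost | +0.025 | planted dynamical group effect on the linked cell |
| symptom link | (2→4, r = 0.40, noise σ = 1) | planted score-transition coupling |
| missing scores | 6% of SZ | mirrors 64/68 and 141/151 usable in the source cohorts |

The five state covariances are correlation-like matrices (unit diagonal)
built from six block values (within-PCu/ACC/PCC and the three
between-group blocks). The block patterns were chosen by randomized
search, frozen, to satisfy two hard requirements: every matrix positive
definite (min eigenvalue > 0.14) and the vectorized patterns mutually
near-orthogonal (max pairwise centroid correlation 0.24). Well-separated
states are what make K-selection and label-recovery tests informative; as
a consequence the per-state sign layout is *not* a replica of any
published table beyond constrained cells (ACC/PCC negative in all
states). Group contrasts are planted directionally as reported in this
literature — PCu/PCC coupling +0.10 in the clinical group in states 1 and
4, within-ACC −0.10 in states 1, 2, 4 — with 0.10 the largest round
magnitude keeping all clinical covariances positive semidefinite.

Clinical symptom scores are a·P̂(2→4) + ε, where P̂ is the subject's
*realized* hidden-chain transition frequency, ε ~ N(0, σ²), and the gain
a = σ·r/(s_P·√(1−r²)) is calibrated against the realized spread s_P so the
score-latent correlation is the target r in expectation; scores are then
affinely mapped to a PANSS-like scale (mean 15, SD 5), which preserves
correlations. Subjects whose chain never leaves state 2 contribute noise
only. Covariates (age, gender, site) are generated independently of
symptoms, so covariate adjustment is a no-op in expectation; an optional
per-site score shift plants a confound for testing adjustment. Ground
truth — hidden sequences, configured and realized transition matrices,
majority-state window sequences, and symptom latents — is embedded in the
returned cohort and written to a separate JSON sidecar, never read by
analysis stages.

**What the generator does not emulate:** hemodynamic response dynamics,
scanner/physiological noise spectra, motion artifacts, spatial maps,
site- or eye-condition-dependent dynamics, within-state nonstationarity.
State switches are instantaneous at TR resolution and emissions are
Gaussian. Passing recovery tests therefore shows the *estimators* are
correct and consistent under the stated model — not that real fMRI
satisfies that model.

### Planted window labels

A window that straddles a hidden state change observes a covariance
mixture and has no well-defined planted identity. The generator therefore
labels a window with a state only when that state carries ≥ 80% of the
taper mass over the window's support (`planted_window_labels`); other
windows are marked undefined and excluded from agreement scoring. At the
preset's 40-s dwell about half the windows are labeled; labeled windows
are recovered at ≈ 98.5% after Hungarian matching. Scoring *all* windows
by bare majority instead would cap any method's agreement near 85%, a
number that measures the chain's switching rate rather than the
clustering.

### Window-resolution attenuation

An empirically important property, documented here because it shapes what
end-to-end tests can show: the majority-state *window* sequence retains
only ≈ 0.46 correlation (between subjects, at N = 144, L = 20) with the
hidden chain's realized P(2→4), because windowing absorbs state runs
shorter than about half a window. A symptom link planted on the TR-level
latent is therefore recovered at full strength from generator-truth
transition features (the association-stage test) but is attenuated
roughly to the noise floor after window-level state estimation at this
scan length. `examples/05_symptom_association.py` demonstrates both runs
side by side. The practical implication for real analyses is that
transition-probability features at T ≈ 124 windows carry large
per-subject estimation noise, and cross-subject associations survive only
to the extent that between-subject variance in the true dynamics exceeds
that noise.

## Numerical and degenerate-case choices

- Taper symmetry is enforced exactly by averaging the cropped convolution
  with its reversal (guards summation-order rounding).
- Constant node signals z-score to zero, yielding zero connectivity
  features rather than NaN.
- Zero-variance windows are rejected under correlation distance with an
  instruction to drop or jitter them.
- k-means ties in elbow selection go to the smaller k; λ ties in CV go to
  the larger λ (more regularization).
- BH q-values preserve input order and are clipped to [0, 1]; a single
  p-value maps to itself.
- All stage seeds derive deterministically from the master seed plus the
  stage name (CRC32 mix, kept below 2³¹); reruns are bit-identical for
  integer outputs and within 1e−10 for floating point.

## Validation problem sizes

The test suite validates at desk scale, chosen so the full suite runs in
minutes on one CPU: state-count/label recovery on 10 cohorts of 40
subjects × 144 time points; classifier null calibration over 50 nested-CV
replicates (n = 60); retention ranking over 20 replicates at n = 400;
association recovery over 50 cohorts of 150 clinical subjects plus 200
null cohorts of 60; a 100,000-step chain for transition consistency; and
a 24-subject end-to-end determinism rerun. Monte-Carlo assertions use
error envelopes consistent with the replicate counts (e.g. the BH family
error is tested against the one-sided binomial envelope of the nominal
rate, since at the nominal 0.05 the observed fraction exceeds 0.05 in
half of all honest replications).

## Known limitations

- Correlation-distance k-means with mean centroids has no global
  optimality guarantee; replicate restarts mitigate but do not remove
  this.
- The elbow criterion (any variant) is a heuristic; the knee strength is
  reported so callers can detect weak structure, but K selection on real
  data should be checked for stability across replicates.
- Transition matrices from T ≈ 124 windows are noisy (see attenuation
  note); occupancy/dwell summaries are more stable per subject.
- The elastic-net path tolerance (1e−7) trades a ~1e−3 coefficient
  agreement with reference solvers for speed; retention flags
  (coefficient ≠ 0) are insensitive to this at the λ grid's resolution
  except exactly at entry points.
- `pairwise_tukeyhsd` assumes equal within-group variances across
  features; retention proportions near 0 or 1 violate this mildly. The
  top-group output should be read as a descriptive grouping, not an
  inferential claim.
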