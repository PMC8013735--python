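"""Hidden-Markov covariance-switching cohort generator."""

import numpy as np
import pytest

from dfcstates import (
    CohortConfig,
    SymptomLink,
    build_taper,
    cobre_like_config,
    default_state_covariances,
    default_transition_matrices,
    generate_cohort,
    sliding_dfc,
)
from dfcstates.simulate import planted_window_labels


def single_state_config(cov, n_timepoints=10_000, seed=0):
    c = cov.shape[0]
    return CohortConfig(
        n_hc=1, n_sz=0, n_nodes=c, n_states=1, n_timepoints=n_timepoints,
        node_labels=tuple(f"n{i}" for i in range(c)),
        state_covariances={"HC": [cov], "SZ": [cov]},
        transition_matrices={"HC": np.ones((1, 1)), "SZ": np.ones((1, 1))},
        seed=seed,
    )


class TestGenerator:
    def test_single_state_identity_covariance(self):
        cohort = generate_cohort(single_state_config(np.eye(4)))
        sig = cohort.subjects[0].signal
        sample_cov = sig.T @ sig / len(sig)
        assert np.max(np.abs(sample_cov - np.eye(4))) < 0.05

    def test_windowed_covariance_inside_single_state_run(self):
        """Windowed estimates inside a long single-state run converge to
        that state's covariance."""
        rng = np.random.default_rng(3)
        a = rng.standard_normal((4, 4)) * 0.4
        cov = np.eye(4) + a @ a.T
        d_inv = 1 / np.sqrt(np.diag(cov))
        corr = cov * d_inv[:, None] * d_inv[None, :]
        cohort = generate_cohort(single_state_config(cov, seed=5))
        taper = build_taper(20, 3.0, 2.0)
        d = sliding_dfc(cohort.subjects[0].signal, taper)
        w = taper.weights
        mean_win = d.features.mean(0) / (1 - np.sum(w**2))
        iu, ju = np.triu_indices(4, 1)
        n_eff = len(d.features) / 21
        se = 3 * (1 - corr[iu, ju] ** 2) / np.sqrt(n_eff)
        assert np.all(np.abs(mean_win - corr[iu, ju]) < np.maximum(se, 0.02))

    def test_null_config_has_no_group_contrast(self):
        cfg = cobre_like_config(n_hc=40, n_sz=40, seed=11,
                                group_contrast=False, symptom_link=None)
        cohort = generate_cohort(cfg)
        taper = build_taper(20, 3.0, 2.0)
        means = {"HC": [], "SZ": []}
        for s in cohort.subjects:
            d = sliding_dfc(s.signal, taper)
            means[s.group].append(d.features.mean(0))
        hc, sz = np.asarray(means["HC"]), np.asarray(means["SZ"])
        diff = hc.mean(0) - sz.mean(0)
        # per-cell Monte-Carlo standard error of the group difference
        se = np.sqrt(hc.var(0) / len(hc) + sz.var(0) / len(sz))
        assert np.all(np.abs(diff) < 4.0 * se)

    def test_chain_frequencies_converge(self):
        cfg = cobre_like_config(n_hc=1, n_sz=0, seed=0).replace(
            n_timepoints=100_000)
        cohort = generate_cohort(cfg)
        seq = cohort.ground_truth.state_sequences[cohort.subjects[0].id]
        from dfcstates import transition_matrix
        est = transition_matrix(seq, 5).matrix
        target = cohort.ground_truth.transition_matrices["HC"]
        assert np.max(np.abs(est - target)) <= 0.02

    def test_symptom_link_hits_target_correlation(self):
        """Across 500 clinical subjects the emitted score correlates with
        the generator's own latent P(2->4) at the target r."""
        cfg = cobre_like_config(n_hc=0, n_sz=500, seed=21).replace(
            missing_symptom_fraction=0.0)
        cohort = generate_cohort(cfg)
        gt = cohort.ground_truth
        lat = np.array([gt.symptom_latents[s.id] for s in cohort.subjects])
        score = np.array([s.symptoms["panss_total"] for s in cohort.subjects])
        ok = np.isfinite(lat)
        r = np.corrcoef(lat[ok], score[ok])[0, 1]
        assert abs(r - 0.40) <= 0.05

    def test_site_confound_removed_by_adjustment(self):
        """With a planted per-site score shift, partial correlation
        adjusting for site recovers the planted link better than the
        unadjusted correlation."""
        from dfcstates import partial_correlation
        from dfcstates.simulate import CovariateModel
        cm = CovariateModel(sites=("siteA", "siteB"),
                            site_score_shift=(0.0, 10.0))
        cfg = cobre_like_config(n_hc=0, n_sz=400, seed=31).replace(
            covariate_model=cm, missing_symptom_fraction=0.0)
        cohort = generate_cohort(cfg)
        gt = cohort.ground_truth
        lat = np.array([gt.symptom_latents[s.id] for s in cohort.subjects])
        score = np.array([s.symptoms["panss_total"] for s in cohort.subjects])
        site = np.array([s.covariates["site"] == "siteB"
                         for s in cohort.subjects], dtype=float)
        ok = np.isfinite(lat)
        r_plain, _ = partial_correlation(lat[ok], score[ok])
        r_adj, _ = partial_correlation(lat[ok], score[ok], site[ok, None])
        assert r_adj > r_plain  # the site shift dilutes the raw correlation
        assert abs(r_adj - 0.40) < 0.10

    def test_missing_fraction_applied(self):
        cfg = cobre_like_config(n_hc=0, n_sz=100, seed=2).replace(
            missing_symptom_fraction=0.10)
        cohort = generate_cohort(cfg)
        n_missing = sum(
            1 for s in cohort.subjects if np.isnan(s.symptoms["panss_total"]))
        assert n_missing == 10

    def test_same_seed_bit_identical_different_seed_differs(self):
        a = generate_cohort(cobre_like_config(n_hc=3, n_sz=3, seed=5))
        b = generate_cohort(cobre_like_config(n_hc=3, n_sz=3, seed=5))
        c = generate_cohort(cobre_like_config(n_hc=3, n_sz=3, seed=6))
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.signal, sb.signal)
            assert sa.symptoms == sb.symptoms or (
                np.isnan(list(sa.symptoms.values())).all()
                and np.isnan(list(sb.symptoms.values())).all())
        assert not np.array_equal(a.subjects[0].signal, c.subjects[0].signal)


class TestValidation:
    def test_non_psd_covariance_rejected_naming_state(self):
        covs = default_state_covariances()
        bad = covs["HC"][2].copy()
        bad[0, 1] = bad[1, 0] = 5.0  # breaks positive semidefiniteness
        covs["HC"][2] = bad
        cfg = cobre_like_config(n_hc=2, n_sz=2).replace(state_covariances=covs)
        with pytest.raises(ValueError, match="HC state 3"):
            generate_cohort(cfg)

    def test_nonstochastic_transition_rows_rejected(self):
        tms = default_transition_matrices()
        tms["SZ"] = tms["SZ"] * 1.01
        cfg = cobre_like_config(n_hc=2, n_sz=2).replace(transition_matrices=tms)
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(cfg)

    def test_out_of_range_target_r_rejected(self):
        cfg = cobre_like_config(n_hc=2, n_sz=2,
                                symptom_link=SymptomLink(target_r=1.0))
        with pytest.raises(ValueError, match="target_r"):
            generate_cohort(cfg)

    def test_nonpositive_noise_sd_rejected(self):
        cfg = cobre_like_config(n_hc=2, n_sz=2,
                                symptom_link=SymptomLink(noise_sd=0.0))
        with pytest.raises(ValueError, match="noise_sd"):
            generate_cohort(cfg)


class TestPreset:
    def test_preset_dimensions(self):
        cfg = cobre_like_config()
        assert cfg.n_timepoints == 144
        assert cfg.n_nodes == 7
        assert cfg.n_states == 5
        assert cfg.n_hc == 89 and cfg.n_sz == 68

    def test_preset_transition_rows_stochastic(self):
        cfg = cobre_like_config()
        for g in ("HC", "SZ"):
            rows = np.asarray(cfg.transition_matrices[g]).sum(axis=1)
            np.testing.assert_allclose(rows, 1.0, atol=1e-12)

    def test_preset_states_well_separated(self):
        """Vectorized state patterns correlate pairwise at <= 0.3, the
        documented separation making recovery tests meaningful."""
        covs = default_state_covariances(group_contrast=False)["HC"]
        iu, ju = np.triu_indices(7, 1)
        v = np.stack([c[iu, ju] for c in covs])
        corr = np.corrcoef(v)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) <= 0.3
        for i, c in enumerate(covs):
            assert np.linalg.eigvalsh(c).min() > 0

    def test_preset_group_contrast_cells(self):
        covs = default_state_covariances()
        pcu, pcc, acc = [0, 1, 5], [3, 6], [2, 4]
        # PCu/PCC coupling higher in the clinical group in states 1 and 4
        for st in (0, 3):
            assert covs["SZ"][st][pcu[0], pcc[0]] > covs["HC"][st][pcu[0], pcc[0]]
        # within-ACC coupling higher in controls
        assert covs["HC"][1][acc[0], acc[1]] > covs["SZ"][1][acc[0], acc[1]]


class TestPlantedWindowLabels:
    def test_pure_run_and_mixed_boundary(self):
        taper = build_taper(4, 1.0, 2.0)  # 5-sample support
        seq = np.array([1] * 10 + [2] * 10)
        lab = planted_window_labels(seq, taper.weights, dominance=0.8)
        assert len(lab) == 16
        assert np.all(lab[:4] == 1)
        assert np.all(lab[-4:] == 2)
        assert np.any(lab == 0)  # windows straddling the change are unlabeled
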