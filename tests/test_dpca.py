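"""Marginalization exactness, reduced-rank fitting, projection, orientation."""

import numpy as np
import pytest

from dpcsig import (CONDITION_SELF, CONDITION_SUPPORT, TrialRecord,
                    fit_condition_dpca, fit_signature, generate_dataset,
                    marginalize, orient_sign, project_trial, project_trials)
from dpcsig.dpca import DpcaError
from conftest import small_config


def make_trial(data, condition, pid="P001"):
    return TrialRecord(participant_id=pid, memory_id="m", condition=condition,
                       target_type="self" if condition == CONDITION_SELF else
                       "support_provider", negativity_rating=3,
                       baseline_negativity=3, data=np.asarray(data, dtype=float))


def random_trials(rng, n_per_condition, n_parcels, n_timepoints):
    trials = []
    for c in (CONDITION_SUPPORT, CONDITION_SELF):
        for _ in range(n_per_condition):
            trials.append(make_trial(rng.standard_normal((n_parcels, n_timepoints)), c))
    return trials


class TestMarginalize:
    def test_two_condition_antisymmetry(self):
        trials = random_trials(np.random.default_rng(0), 5, 4, 3)
        m = marginalize(trials)
        assert np.abs(m.x_cond[:, 0, :] + m.x_cond[:, 1, :]).max() < 1e-12

    def test_identical_conditions_have_zero_condition_part(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((4, 3))
        trials = [make_trial(base, CONDITION_SUPPORT), make_trial(base, CONDITION_SELF)]
        m = marginalize(trials)
        assert np.abs(m.x_cond).max() < 1e-12

    def test_matches_loop_based_averaging_oracle(self):
        rng = np.random.default_rng(2)
        trials = random_trials(rng, 6, 4, 3)
        m = marginalize(trials)
        # independent oracle: explicit loops over cells
        conditions = (CONDITION_SUPPORT, CONDITION_SELF)
        cond_mean = np.zeros((4, 2, 3))
        for ci, c in enumerate(conditions):
            members = [t.data for t in trials if t.condition == c]
            for p in range(4):
                for tt in range(3):
                    cond_mean[p, ci, tt] = np.mean([d[p, tt] for d in members])
        gm = cond_mean.mean(axis=(1, 2))
        xbar = cond_mean - gm[:, None, None]
        x_time = xbar.mean(axis=1)
        assert np.abs(m.xbar - xbar).max() < 1e-12
        assert np.abs(m.x_time - x_time).max() < 1e-12
        assert np.abs(m.x_cond - (xbar - x_time[:, None, :])).max() < 1e-12

    def test_decomposition_is_exact_and_centered(self, small_dataset):
        m = marginalize(small_dataset.trials)
        recon = m.x_time[:, None, :] + m.x_cond
        assert np.abs(recon - m.xbar).max() < 1e-12
        assert np.abs(m.xbar.mean(axis=(1, 2))).max() < 1e-10

    def test_missing_condition_errors_naming_it(self):
        trials = [make_trial(np.zeros((3, 3)), CONDITION_SUPPORT)]
        with pytest.raises(DpcaError, match=CONDITION_SELF):
            marginalize(trials)


class TestFit:
    def test_noiseless_rank_one_recovery(self):
        rng = np.random.default_rng(3)
        P, T = 12, 8
        w = rng.standard_normal(P)
        w /= np.linalg.norm(w)
        g = rng.standard_normal(T)
        trials = [make_trial(s * np.outer(w, g), c)
                  for c, s in ((CONDITION_SUPPORT, 1.0), (CONDITION_SELF, -1.0))]
        model = fit_condition_dpca(trials, lam=0.0)
        assert abs(float(model.decoder @ w)) > 0.9999
        assert model.variance_explained["condition_captured"] > 0.9999

    def test_objective_matches_bruteforce_reduced_rank_oracle(self):
        # brute-force oracle: best rank-1 objective via the generalized
        # eigenproblem max_d (d'XY'YX'd)/(d'XX'd); residual = ||Y||^2 - lam_max
        from scipy.linalg import eigh

        rng = np.random.default_rng(4)
        for _ in range(10):
            trials = random_trials(rng, 3, 5, 4)
            m = marginalize(trials)
            X = m.xbar.reshape(5, -1)
            Y = m.x_cond.reshape(5, -1)
            lam_max = eigh(X @ Y.T @ Y @ X.T, X @ X.T, eigvals_only=True,
                           subset_by_index=[4, 4])[0]
            expected = float((Y ** 2).sum()) - float(lam_max)
            model = fit_condition_dpca(trials, lam=0.0)
            assert abs(model.objective - expected) < 1e-8

    def test_reconstruction_error_monotone_in_ridge_strength(self):
        rng = np.random.default_rng(5)
        trials = random_trials(rng, 4, 6, 5)
        lams = [0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
        objectives = [fit_condition_dpca(trials, lam=l).objective for l in lams]
        assert np.all(np.diff(objectives) >= -1e-10)
        # heavy shrinkage: the fitted component vanishes
        weak = fit_condition_dpca(trials, lam=1e8)
        assert np.linalg.norm(weak.encoder) < 1e-4

    def test_no_condition_variance_errors(self):
        base = np.random.default_rng(6).standard_normal((4, 3))
        trials = [make_trial(base, CONDITION_SUPPORT), make_trial(base, CONDITION_SELF)]
        with pytest.raises(DpcaError, match="condition variance"):
            fit_condition_dpca(trials)

    def test_fit_commutes_with_parcel_permutation(self):
        rng = np.random.default_rng(7)
        trials = random_trials(rng, 4, 6, 5)
        model = fit_signature(trials)
        perm = rng.permutation(6)
        permuted = [make_trial(t.data[perm], t.condition) for t in trials]
        model_p = fit_signature(permuted)
        assert np.allclose(model_p.decoder, model.decoder[perm], atol=1e-8)

    def test_recovery_improves_with_snr(self):
        snrs = [0.25, 0.5, 1.0, 2.0]
        mean_cos = []
        for snr in snrs:
            cosines = []
            for rep in range(8):
                trials, _, truth = generate_dataset(small_config(
                    seed=100 + rep, snr=snr, n_participants=12,
                    trials_per_participant=6))
                model = fit_signature(trials)
                cosines.append(abs(float(model.decoder @ truth.spatial_pattern)))
            mean_cos.append(np.mean(cosines))
        assert np.all(np.diff(mean_cos) >= -0.02)  # non-decreasing within MC slack


class TestProjection:
    def test_trial_at_grand_mean_projects_to_zero(self, small_dataset):
        model = fit_signature(small_dataset.trials)
        flat = make_trial(np.tile(model.grand_mean[:, None], (1, 12)),
                          CONDITION_SUPPORT)
        feats = project_trial(model, flat)
        assert np.abs(feats.z).max() < 1e-10
        assert feats.z.shape == (12,)

    def test_decoder_direction_projects_to_constant(self, small_dataset):
        model = fit_signature(small_dataset.trials)
        c = 2.5
        data = model.grand_mean[:, None] + c * model.decoder[:, None] * np.ones(12)
        feats = project_trial(model, make_trial(data, CONDITION_SUPPORT))
        assert np.allclose(feats.z, c, atol=1e-10)  # ||d|| = 1

    def test_dimension_mismatch_errors(self, small_dataset):
        model = fit_signature(small_dataset.trials)
        with pytest.raises(DpcaError, match="parcel dimension"):
            project_trial(model, make_trial(np.zeros((3, 12)), CONDITION_SUPPORT))

    def test_condition_difference_tracks_planted_profile(self, small_dataset):
        trials, _, truth = small_dataset
        model = fit_signature(trials)
        z = project_trials(model, trials)
        conds = np.array([t.condition for t in trials])
        diff = (z[conds == CONDITION_SUPPORT].mean(axis=0)
                - z[conds == CONDITION_SELF].mean(axis=0))
        r = np.corrcoef(diff, truth.temporal_profile)[0, 1]
        assert r > 0.9


class TestOrientation:
    def test_flipped_model_is_reoriented(self, small_dataset):
        trials, _, truth = small_dataset
        model = fit_signature(trials)
        import dataclasses
        flipped = dataclasses.replace(model, decoder=-model.decoder,
                                      encoder=-model.encoder, oriented=False)
        restored = orient_sign(flipped, trials)
        assert np.allclose(restored.decoder, model.decoder)

    def test_orientation_is_idempotent(self, small_dataset):
        model = fit_signature(small_dataset.trials)
        again = orient_sign(model, small_dataset.trials)
        assert np.array_equal(again.decoder, model.decoder)
        assert np.array_equal(again.encoder, model.encoder)

    def test_oriented_support_mean_exceeds_self_mean(self, small_dataset):
        model = fit_signature(small_dataset.trials)
        z = project_trials(model, small_dataset.trials)
        conds = np.array([t.condition for t in small_dataset.trials])
        assert z[conds == CONDITION_SUPPORT].mean() > z[conds == CONDITION_SELF].mean()

    def test_inverted_condition_signs_flip_decoder(self, small_dataset):
        # relabeling the conditions inverts the planted sign map, so the
        # oriented decoder must anti-correlate with the planted axis
        trials, _, truth = small_dataset
        swap = {CONDITION_SUPPORT: CONDITION_SELF, CONDITION_SELF: CONDITION_SUPPORT}
        swapped = [make_trial(t.data, swap[t.condition], t.participant_id)
                   for t in trials]
        model = fit_signature(trials)
        model_swapped = fit_signature(swapped)
        assert float(model.decoder @ truth.spatial_pattern) > 0.9
        assert float(model_swapped.decoder @ truth.spatial_pattern) < -0.9

    def test_tie_warns_and_keeps_sign(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((4, 3))
        # antisymmetric construction: projections of the two condition means
        # onto any axis are exactly opposite, never tied, so build a tie by
        # giving both conditions identical *time-averaged* projections
        w = np.array([1.0, 0, 0, 0])
        g = np.array([1.0, -1.0, 0.0])  # zero time-mean profile
        trials = [make_trial(np.outer(w, g), CONDITION_SUPPORT),
                  make_trial(-np.outer(w, g), CONDITION_SELF)]
        model = fit_condition_dpca(trials, lam=0.0)
        with pytest.warns(RuntimeWarning, match="tie"):
            oriented = orient_sign(model, trials)
        assert np.array_equal(oriented.decoder, model.decoder)
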