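import numpy as np
import pytest

from aefn import (MISSING, AnnotationMatrix, FeatureMatrix, RunConfig,
                  filter_annotators, fit_prior, majority_vote_hard,
                  majority_vote_soft, map_posterior, ranking_score, run_aefn,
                  run_gmm_mapml, run_map_ml, update_alpha_beta)
from aefn.aggregators import AnnotatorProfile, _engine
from aefn.errors import InputError
from aefn.mixture import Responsibilities
from aefn.simulator import AnnotatorSpec, SimulationConfig, make_panel, simulate

from conftest import random_annotations


def _profile(alpha, beta, active=None):
    alpha = np.atleast_2d(np.asarray(alpha, float))
    beta = np.atleast_2d(np.asarray(beta, float))
    if active is None:
        active = np.ones_like(alpha, dtype=bool)
    return AnnotatorProfile(alpha, beta, np.abs(alpha + beta - 1.0), active)


class TestMajorityVote:
    def test_soft_mean_of_observed(self):
        ann = AnnotationMatrix(np.array([[1, 0, 1], [1, 1, 1], [1, 0, MISSING]]),
                               ("a", "b", "c"), ("j1", "j2", "j3"))
        np.testing.assert_allclose(majority_vote_soft(ann), [2 / 3, 1.0, 0.5])

    def test_hard_tie_resolves_to_zero(self):
        ann = AnnotationMatrix(np.array([[1, 0], [1, 1]]), ("a", "b"), ("x", "y"))
        np.testing.assert_array_equal(majority_vote_hard(ann), [False, True])

    @pytest.mark.parametrize("seed", range(20))
    def test_hard_matches_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ann = random_annotations(rng, 15, 5, missing_rate=0.2)
        got = majority_vote_hard(ann)
        for i in range(ann.n):
            row = [v for v in ann.labels[i] if v != MISSING]
            assert got[i] == (sum(row) * 2 > len(row))


class TestRankingScore:
    @pytest.mark.parametrize("alpha,beta,expected", [
        (1.0, 1.0, 1.0),            # perfect annotator
        (0.5, 0.5, 0.0),            # coin-flip annotator
        (0.8400, 0.8445, 0.6845),   # competent annotator, typical estimates
        (0.1, 0.1, 0.8),            # systematic inverter still scores high
    ])
    def test_values(self, alpha, beta, expected):
        assert ranking_score(alpha, beta) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            ranking_score(1.2, 0.5)

    def test_invariant_under_label_flip(self):
        # flipping all labels and z turns sensitivity into specificity and
        # vice versa; the ranking score must not change
        rng = np.random.default_rng(3)
        ann = random_annotations(rng, 25, 4)
        z = rng.random(25)
        tau = Responsibilities(np.ones((25, 1)))
        active = np.ones((1, 4), bool)
        prof = update_alpha_beta(ann, z, tau, active)
        flipped = AnnotationMatrix(1 - ann.labels, ann.instance_ids, ann.annotator_ids)
        prof_f = update_alpha_beta(flipped, 1 - z, tau, active)
        np.testing.assert_allclose(prof_f.score, prof.score, atol=1e-12)
        np.testing.assert_allclose(prof_f.alpha, prof.beta, atol=1e-12)


class TestUpdateAlphaBeta:
    def test_degenerate_positive_mass(self):
        ann = AnnotationMatrix(np.ones((3, 1), int), ("a", "b", "c"), ("j",))
        tau = Responsibilities(np.ones((3, 1)))
        prof = update_alpha_beta(ann, np.ones(3), tau, np.ones((1, 1), bool))
        assert prof.alpha[0, 0] == pytest.approx(1.0, abs=1e-5)
        assert prof.beta[0, 0] == 0.5 and prof.beta_flagged[0, 0]

    def test_hand_count(self):
        ann = AnnotationMatrix(np.array([[1], [0], [0], [1]]),
                               ("a", "b", "c", "d"), ("j",))
        tau = Responsibilities(np.ones((4, 1)))
        prof = update_alpha_beta(ann, np.array([1.0, 1.0, 0.0, 0.0]), tau,
                                 np.ones((1, 1), bool))
        assert prof.alpha[0, 0] == pytest.approx(0.5)
        assert prof.beta[0, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, r, k = int(rng.integers(5, 30)), int(rng.integers(2, 5)), 2
        ann = random_annotations(rng, n, r, missing_rate=0.15)
        z = rng.random(n)
        tau = rng.random((n, k))
        tau /= tau.sum(axis=1, keepdims=True)
        prof = update_alpha_beta(ann, z, Responsibilities(tau), np.ones((k, r), bool))
        for kk in range(k):
            for j in range(r):
                num_a = den_a = num_b = den_b = 0.0
                for i in range(n):
                    if ann.labels[i, j] == MISSING:
                        continue
                    zik = tau[i, kk] * z[i]
                    num_a += zik * ann.labels[i, j]
                    den_a += zik
                    num_b += (tau[i, kk] - zik) * (1 - ann.labels[i, j])
                    den_b += tau[i, kk] - zik
                exp_a = np.clip(num_a / den_a, 1e-6, 1 - 1e-6) if den_a > 1e-12 else 0.5
                exp_b = np.clip(num_b / den_b, 1e-6, 1 - 1e-6) if den_b > 1e-12 else 0.5
                assert prof.alpha[kk, j] == pytest.approx(exp_a, abs=1e-12)
                assert prof.beta[kk, j] == pytest.approx(exp_b, abs=1e-12)


class TestFilterAnnotators:
    def test_threshold_rule(self):
        prof = _profile([[0.5, 0.9, 0.49]], [[0.55, 0.9, 0.53]])
        out = filter_annotators(prof, 0.3)
        np.testing.assert_array_equal(out.active, [[False, True, False]])

    def test_zero_threshold_never_filters(self):
        prof = _profile([[0.5, 0.5]], [[0.5, 0.5]])
        out = filter_annotators(prof, 0.0)
        assert out.active.all()

    def test_component_never_emptied(self):
        prof = _profile([[0.5, 0.52, 0.51]], [[0.5, 0.56, 0.51]])
        out = filter_annotators(prof, 0.3)  # all scores below threshold
        np.testing.assert_array_equal(out.active, [[False, True, False]])

    def test_inactive_cells_stay_inactive(self):
        prof = _profile([[0.9, 0.9]], [[0.9, 0.9]],
                        active=np.array([[True, False]]))
        out = filter_annotators(prof, 0.3)
        np.testing.assert_array_equal(out.active, [[True, False]])

    def test_threshold_domain(self):
        with pytest.raises(InputError):
            filter_annotators(_profile([[0.9]], [[0.9]]), 1.0)


class TestMapPosterior:
    def test_single_annotator_hand_arithmetic(self):
        ann = AnnotationMatrix(np.array([[1]]), ("i",), ("j",))
        prof = _profile([[0.9]], [[0.9]])
        z, factors = map_posterior(ann, prof, np.array([0.5]), np.array([0]))
        assert factors.a[0] == pytest.approx(0.9, abs=1e-9)
        assert factors.b[0] == pytest.approx(0.1, abs=1e-9)
        assert z[0] == pytest.approx(0.9, abs=1e-9)

    def test_symmetric_factors_return_prior(self):
        ann = AnnotationMatrix(np.array([[1, 0]]), ("i",), ("j1", "j2"))
        prof = _profile([[0.7, 0.7]], [[0.7, 0.7]])  # a == b by symmetry
        z, _ = map_posterior(ann, prof, np.array([0.5]), np.array([0]))
        assert z[0] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, r, k = 10, 4, 2
        ann = random_annotations(rng, n, r, missing_rate=0.2)
        alpha = rng.uniform(0.1, 0.9, (k, r))
        beta = rng.uniform(0.1, 0.9, (k, r))
        active = rng.random((k, r)) < 0.7
        active[:, 0] = True  # keep every component non-empty
        prof = _profile(alpha, beta, active)
        p = rng.uniform(0.05, 0.95, n)
        q = rng.integers(0, k, n)
        z, factors = map_posterior(ann, prof, p, q)
        for i in range(n):
            a = b = 1.0
            for j in range(r):
                if ann.labels[i, j] == MISSING or not active[q[i], j]:
                    continue
                y = ann.labels[i, j]
                a *= alpha[q[i], j] ** y * (1 - alpha[q[i], j]) ** (1 - y)
                b *= (1 - beta[q[i], j]) ** y * beta[q[i], j] ** (1 - y)
            expected = a * p[i] / (a * p[i] + b * (1 - p[i]))
            assert z[i] == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= z[i] <= 1.0

    def test_prior_only_fallback(self):
        ann = AnnotationMatrix(np.array([[1, MISSING], [MISSING, 0]]),
                               ("i1", "i2"), ("j1", "j2"))
        prof = _profile([[0.9, 0.9]], [[0.9, 0.9]],
                        active=np.array([[True, False]]))
        z, _ = map_posterior(ann, prof, np.array([0.3, 0.3]), np.array([0, 0]))
        assert z[1] == pytest.approx(0.3)  # only the inactive annotator observed i2


class TestFitPrior:
    def test_uninformative_targets_give_flat_prior(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 3))
        w, p = fit_prior(x, np.full(200, 0.5))
        np.testing.assert_allclose(w, 0.0, atol=1e-4)
        np.testing.assert_allclose(p, 0.5, atol=1e-4)

    def test_separable_targets_put_p_on_correct_side(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-2, 0.5, 100), rng.normal(2, 0.5, 100)])
        z = (x > 0).astype(float)
        _, p = fit_prior(x[:, None], z)
        assert ((p > 0.5) == (z == 1)).all()

    def test_local_optimality_against_perturbations(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((150, 2))
        z = 1 / (1 + np.exp(-(x @ [1.0, -0.5] + 0.2))) * 0.8 + 0.1
        w, _ = fit_prior(x, z)
        xa = np.column_stack([x, np.ones(len(x))])

        def penalized_ll(wv):
            s = xa @ wv
            return float(z @ s - np.logaddexp(0, s).sum() - 0.5e-4 * (wv @ wv))

        best = penalized_ll(w)
        for _ in range(100):
            assert best >= penalized_ll(w + rng.normal(0, 0.1, w.shape)) - 1e-9


def _sim(n, specs, seed):
    cfg = SimulationConfig(n_instances=n, annotator_specs=specs, seed=seed)
    return simulate(cfg)


def _fast_config(seed, **kw):
    kw.setdefault("k_range", (2, 2))
    kw.setdefault("families", ("full",))
    kw.setdefault("restarts", 2)
    return RunConfig(seed=seed, **kw)


class TestAlgorithmContracts:
    def test_filtering_disabled_reduces_to_unfiltered_run(self):
        truth = _sim(400, make_panel(2, 3, 2, seed=1), seed=1)
        cfg = _fast_config(1, xi_prune=0.0)
        res_a, _, _ = run_aefn(truth.annotations, truth.features, cfg)
        res_g = run_gmm_mapml(truth.annotations, truth.features, cfg)
        np.testing.assert_allclose(res_a.z, res_g.z, atol=1e-12)
        np.testing.assert_array_equal(res_a.y_hat, res_g.y_hat)

    def test_single_component_run_equals_global_run(self):
        truth = _sim(300, make_panel(2, 2, 2, seed=2), seed=2)
        cfg = _fast_config(2, k_range=(1, 1))
        res_g = run_gmm_mapml(truth.annotations, truth.features, cfg)
        res_m = run_map_ml(truth.annotations, truth.features, cfg)
        np.testing.assert_allclose(res_g.z, res_m.z, atol=1e-12)

    def test_initialization_is_majority_vote(self):
        truth = _sim(200, make_panel(1, 3, 2, seed=3), seed=3)
        cfg = _fast_config(3, max_iter=0)
        res = run_gmm_mapml(truth.annotations, truth.features, cfg)
        np.testing.assert_array_equal(res.z, majority_vote_soft(truth.annotations))

    def test_single_perfect_annotator_fixed_point(self):
        spec = (AnnotatorSpec("expert", np.full(2, 1 - 1e-6), np.full(2, 1 - 1e-6)),)
        truth = _sim(300, spec, seed=5)
        res, _, _ = run_aefn(truth.annotations, truth.features, _fast_config(5))
        np.testing.assert_array_equal(res.y_hat.astype(int),
                                      truth.annotations.labels[:, 0])

    def test_experts_survive_filtering_novices_removed(self):
        truth = _sim(2000, make_panel(2, 8, 2, seed=42), seed=42)
        _, profile, _ = run_aefn(truth.annotations, truth.features, _fast_config(42))
        roles = [s.role for s in truth.config.annotator_specs]
        experts = [j for j, role in enumerate(roles) if role == "expert"]
        novices = [j for j, role in enumerate(roles) if role == "novice"]
        assert profile.active[:, experts].all()      # both experts retained
        assert not profile.active[:, novices].any()  # active set within expert set

    def test_map_ml_recovers_homogeneous_accuracy(self):
        specs = tuple(AnnotatorSpec("expert", np.full(2, 0.8), np.full(2, 0.8))
                      for _ in range(5))
        truth = _sim(2000, specs, seed=11)
        _, profile, _ = _engine(truth.annotations, truth.features,
                                RunConfig(seed=11), fit_gmm=False, filtering=False)
        np.testing.assert_allclose(profile.alpha, 0.8, atol=0.05)
        np.testing.assert_allclose(profile.beta, 0.8, atol=0.05)

    def test_component_dependent_accuracy_estimated_in_right_direction(self):
        from aefn.simulator import make_specialist_panel
        from aefn.experiments import match_components
        from aefn.mixture import hard_component, responsibilities

        panel = make_specialist_panel(4, 2, seed=6)
        truth = _sim(2000, panel, seed=6)
        cfg = _fast_config(6)
        _, profile, model = _engine(truth.annotations, truth.features, cfg,
                                    fit_gmm=True, filtering=False)
        q = hard_component(responsibilities(model, truth.features))
        perm = match_components(truth.components, q, 2)
        for fitted_k in range(2):
            home = perm[fitted_k]          # specialist `home` is expert there
            away = 1 - home
            assert profile.score[fitted_k, home] > profile.score[fitted_k, away] + 0.2

    def test_active_sets_shrink_monotonically_and_never_empty(self):
        truth = _sim(800, make_panel(1, 6, 2, seed=9), seed=9)
        lines = []
        run_aefn(truth.annotations, truth.features, _fast_config(9),
                 log_fn=lines.append)
        counts = [list(map(int, ln.split("[")[1].rstrip("]").split()))
                  for ln in lines if "active_per_component" in ln]
        for prev, cur in zip(counts, counts[1:]):
            assert all(c <= p for c, p in zip(cur, prev))
            assert all(c >= 1 for c in cur)

    def test_posterior_in_unit_interval_every_iteration(self):
        truth = _sim(300, make_panel(1, 4, 2, seed=13), seed=13)
        zs = []
        # snapshot z at several depths of the iteration by capping max_iter
        for it in (1, 2, 3, 5, 8):
            cfg = _fast_config(13, max_iter=it)
            res = run_gmm_mapml(truth.annotations, truth.features, cfg)
            zs.append(res.z)
        for z in zs:
            assert ((z >= 0) & (z <= 1)).all()
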