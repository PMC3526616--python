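"""Linear SVM, LOO-CV, and the balanced-subsampling evaluation protocol."""

import numpy as np
import pytest
from scipy.optimize import minimize

from adcascade import (
    CohortSpec,
    assemble_features,
    balanced_subsample_eval,
    combine_structures,
    compare_classifiers,
    generate_cohort,
    isomap,
    loo_cv,
    pairwise_distances,
    select_components,
    train_linear_classifier,
)
from adcascade.classify import FEATURE_SETS, balanced_target_size, zscore_columns
from adcascade.synthetic import CSF_MARKERS


def svm_primal_objective(w, b, X, y, C):
    margins = 1 - y * (X @ w + b)
    return 0.5 * w @ w + C * np.clip(margins, 0, None).sum()


def qp_oracle(X, y, C):
    """Brute-force dual soft-margin QP on a small instance: maximize
    sum(a) - 1/2 a' (yy' * XX') a subject to 0 <= a <= C, a . y = 0."""
    n = len(y)
    Q = (y[:, None] * X) @ (y[:, None] * X).T

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(
        neg_dual, np.full(n, C / 2), jac=grad, method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    a = res.x
    w = ((a * y)[:, None] * X).sum(axis=0)
    margin_sv = (a > 1e-8 * C) & (a < C * (1 - 1e-8))
    b = float(np.mean(y[margin_sv] - X[margin_sv] @ w))
    return w, b, svm_primal_objective(w, b, X, y, C)


class TestLinearClassifier:
    def test_two_point_symmetry(self):
        model = train_linear_classifier(np.array([[-1.0], [1.0]]), np.array([-1, 1]), C=1.0)
        assert model.predict(np.array([[-0.5], [0.5]])).tolist() == [-1, 1]
        assert abs(model.bias) < 1e-9

    def test_separable_blobs_perfect_training(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(size=(20, 2)) - 5, rng.normal(size=(20, 2)) + 5])
        y = np.array([-1] * 20 + [1] * 20)
        model = train_linear_classifier(X, y, C=100.0)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(np.zeros((4, 2)), np.ones(4))

    @pytest.mark.parametrize("C", [0.5, 1.0, 10.0])
    def test_matches_qp_oracle_objective(self, C):
        """The fitted decision rule attains the brute-force QP optimum of the
        soft-margin objective on a 6-point toy set."""
        X = np.array([[0.0, 0], [1, 0.5], [0.4, 1.2], [2, 2], [2.5, 1.2], [1.4, 2.4]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        model = train_linear_classifier(X, y, C=C)
        ours = svm_primal_objective(model.weights, model.bias, X, y, C)
        _, _, oracle = qp_oracle(X, y, C)
        assert ours == pytest.approx(oracle, abs=1e-5)


class TestLooCv:
    def test_perfectly_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(10, 2)) - 10, rng.normal(size=(10, 2)) + 10])
        y = np.array([-1] * 10 + [1] * 10)
        acc, sens, spec = loo_cv(X, y)
        assert acc == sens == spec == 1.0

    def test_balanced_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(16, 3))
        y = np.array([-1, 1] * 8)
        acc, sens, spec = loo_cv(X, y)
        assert acc == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_null_centered_on_half(self):
        """Uninformative features: LOO accuracy distribution sits near 0.5
        (with the well-known slight pessimistic bias)."""
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(30):
            X = rng.normal(size=(24, 3))
            y = np.array([-1, 1] * 12)
            accs.append(loo_cv(X, y)[0])
        assert 0.35 < np.mean(accs) < 0.6

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            loo_cv(np.zeros((3, 1)), np.array([-1, 1, 1]))


class TestAssembleFeatures:
    def test_csf_columns(self, default_cohort):
        F = assemble_features(default_cohort, "CSF")
        assert F.feature_names == list(CSF_MARKERS)
        assert F.matrix.shape == (218, 3)

    def test_volume_columns(self, default_cohort):
        F = assemble_features(default_cohort, "Hp_volumes")
        assert F.matrix.shape == (218, 2)
        F = assemble_features(default_cohort, "LV_volumes")
        assert F.feature_names == ["volume_ventricle_L", "volume_ventricle_R"]

    def test_zscored(self, default_cohort):
        F = assemble_features(default_cohort, "CSF")
        np.testing.assert_allclose(F.matrix.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(F.matrix.std(axis=0), 1.0, atol=1e-12)

    def test_shape_set_uses_selected_components(self, default_cohort, hippo_embedding):
        _, E = hippo_embedding
        labels = np.array([r.group for r in default_cohort])
        sel = select_components(E, labels, ("NC", "AD"))
        F = assemble_features(
            default_cohort, "Hp_shapes",
            embeddings={"hippocampus": E}, selections={"hippocampus": sel},
        )
        assert F.matrix.shape == (218, len(sel.selected))
        assert all(name.startswith("Hp_comp") for name in F.feature_names)

    def test_unknown_set_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            assemble_features(default_cohort, "PET")

    def test_known_sets_enumerated(self):
        assert set(FEATURE_SETS) == {
            "Hp_volumes", "Hp_shapes", "LV_volumes", "LV_shapes",
            "CSF", "CSF+volumes", "CSF+shapes",
        }


class TestBalancedEval:
    def test_target_size_is_smallest_group(self, default_cohort):
        labels = [r.group for r in default_cohort]
        assert balanced_target_size(labels) == 35

    def test_deterministic(self, default_cohort):
        labels = np.array([r.group for r in default_cohort])
        F = assemble_features(default_cohort, "CSF")
        a = balanced_subsample_eval(F, labels, ("NC", "AD"), n_trials=5, seed=3)
        b = balanced_subsample_eval(F, labels, ("NC", "AD"), n_trials=5, seed=3)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        assert a.mean_accuracy == b.mean_accuracy

    def test_report_invariants(self, default_cohort):
        labels = np.array([r.group for r in default_cohort])
        F = assemble_features(default_cohort, "CSF")
        rep = balanced_subsample_eval(F, labels, ("NC", "AD"), n_trials=10, seed=0)
        assert 0 <= rep.ci_low <= rep.mean_accuracy <= rep.ci_high <= 1
        assert 0 <= rep.sensitivity <= 1 and 0 <= rep.specificity <= 1
        # balanced trials: accuracy = (sens + spec) / 2 holds for the means
        assert rep.mean_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2, abs=1e-12
        )

    def test_strong_effect_high_accuracy(self):
        """Well-separated CSF distributions: accuracy >= 0.9, tight CI."""
        csf = {
            "NC": {"abeta42": (300.0, 30.0), "t_tau": (50.0, 10.0), "p_tau": (20.0, 5.0)},
            "MCI_s": {"abeta42": (200.0, 30.0), "t_tau": (90.0, 10.0), "p_tau": (35.0, 5.0)},
            "MCI_c": {"abeta42": (100.0, 30.0), "t_tau": (130.0, 10.0), "p_tau": (50.0, 5.0)},
            "AD": {"abeta42": (100.0, 30.0), "t_tau": (130.0, 10.0), "p_tau": (50.0, 5.0)},
        }
        cohort = generate_cohort(CohortSpec(seed=6, structures=(), csf_params=csf))
        labels = np.array([r.group for r in cohort])
        F = assemble_features(cohort, "CSF")
        rep = balanced_subsample_eval(F, labels, ("NC", "AD"), n_trials=100, seed=6)
        assert rep.mean_accuracy >= 0.9
        assert rep.ci_high - rep.ci_low < 0.05

    def test_ordering_invariance(self, default_cohort):
        labels = np.array([r.group for r in default_cohort])
        F = assemble_features(default_cohort, "CSF")
        perm = np.random.default_rng(9).permutation(len(labels))
        cohort_p = [default_cohort[i] for i in perm]
        F_p = assemble_features(cohort_p, "CSF")
        a = balanced_subsample_eval(F, labels, ("NC", "AD"), n_trials=5, seed=1)
        b = balanced_subsample_eval(F_p, labels[perm], ("NC", "AD"), n_trials=5, seed=1)
        assert abs(a.mean_accuracy - b.mean_accuracy) < 0.15  # same protocol, same scale

    def test_too_few_trials(self, default_cohort):
        labels = np.array([r.group for r in default_cohort])
        F = assemble_features(default_cohort, "CSF")
        with pytest.raises(ValueError):
            balanced_subsample_eval(F, labels, ("NC", "AD"), n_trials=1)


class TestCompareClassifiers:
    def test_identical_streams_degenerate(self):
        a = np.full(20, 0.7)
        res = compare_classifiers(a, a)
        assert res.degenerate
        assert res.p == 0.0

    def test_shifted_stream_significant(self):
        rng = np.random.default_rng(7)
        a = 0.6 + rng.normal(0, 0.01, size=50)
        b = a + 0.05 + rng.normal(0, 0.005, size=50)
        res = compare_classifiers(b, a)
        assert res.p < 0.001
        assert res.t > 0

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            a = rng.normal(0.6, 0.02, size=30)
            b = rng.normal(0.6, 0.02, size=30)
            ps.append(compare_classifiers(a, b).p)
        ps = np.array(ps)
        assert 0.01 < (ps < 0.05).mean() < 0.12
        assert abs(np.mean(ps) - 0.5) < 0.08


class TestCombinationGain:
    def test_csf_plus_shapes_beats_csf_alone(self):
        """Adding shape components to CSF markers improves (or matches)
        NC-vs-AD accuracy in a majority of cohort replicates."""
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            half = {"NC": 36, "MCI_s": 43, "MCI_c": 13, "AD": 18}
            spec = CohortSpec(seed=300 + seed, group_sizes=half)
            cohort = generate_cohort(spec)
            labels = np.array([r.group for r in cohort])
            ids = [r.id for r in cohort]
            embeddings = {}
            for key, (tl, tr) in (("hippocampus", ("hippocampus_L", "hippocampus_R")),
                                  ("ventricle", ("ventricle_L", "ventricle_R"))):
                D = combine_structures(
                    pairwise_distances([r.meshes[tl] for r in cohort], subject_ids=ids),
                    pairwise_distances([r.meshes[tr] for r in cohort], subject_ids=ids),
                )
                embeddings[key] = isomap(D, k=10, m=20)
            selections = {
                key: select_components(E, labels, ("NC", "AD"))
                for key, E in embeddings.items()
            }
            csf = assemble_features(cohort, "CSF")
            both = assemble_features(cohort, "CSF+shapes", embeddings, selections)
            r_csf = balanced_subsample_eval(csf, labels, ("NC", "AD"), n_trials=10, seed=seed)
            r_both = balanced_subsample_eval(both, labels, ("NC", "AD"), n_trials=10, seed=seed)
            wins += r_both.mean_accuracy >= r_csf.mean_accuracy - 1e-12
        assert wins > n_seeds / 2


def test_zscore_with_external_stats():
    rng = np.random.default_rng(10)
    train = rng.normal(5, 2, size=(30, 2))
    test = rng.normal(5, 2, size=(10, 2))
    z = zscore_columns(test, stats_from=train)
    expect = (test - train.mean(0)) / train.std(0)
    np.testing.assert_allclose(z, expect, rtol=1e-12)
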