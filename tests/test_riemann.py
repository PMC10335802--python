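import numpy as np
import pytest

from conftest import random_spd
from eegloop.errors import (
    FormatError,
    InvalidArgumentError,
    NumericalError,
    VersionError,
)
from eegloop.preprocess import Epoch, EpochSpec, epoch_timelocked
from eegloop.riemann import (
    CovSpec,
    MDMModel,
    ModelBundle,
    airm_distance,
    distance,
    epoch_covariance,
    load_model,
    logeuclid_distance,
    mdm_accuracy,
    mdm_fit,
    mdm_predict,
    model_digest,
    riemannian_mean,
    save_model,
    validate_spd,
)
from eegloop.synth import SynthConfig, make_mi_session

FS = 256.0


def epoch_of(data, label=None):
    return Epoch(0.0, data, label=label, meta={"fs": FS, "t_min": 0.0})


class TestEpochCovariance:
    def test_anticorrelated_channels_hand_computed(self, rng):
        """Rows [t, -t]: covariance [[1,-1],[-1,1]] (times var(t)); with
        shrinkage the smallest eigenvalue is bounded below."""
        t = rng.standard_normal(10_000)
        t = (t - t.mean()) / t.std(ddof=1)
        X = np.vstack([t, -t])
        C0 = epoch_covariance(epoch_of(X), CovSpec(shrinkage=0.0))
        # brute-force sum oracle
        expected = np.zeros((2, 2))
        Xc = X - X.mean(axis=1, keepdims=True)
        for i in range(2):
            for j in range(2):
                expected[i, j] = np.sum(Xc[i] * Xc[j]) / (X.shape[1] - 1)
        np.testing.assert_allclose(C0, expected, atol=1e-10)
        np.testing.assert_allclose(C0, [[1, -1], [-1, 1]], atol=1e-2)
        C = epoch_covariance(epoch_of(X), CovSpec(shrinkage=0.05))
        assert np.linalg.eigvalsh(C).min() >= 0.05 * np.trace(C0) / 2 * (1 - 1e-9)

    def test_lln_identity_recovery(self, rng):
        X = rng.standard_normal((2, 100_000))
        C = epoch_covariance(epoch_of(X), CovSpec(shrinkage=0.0))
        np.testing.assert_allclose(C, np.eye(2), atol=0.02)

    def test_shrinkage_limit(self, rng):
        X = rng.standard_normal((3, 500))
        C = epoch_covariance(epoch_of(X), CovSpec(shrinkage=0.999))
        emp = epoch_covariance(epoch_of(X), CovSpec(shrinkage=0.0))
        np.testing.assert_allclose(C, np.trace(emp) / 3 * np.eye(3), atol=0.02)

    def test_constant_epoch_singular_without_shrinkage(self):
        X = np.ones((2, 100))
        with pytest.raises(NumericalError):
            epoch_covariance(epoch_of(X), CovSpec(shrinkage=0.0))
        C = epoch_covariance(epoch_of(X), CovSpec(shrinkage=0.05))
        assert np.linalg.eigvalsh(C).min() > 0

    def test_shrinkage_range_enforced(self):
        with pytest.raises(InvalidArgumentError):
            CovSpec(shrinkage=1.0)


class TestAirmDistance:
    def test_identity_of_indiscernibles(self, rng):
        C = random_spd(rng, 4)
        assert airm_distance(C, C) == pytest.approx(0.0, abs=1e-7)

    def test_analytic_diagonal_case(self):
        """d(I, diag(e^2, 1)) = 2: log-eigenvalues are 2 and 0."""
        B = np.diag([np.e ** 2, 1.0])
        assert airm_distance(np.eye(2), B) == pytest.approx(2.0, abs=1e-10)

    def test_symmetry(self, rng):
        A, B = random_spd(rng, 3), random_spd(rng, 3)
        assert airm_distance(A, B) == pytest.approx(airm_distance(B, A), abs=1e-9)

    def test_congruence_invariance(self, rng):
        """d(WAW', WBW') == d(A, B) for random invertible W."""
        for _ in range(10):
            A, B = random_spd(rng, 4), random_spd(rng, 4)
            W = rng.standard_normal((4, 4)) + 4 * np.eye(4)
            lhs = airm_distance(W @ A @ W.T, W @ B @ W.T)
            assert lhs == pytest.approx(airm_distance(A, B), abs=1e-8)

    def test_metric_axioms_on_random_triples(self, rng):
        """Nonnegativity, symmetry, triangle inequality over 200 triples."""
        for _ in range(200):
            A, B, C = (random_spd(rng, 3) for _ in range(3))
            dab, dbc, dac = (airm_distance(A, B), airm_distance(B, C),
                             airm_distance(A, C))
            assert dab >= 0 and dbc >= 0 and dac >= 0
            assert dac <= dab + dbc + 1e-8

    def test_non_spd_rejected(self):
        with pytest.raises(InvalidArgumentError):
            airm_distance(np.diag([1.0, -1.0]), np.eye(2))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(InvalidArgumentError):
            airm_distance(random_spd(rng, 2), random_spd(rng, 3))

    def test_logeuclid_agrees_on_commuting_matrices(self, rng):
        A, B = np.diag([1.0, 4.0]), np.diag([2.0, 3.0])
        assert logeuclid_distance(A, B) == pytest.approx(airm_distance(A, B),
                                                         abs=1e-10)


class TestRiemannianMean:
    def test_singleton(self, rng):
        C = random_spd(rng, 3)
        np.testing.assert_allclose(riemannian_mean([C]), C)

    def test_commuting_case_geometric_mean(self):
        """mean(diag(1,4), diag(4,1)) = diag(2,2)."""
        M = riemannian_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        np.testing.assert_allclose(M, np.diag([2.0, 2.0]), atol=1e-7)

    def test_frechet_local_optimality(self, rng):
        """Sum of squared distances at the mean beats 1000 random
        perturbations (local-optimality probe)."""
        covs = [random_spd(rng, 3) for _ in range(20)]
        M = riemannian_mean(covs)
        crit = sum(airm_distance(M, C) ** 2 for C in covs)
        for _ in range(1000):
            D = rng.standard_normal((3, 3)) * 0.05
            P = M + (D + D.T) / 2
            if np.linalg.eigvalsh(P).min() <= 0:
                continue
            assert crit <= sum(airm_distance(P, C) ** 2 for C in covs) + 1e-9

    def test_logeuclid_mean_closed_form(self, rng):
        covs = [np.diag([1.0, 8.0]), np.diag([4.0, 2.0])]
        M = riemannian_mean(covs, metric="logeuclid")
        np.testing.assert_allclose(M, np.diag([2.0, 4.0]), atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            riemannian_mean([])


def mi_epochs(n_per_class, covs, seed, epoch_duration=2.0):
    config = SynthConfig(n_channels=covs[0].shape[0], seed=seed)
    session = make_mi_session(n_per_class, covs, config,
                              epoch_duration=epoch_duration)
    epochs, _ = epoch_timelocked(session.eeg, session.markers,
                                 EpochSpec(0.0, epoch_duration), fs=config.fs)
    return epochs


class TestMDM:
    def test_degenerate_fit_means_equal_covariances(self, rng):
        spec = CovSpec(shrinkage=0.0)
        ep_a = epoch_of(rng.standard_normal((3, 500)), label="a")
        ep_b = epoch_of(rng.standard_normal((3, 500)), label="b")
        model = mdm_fit([ep_a, ep_a, ep_b, ep_b], spec)
        np.testing.assert_allclose(model.means[0],
                                   epoch_covariance(ep_a, spec), atol=1e-9)
        np.testing.assert_allclose(model.means[1],
                                   epoch_covariance(ep_b, spec), atol=1e-9)

    def test_single_class_rejected(self, rng):
        eps = [epoch_of(rng.standard_normal((2, 100)), label="only")
               for _ in range(3)]
        with pytest.raises(InvalidArgumentError):
            mdm_fit(eps)

    def test_order_invariance(self, rng):
        eps = [epoch_of(rng.standard_normal((2, 300)), label=i % 2)
               for i in range(8)]
        m1 = mdm_fit(eps)
        m2 = mdm_fit(list(reversed(eps)))
        assert m1.class_ids == m2.class_ids
        for a, b in zip(m1.means, m2.means):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_parameter_recovery_on_synthetic_mi(self):
        """Recovered class means within AIRM distance 0.3 of the generating
        covariances (parameter-recovery oracle on synth truth)."""
        covs = [np.diag([4.0, 1.0, 1.0, 1.0]), np.diag([1.0, 4.0, 1.0, 1.0])]
        epochs = mi_epochs(50, covs, seed=13)
        model = mdm_fit(epochs, CovSpec(shrinkage=0.0))
        for mean, cov in zip(model.means, covs):
            assert airm_distance(mean, cov) <= 0.3

    def test_zero_distance_epoch_predicted_with_max_score(self, rng):
        eps = [epoch_of(rng.standard_normal((2, 400)), label=i % 2)
               for i in range(6)]
        model = mdm_fit(eps)
        pred, scores = mdm_predict(model, eps[0])
        assert scores[pred] == max(scores.values())

    def test_equidistant_tie_breaks_to_first_class(self, rng):
        X = rng.standard_normal((2, 1000))
        C = epoch_covariance(epoch_of(X))
        model = MDMModel(class_ids=["a", "b"], means=[C.copy(), C.copy()])
        pred, scores = mdm_predict(model, epoch_of(X))
        assert pred == "a"
        assert scores["a"] == pytest.approx(0.5, abs=1e-12)
        assert scores["b"] == pytest.approx(0.5, abs=1e-12)

    def test_scores_sum_to_one(self, rng):
        eps = [epoch_of(rng.standard_normal((3, 300)), label=i % 3)
               for i in range(9)]
        model = mdm_fit(eps)
        _, scores = mdm_predict(model, eps[4])
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        eps = [epoch_of(rng.standard_normal((2, 200)), label=i % 2)
               for i in range(4)]
        model = mdm_fit(eps)
        with pytest.raises(InvalidArgumentError):
            mdm_predict(model, epoch_of(rng.standard_normal((3, 200))))

    def test_held_out_accuracy_on_separable_classes(self):
        covs = [np.diag([4.0, 1.0, 1.0, 1.0]), np.diag([1.0, 4.0, 1.0, 1.0])]
        model = mdm_fit(mi_epochs(30, covs, seed=17))
        test = mi_epochs(30, covs, seed=18)
        assert mdm_accuracy(model, test) >= 0.9

    def test_null_classes_near_chance(self):
        covs = [np.eye(4), np.eye(4)]
        model = mdm_fit(mi_epochs(30, covs, seed=19))
        test = mi_epochs(30, covs, seed=20)
        acc = mdm_accuracy(model, test)
        # binomial noise around 0.5 at n=60: 3 sigma ~ 0.19
        assert abs(acc - 0.5) <= 0.2

    def test_accuracy_monotone_in_separation(self):
        """Held-out accuracy non-decreasing on a 3-point separation grid."""
        accs = []
        for ratio in (1.0, 2.0, 4.0):
            covs = [np.diag([ratio, 1.0, 1.0, 1.0]),
                    np.diag([1.0, ratio, 1.0, 1.0])]
            model = mdm_fit(mi_epochs(20, covs, seed=23))
            accs.append(mdm_accuracy(model, mi_epochs(20, covs, seed=24)))
        assert accs[0] <= accs[1] + 0.1 and accs[1] <= accs[2] + 0.05


class TestPersistence:
    def fitted_model(self, rng):
        eps = [epoch_of(rng.standard_normal((3, 400)), label=i % 2)
               for i in range(8)]
        return mdm_fit(eps), eps

    def test_round_trip_identical_predictions(self, rng, tmp_path):
        model, _ = self.fitted_model(rng)
        path = tmp_path / "model.npz"
        save_model(ModelBundle(model), path)
        loaded = load_model(path).model
        for _ in range(100):
            ep = epoch_of(rng.standard_normal((3, 100)))
            assert mdm_predict(model, ep) == mdm_predict(loaded, ep)

    def test_truncated_file_is_format_error(self, rng, tmp_path):
        model, _ = self.fitted_model(rng)
        path = tmp_path / "model.npz"
        save_model(ModelBundle(model), path)
        raw = path.read_bytes()
        path.write_bytes(raw[:len(raw) // 3])
        with pytest.raises(FormatError):
            load_model(path)

    def test_version_mismatch(self, rng, tmp_path):
        model, _ = self.fitted_model(rng)
        path = tmp_path / "model.npz"
        bundle = ModelBundle(model)
        bundle.format_version = "999"
        save_model(bundle, path)
        with pytest.raises(VersionError):
            load_model(path)

    def test_digest_changes_iff_parameters_change(self, rng):
        model, eps = self.fitted_model(rng)
        refit_same = mdm_fit(eps)
        assert model_digest(model) == model_digest(refit_same)
        refit_other = mdm_fit(eps, CovSpec(shrinkage=0.2))
        assert model_digest(model) != model_digest(refit_other)

    def test_sidecar_is_human_readable(self, rng, tmp_path):
        import json

        model, _ = self.fitted_model(rng)
        path = tmp_path / "model.npz"
        save_model(ModelBundle(model), path)
        meta = json.loads((tmp_path / "model.npz.json").read_text())
        assert meta["metric"] == "airm"
        assert meta["n_channels"] == 3


def test_validate_spd_rejects_asymmetry():
    M = np.array([[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(InvalidArgumentError):
        validate_spd(M)


def test_distance_dispatch():
    with pytest.raises(InvalidArgumentError):
        distance(np.eye(2), np.eye(2), metric="euclid")
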