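import itertools

import numpy as np
import pytest

from avfppg.ecoc_svm import (
    CodeMatrix,
    ECOCEnsemble,
    KernelSpec,
    ecoc_fit,
    ecoc_predict,
    ecoc_predict_batch,
    hamming_decode,
    kernel_eval,
    kernel_matrix,
    kkt_violation,
    svm_train,
)


class TestKernels:
    def test_quadratic_hand_value(self):
        assert kernel_eval(KernelSpec("quadratic", 1.0), [1.0, 0.0], [1.0, 1.0]) == 4.0

    def test_linear_dot_product(self):
        assert kernel_eval(KernelSpec("linear", None), [1.0, 2.0], [3.0, 4.0]) == 11.0

    def test_rbf_unit_at_equal_arguments(self):
        x = np.array([0.3, -1.2, 4.0])
        assert kernel_eval(KernelSpec("rbf", 2.5), x, x) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, z = rng.standard_normal(4), rng.standard_normal(4)
        for spec in (KernelSpec("linear", None), KernelSpec("quadratic", 1.0), KernelSpec("rbf", 0.7)):
            assert kernel_eval(spec, x, z) == pytest.approx(kernel_eval(spec, z, x))

    @pytest.mark.parametrize(
        "spec",
        [KernelSpec("linear", None), KernelSpec("quadratic", 1.0), KernelSpec("rbf", 0.5)],
    )
    def test_gram_positive_semidefinite(self, spec):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((25, 4))
        K = kernel_matrix(spec, X, X)
        eigs = np.linalg.eigvalsh(0.5 * (K + K.T))
        assert eigs.min() >= -1e-8

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec("linear", None), [1.0], [1.0, 2.0])

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            KernelSpec("cubic")
        with pytest.raises(ValueError):
            KernelSpec("rbf", -1.0)


class TestSvmTrain:
    def test_two_point_analytic_separator(self):
        """1-D points at -1/+1 give the midpoint decision boundary with
        equal margins."""
        X = np.array([[-1.0], [1.0]])
        y = [-1, 1]
        model = svm_train(X, y, KernelSpec("linear", None), C=10.0)
        assert model.decision_function(np.array([[-0.5]]))[0] < 0
        assert model.decision_function(np.array([[0.5]]))[0] > 0
        margins = model.decision_function(X) * y
        assert margins[0] == pytest.approx(margins[1], abs=1e-6)
        assert abs(model.decision_function(np.array([[0.0]]))[0]) < 1e-6

    def test_xor_with_quadratic_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([-1, -1, 1, 1])
        model = svm_train(X, y, KernelSpec("quadratic", 1.0), C=100.0)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_dual_feasibility_and_kkt(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(-1, 0.6, (20, 3)), rng.normal(1, 0.6, (20, 3))])
        y = np.array([-1.0] * 20 + [1.0] * 20)
        for spec in (KernelSpec("linear", None), KernelSpec("quadratic", 1.0), KernelSpec("rbf", 0.5)):
            model = svm_train(X, y, spec, C=5.0)
            assert np.all(model.alphas >= 0.0)
            assert np.all(model.alphas <= model.C + 1e-12)
            assert abs(np.sum(model.alphas * model.labels)) < 1e-6
            assert kkt_violation(model, X, y) < 1e-3 + 1e-6

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            svm_train(np.ones((3, 2)), [1, 1, 1])

    def test_invalid_c(self):
        with pytest.raises(ValueError):
            svm_train(np.array([[0.0], [1.0]]), [-1, 1], C=0.0)


class TestCodeMatrix:
    def test_default_codewords(self):
        cm = CodeMatrix()
        assert cm.rows == ((1, 1, 1), (0, 1, 0), (0, 0, 1))
        assert cm.n_classes == 3
        assert cm.code_length == 3
        assert cm.code_length <= 2 ** (cm.n_classes - 1) - 1

    def test_rejects_duplicate_codewords(self):
        with pytest.raises(ValueError):
            CodeMatrix(((1, 0, 0), (1, 0, 0), (0, 1, 0)))


class TestDecoding:
    def test_all_eight_codes_match_brute_force(self):
        """Hard Hamming decoding agrees with exhaustive enumeration."""
        cm = CodeMatrix()
        words = np.asarray(cm.rows)
        for bits in itertools.product((0, 1), repeat=3):
            d = hamming_decode(bits, cm)
            brute = np.array([sum(b != w for b, w in zip(bits, word)) for word in words])
            np.testing.assert_array_equal(d, brute)

    def test_known_distances(self):
        # (1,1,0): one bit from class 1's (1,1,1) and class 2's (0,1,0),
        # three bits from class 3's (0,0,1)
        np.testing.assert_array_equal(hamming_decode((1, 1, 0)), [1, 1, 3])
        np.testing.assert_array_equal(hamming_decode((1, 1, 1)), [0, 2, 2])
        # (0,0,0) ties classes 2 and 3 at distance 1
        np.testing.assert_array_equal(hamming_decode((0, 0, 0)), [3, 1, 1])


class TestEcocEnsemble:
    def _fit(self, blob_features):
        X, y = blob_features
        return ecoc_fit(X, y, KernelSpec("quadratic", 1.0), C=10.0), X, y

    def test_column_relabeling(self, blob_features):
        """Learner k's positive set is the classes whose bit k is 1."""
        ens, X, y = self._fit(blob_features)
        assert len(ens.models) == 3
        # column 1 separates class 1 from {2, 3}
        pred1 = ens.models[0].predict(X)
        np.testing.assert_array_equal(pred1, np.where(y == 1, 1, -1))
        # column 2 separates {1, 2} from {3}
        pred2 = ens.models[1].predict(X)
        np.testing.assert_array_equal(pred2, np.where(np.isin(y, (1, 2)), 1, -1))
        # column 3 separates {1, 3} from {2}
        pred3 = ens.models[2].predict(X)
        np.testing.assert_array_equal(pred3, np.where(np.isin(y, (1, 3)), 1, -1))

    def test_separable_training_accuracy_is_100(self, blob_features):
        ens, X, y = self._fit(blob_features)
        np.testing.assert_array_equal(ecoc_predict_batch(ens, X), y)

    def test_predict_returns_code_and_distances(self, blob_features):
        ens, X, y = self._fit(blob_features)
        cls, bits, dists = ecoc_predict(ens, X[0])
        assert cls == y[0]
        assert bits.shape == (3,)
        assert dists[cls - 1] == dists.min()

    def test_missing_class_raises(self, blob_features):
        X, y = blob_features
        mask = y != 2
        with pytest.raises(ValueError):
            ecoc_fit(X[mask], y[mask])

    def test_serialization_round_trip(self, tmp_path, blob_features):
        ens, X, y = self._fit(blob_features)
        path = tmp_path / "model.json"
        ens.save(path)
        back = ECOCEnsemble.load(path)
        np.testing.assert_array_equal(
            ecoc_predict_batch(back, X), ecoc_predict_batch(ens, X)
        )
        assert back.code.rows == ens.code.rows


class TestTieBreak:
    def test_all_zero_code_resolved_by_margin_weighting(self):
        """Output code (0,0,0) ties classes 2 and 3; the learner margins
        decide, then the lower class index."""

        class Stub:
            def __init__(self, margin):
                self.margin = margin

            def decision_function(self, X):
                return np.array([self.margin])

        cm = CodeMatrix()
        # margins all negative -> bits (0,0,0); |m| = (0.1, 0.9, 0.2)
        # cost(class2) = mismatch at bit f2 -> 0.9; cost(class3) = bit f3 -> 0.2
        ens = ECOCEnsemble(code=cm, models=[Stub(-0.1), Stub(-0.9), Stub(-0.2)])
        cls, bits, dists = ecoc_predict(ens, np.zeros(4))
        np.testing.assert_array_equal(bits, [0, 0, 0])
        assert cls == 3
        # symmetric margins -> cost tie -> lowest class index wins
        ens2 = ECOCEnsemble(code=cm, models=[Stub(-0.5), Stub(-0.3), Stub(-0.3)])
        assert ecoc_predict(ens2, np.zeros(4))[0] == 2
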