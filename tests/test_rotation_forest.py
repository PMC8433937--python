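"""Rotation Forest mechanics: rotations, reductions, averaging, recovery."""

import numpy as np
import pytest

import dtcwt_dti as dd
from dtcwt_dti.rotation_forest import RotationSpec, _pca_basis
from sklearn.tree import DecisionTreeClassifier


def _blobs(n=60, sep=10.0, seed=0, dims=2):
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n // 2, dims))
    X1 = rng.standard_normal((n // 2, dims)) + sep
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
    return X, y


# ---------------------------------------------------------------------------
# rotation structure
# ---------------------------------------------------------------------------

def test_rotation_matrices_orthonormal_and_isometric(planted_subset, small_rof_config):
    X, y = planted_subset(120)
    model = dd.RotationForestClassifier(small_rof_config).fit(X, y)
    rng = np.random.default_rng(0)
    rows = X[rng.choice(len(X), 10, replace=False)]
    for spec, _ in model.members_:
        R = spec.rotation_matrix()
        assert np.abs(R @ R.T - np.eye(R.shape[0])).max() < 1e-8
        # orthonormal blocks individually
        for B in spec.blocks:
            assert np.abs(B @ B.T - np.eye(B.shape[0])).max() < 1e-8
        # rotation preserves pairwise distances
        d0 = np.linalg.norm(rows[:, None] - rows[None, :], axis=-1)
        rot = rows @ R
        d1 = np.linalg.norm(rot[:, None] - rot[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-8)
        # apply() agrees with the assembled matrix
        np.testing.assert_allclose(spec.apply(rows), rows @ R, atol=1e-10)


def test_k1_l1_reduces_to_tree_on_full_pca_rotation():
    """With one subset, one tree, all classes and the full sample, the
    member rotation is exactly full-data PCA and the predictions match a
    single tree on the PCA-rotated data."""
    rng = np.random.default_rng(4)
    X = rng.standard_normal((80, 6)) @ rng.standard_normal((6, 6))
    y = (X[:, 0] + 0.2 * rng.standard_normal(80) > 0).astype(int)
    cfg = dd.RoFConfig(n_subsets=1, n_trees=1, class_subset_prob=1.0,
                       bootstrap_frac=1.0, seed=3)
    model = dd.RotationForestClassifier(cfg).fit(X, y)
    spec, fitted_tree = model.members_[0]
    R = spec.rotation_matrix()
    V = _pca_basis(X)          # full-data PCA loadings
    # equality up to per-component sign
    overlap = R.T @ V
    np.testing.assert_allclose(np.abs(np.diag(overlap)), 1.0, atol=1e-8)
    np.testing.assert_allclose(np.abs(overlap) - np.diag(np.diag(np.abs(overlap))),
                               0.0, atol=1e-8)
    direct = DecisionTreeClassifier(
        criterion="gini", random_state=fitted_tree.random_state
    ).fit(X @ R, y)
    np.testing.assert_array_equal(model.predict(X), direct.predict(X @ R))


def test_rank_deficient_subset_still_orthonormal():
    """Constant/duplicate columns (common for sparse fingerprint bits)
    must not break the block construction."""
    rng = np.random.default_rng(0)
    X = np.zeros((40, 10))
    X[:, 0] = rng.standard_normal(40)
    X[:, 1] = X[:, 0]                      # duplicate
    y = (X[:, 0] > 0).astype(int)
    model = dd.RotationForestClassifier(
        dd.RoFConfig(n_subsets=2, n_trees=2, seed=0)).fit(X, y)
    for spec, _ in model.members_:
        R = spec.rotation_matrix()
        assert np.abs(R @ R.T - np.eye(10)).max() < 1e-8


# ---------------------------------------------------------------------------
# prediction semantics
# ---------------------------------------------------------------------------

def test_probabilities_sum_to_one(planted_subset, small_rof_config):
    X, y = planted_subset(80)
    model = dd.RotationForestClassifier(small_rof_config).fit(X, y)
    proba = model.predict_proba(X[:20])
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)


def test_confidence_averaging_over_stub_trees():
    """Ensemble confidence is the arithmetic mean of member confidences."""
    class StubTree:
        def __init__(self, proba):
            self.proba = np.asarray(proba)
            self.classes_ = np.array([0, 1])

        def predict_proba(self, X):
            return np.tile(self.proba, (len(X), 1))

    F = 4
    identity = RotationSpec(permutation=np.arange(F), block_sizes=[F],
                            blocks=[np.eye(F)])
    model = dd.RotationForestClassifier(dd.RoFConfig(n_subsets=1, n_trees=3))
    model.classes_ = np.array([0, 1])
    model.n_features_ = F
    model.members_ = [(identity, StubTree(p))
                      for p in [(0.9, 0.1), (0.6, 0.4), (0.3, 0.7)]]
    proba = model.predict_proba(np.zeros((2, F)))
    np.testing.assert_allclose(proba, [[0.6, 0.4], [0.6, 0.4]], atol=1e-12)
    # argmax with the documented tie rule (ties -> first class)
    model.members_ = [(identity, StubTree((0.5, 0.5)))]
    assert model.predict(np.zeros((1, F)))[0] == 0
    model.members_ = [(identity, StubTree((0.4, 0.6)))]
    assert model.predict(np.zeros((1, F)))[0] == 1


def test_single_tree_ensemble_equals_that_tree(planted_subset):
    X, y = planted_subset(100)
    model = dd.RotationForestClassifier(
        dd.RoFConfig(n_subsets=4, n_trees=1, seed=2)).fit(X, y)
    spec, tree = model.members_[0]
    np.testing.assert_allclose(model.predict_proba(X),
                               tree.predict_proba(spec.apply(X)), atol=1e-12)


def test_separable_blobs_reach_perfect_training_accuracy():
    X, y = _blobs(sep=10.0)
    model = dd.RotationForestClassifier(
        dd.RoFConfig(n_subsets=2, n_trees=5, seed=1)).fit(X, y)
    assert (model.predict(X) == y).mean() == 1.0


def test_fit_is_deterministic(planted_subset, small_rof_config):
    X, y = planted_subset(150)
    m1 = dd.RotationForestClassifier(small_rof_config).fit(X, y)
    m2 = dd.RotationForestClassifier(small_rof_config).fit(X, y)
    for (s1, _), (s2, _) in zip(m1.members_, m2.members_):
        np.testing.assert_array_equal(s1.permutation, s2.permutation)
        np.testing.assert_array_equal(s1.rotation_matrix(), s2.rotation_matrix())
    np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def test_single_class_labels_rejected():
    X = np.zeros((10, 4))
    with pytest.raises(ValueError, match="single class"):
        dd.RotationForestClassifier(dd.RoFConfig(n_subsets=2, n_trees=1)).fit(
            X, np.zeros(10, dtype=int))


def test_k_larger_than_features_rejected():
    X, y = _blobs(dims=3)
    with pytest.raises(ValueError, match="exceeds feature count"):
        dd.RotationForestClassifier(dd.RoFConfig(n_subsets=5, n_trees=1)).fit(X, y)


def test_dimension_mismatch_at_predict(planted_subset, small_rof_config):
    model = dd.RotationForestClassifier(small_rof_config).fit(*planted_subset(50))
    with pytest.raises(ValueError, match="features"):
        model.predict(np.zeros((3, 10)))


# ---------------------------------------------------------------------------
# signal recovery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def split_world(planted_dataset):
    rng = np.random.default_rng(13)
    n = len(planted_dataset)
    idx = rng.permutation(n)
    cut = int(0.75 * n)
    return (planted_dataset.X[idx[:cut]], planted_dataset.y[idx[:cut]],
            planted_dataset.X[idx[cut:]], planted_dataset.y[idx[cut:]])


def test_planted_signal_recovery_auc(split_world):
    Xtr, ytr, Xte, yte = split_world
    model = dd.RotationForestClassifier(
        dd.RoFConfig(n_subsets=5, n_trees=17, seed=7)).fit(Xtr, ytr)
    auc, _ = dd.roc_auc(model.decision_scores(Xte), yte)
    assert auc > 0.90


def test_label_permutation_destroys_signal(split_world):
    Xtr, ytr, Xte, yte = split_world
    rng = np.random.default_rng(3)
    model = dd.RotationForestClassifier(
        dd.RoFConfig(n_subsets=5, n_trees=17, seed=7)).fit(
            Xtr, rng.permutation(ytr))
    auc, _ = dd.roc_auc(model.decision_scores(Xte), yte)
    assert abs(auc - 0.5) <= 0.08


def test_more_trees_never_hurt_on_average(split_world):
    """Mean test AUC with L=17 must not trail L=1 by more than noise."""
    Xtr, ytr, Xte, yte = split_world
    aucs = {1: [], 17: []}
    for seed in range(10):
        for L in (1, 17):
            model = dd.RotationForestClassifier(
                dd.RoFConfig(n_subsets=5, n_trees=L, seed=seed)).fit(Xtr, ytr)
            auc, _ = dd.roc_auc(model.decision_scores(Xte), yte)
            aucs[L].append(auc)
    assert np.mean(aucs[17]) >= np.mean(aucs[1]) - 0.02


def test_save_load_round_trip(tmp_path, planted_subset, small_rof_config):
    X, y = planted_subset(80)
    model = dd.RotationForestClassifier(small_rof_config).fit(X, y)
    path = tmp_path / "model.rof"
    model.save(path)
    loaded = dd.RotationForestClassifier.load(path)
    np.testing.assert_array_equal(model.predict_proba(X), loaded.predict_proba(X))
    assert loaded.config == small_rof_config
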