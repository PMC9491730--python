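"""Two-stage decorrelation: correlation handling, greedy replay, PCA stage."""

import numpy as np
import pytest

from crossgc.atd import (
    ATD,
    correlation_matrix,
    fit_atd,
    stage1_decorrelate,
    stage2_pca,
    transform_atd,
)
from crossgc.evaluate import AccuracyEvaluator


@pytest.fixture
def evaluator():
    return AccuracyEvaluator(n_folds=2, seed=0)


def two_class_labels(n):
    return np.array((["a", "b"] * ((n + 1) // 2))[:n])


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        X = rng.standard_normal((20, 4))
        cm = correlation_matrix(X)
        np.testing.assert_allclose(np.diag(cm.r), 1.0)

    def test_hand_computed_pair(self):
        X = np.column_stack([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]])
        cm = correlation_matrix(X)
        # r = 3 / sqrt(2 * 42/9) = 0.981981...
        assert abs(cm.r[0, 1] - 0.9819805060619657) < 1e-12

    def test_sign_reversal(self, rng):
        a = rng.standard_normal(30)
        cm = correlation_matrix(np.column_stack([a, -a]))
        assert abs(cm.r[0, 1] + 1.0) < 1e-12

    def test_constant_column_flagged_not_fatal(self, rng):
        X = np.column_stack([rng.standard_normal(10), np.full(10, 3.0)])
        cm = correlation_matrix(X, feature_ids=["a", "b"])
        assert cm.constant_columns == ["b"]
        assert cm.r[0, 1] == 0.0 and cm.r[1, 1] == 1.0

    def test_symmetric_and_bounded(self, rng):
        X = rng.standard_normal((15, 6))
        cm = correlation_matrix(X)
        np.testing.assert_allclose(cm.r, cm.r.T)
        assert np.all(np.abs(cm.r) <= 1.0)


def replay_stage1(X, rule="first"):
    """Independent re-implementation of the greedy deletion path."""
    M = X.shape[1]
    r = np.abs(np.corrcoef(X, rowvar=False))
    alive = list(range(M))
    order = []
    while len(alive) > 1:
        best = None
        for bi, v in enumerate(alive):
            for bj in range(bi):
                u = alive[bj]
                cand = (r[v, u], -v, -u)
                if best is None or cand > best[0]:
                    best = (cand, u, v)
        _, u, v = best
        d = u if rule == "first" else v
        order.append(d)
        alive.remove(d)
    return order


class TestStage1:
    def test_duplicate_column_removed_first(self, evaluator, rng):
        base = rng.standard_normal((24, 5))
        X = np.column_stack([base, base[:, 2]])  # exact duplicate of col 2
        res = stage1_decorrelate(X, two_class_labels(24), evaluator)
        assert res.deletion_order[0] == 2  # "first" member of the |r|=1 pair

    def test_greedy_path_matches_independent_replay(self, evaluator, rng):
        X = rng.standard_normal((30, 6))
        X[:, 3] = 0.9 * X[:, 0] + 0.1 * rng.standard_normal(30)
        X[:, 5] = -0.8 * X[:, 1] + 0.2 * rng.standard_normal(30)
        y = two_class_labels(30)
        res = stage1_decorrelate(X, y, evaluator)
        assert res.deletion_order == replay_stage1(X)
        # returned m is the argmax of the stored curve, ties to fewest
        best = max(res.curve_accuracy)
        expect_m = min(s for s, a in zip(res.curve_sizes, res.curve_accuracy)
                       if a == best)
        assert res.m == expect_m
        assert len(res.selected) == res.m
        assert res.selected == sorted(res.selected)

    def test_orthogonal_informative_features_all_kept(self, evaluator, rng):
        # two independent binary factors jointly define a 4-class label:
        # dropping either destroys separability, so the curve peaks at M
        f1 = rng.integers(0, 2, 60).astype(float)
        f2 = rng.integers(0, 2, 60).astype(float)
        X = np.column_stack([f1 + 0.01 * rng.standard_normal(60),
                             f2 + 0.01 * rng.standard_normal(60)])
        y = (2 * f1 + f2).astype(int)
        res = stage1_decorrelate(X, y, evaluator)
        accs = dict(zip(res.curve_sizes, res.curve_accuracy))
        assert accs[2] > accs[1]
        assert res.m == 2

    def test_curve_stride_still_finds_peak_region(self, evaluator, rng):
        X = rng.standard_normal((40, 9))
        y = two_class_labels(40)
        full = stage1_decorrelate(X, y, evaluator, curve_stride=1)
        strided = stage1_decorrelate(X, y, evaluator, curve_stride=4)
        # refinement around the strided best evaluates its neighbourhood
        assert strided.deletion_order == full.deletion_order
        assert set(strided.curve_sizes) <= set(full.curve_sizes)


class TestStage2:
    def test_rank_deficient_eigenvalues_vanish(self, evaluator, rng):
        latent = rng.standard_normal((40, 2))
        mix = rng.standard_normal((2, 5))
        X = latent @ mix
        res = stage2_pca(X, two_class_labels(40), evaluator)
        assert np.all(res.eigenvalues[2:] < 1e-10 * res.eigenvalues[0])

    def test_total_variance_conserved(self, evaluator, rng):
        X = rng.standard_normal((30, 4))
        res = stage2_pca(X, two_class_labels(30), evaluator)
        S = np.cov(X, rowvar=False)
        assert abs(res.eigenvalues.sum() - np.trace(S)) < 1e-10

    def test_eigenvalues_match_characteristic_polynomial(self, evaluator):
        # independent eigen oracle for a hand-sized covariance
        rng = np.random.default_rng(7)
        X = rng.standard_normal((25, 3))
        res = stage2_pca(X, two_class_labels(25), evaluator)
        S = np.cov(X, rowvar=False)
        a = -np.trace(S)
        b = 0.5 * (np.trace(S) ** 2 - np.trace(S @ S))
        c = -np.linalg.det(S)
        roots = np.sort(np.roots([1.0, a, b, c]).real)[::-1]
        np.testing.assert_allclose(res.eigenvalues, roots, atol=1e-8)

    def test_basis_is_orthonormal(self, evaluator, rng):
        X = rng.standard_normal((30, 6))
        res = stage2_pca(X, two_class_labels(30), evaluator)
        np.testing.assert_allclose(res.basis.T @ res.basis, np.eye(6),
                                   atol=1e-8)

    def test_k_is_curve_argmax(self, evaluator, rng):
        X = rng.standard_normal((30, 5))
        res = stage2_pca(X, two_class_labels(30), evaluator)
        best = max(res.curve_accuracy)
        assert res.k == min(p for p, a in zip(res.curve_ranks,
                                              res.curve_accuracy) if a == best)


class TestATDModel:
    def test_training_projection_has_zero_mean(self, evaluator, rng):
        X = rng.standard_normal((40, 8))
        y = two_class_labels(40)
        model = ATD(evaluator).fit(X, y)
        Z = model.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        assert Z.shape == (40, model.k_)

    def test_single_sample_transform_shape(self, evaluator, rng):
        X = rng.standard_normal((40, 8))
        model = ATD(evaluator).fit(X, two_class_labels(40))
        z = model.transform(X[0])
        assert z.shape == (1, model.k_)

    def test_dimension_never_grows(self, evaluator, rng):
        X = rng.standard_normal((30, 7))
        model = ATD(evaluator).fit(X, two_class_labels(30))
        assert model.k_ <= model.m_ <= 7

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((36, 6))
        y = two_class_labels(36)
        a = ATD(AccuracyEvaluator(n_folds=3, seed=11)).fit(X, y)
        b = ATD(AccuracyEvaluator(n_folds=3, seed=11)).fit(X, y)
        assert a.to_dict() == b.to_dict()

    def test_serialization_round_trip_exact(self, evaluator, rng, tmp_path):
        import pandas as pd

        X = pd.DataFrame(rng.standard_normal((30, 5)),
                         columns=[f"c{i}" for i in range(5)])
        y = two_class_labels(30)
        model = fit_atd(X, y, evaluator)
        path = tmp_path / "atd.json"
        model.save(path)
        back = ATD.load(path)
        assert back.to_dict() == model.to_dict()
        np.testing.assert_array_equal(transform_atd(back, X),
                                      transform_atd(model, X))

    def test_feature_id_mismatch_errors(self, evaluator, rng):
        import pandas as pd

        X = pd.DataFrame(rng.standard_normal((30, 5)),
                         columns=[f"c{i}" for i in range(5)])
        model = ATD(evaluator).fit(X, two_class_labels(30))
        bad = X.rename(columns={model.selected_ids_[0]: "zzz"})
        with pytest.raises(ValueError, match="lacks fitted feature ids"):
            model.transform(bad)

    def test_redundant_copies_are_compressed(self, rng):
        # 5 informative columns plus 55 noisy duplicates of them: the fitted
        # selector must land near the informative dimensionality without
        # losing accuracy relative to the known-informative subset
        n = 120
        informative = rng.standard_normal((n, 5))
        y = (informative[:, :2].sum(axis=1) > 0).astype(int)
        dup = informative[:, rng.integers(0, 5, 55)] + \
            0.05 * rng.standard_normal((n, 55))
        X = np.column_stack([informative, dup])
        evaluator = AccuracyEvaluator(n_folds=3, seed=2)
        model = ATD(evaluator).fit(X, y)
        assert model.k_ <= 20
        acc_model = evaluator.evaluate(model.transform(X), y)
        acc_oracle = evaluator.evaluate(informative, y)
        assert acc_model >= acc_oracle - 0.02


class TestDeletionRules:
    @pytest.fixture
    def redundant_pair(self, rng):
        # columns 1 and 3 are the dominant correlated pair
        X = rng.standard_normal((30, 5))
        X[:, 3] = 0.98 * X[:, 1] + 0.02 * rng.standard_normal(30)
        return X

    def test_first_and_second_rules_pick_opposite_members(self, evaluator,
                                                          redundant_pair):
        y = two_class_labels(30)
        first = stage1_decorrelate(redundant_pair, y, evaluator, rule="first")
        second = stage1_decorrelate(redundant_pair, y, evaluator, rule="second")
        assert first.deletion_order[0] == 1
        assert second.deletion_order[0] == 3

    def test_random_rule_is_seed_deterministic(self, redundant_pair):
        y = two_class_labels(30)
        ev = AccuracyEvaluator(n_folds=2, seed=9)
        a = stage1_decorrelate(redundant_pair, y, ev, rule="random")
        b = stage1_decorrelate(redundant_pair, y, ev, rule="random")
        assert a.deletion_order == b.deletion_order
        assert a.deletion_order[0] in (1, 3)

    def test_most_correlated_rule_prefers_hub_feature(self, evaluator, rng):
        # column 0 correlates with the pair member 1 and with column 2,
        # so when (0, 1) is the top pair, 0 is the more redundant member
        n = 200
        base = rng.standard_normal(n)
        X = np.column_stack([
            base + 0.10 * rng.standard_normal(n),
            base + 0.12 * rng.standard_normal(n),
            base + 0.50 * rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        y = two_class_labels(n)
        res = stage1_decorrelate(X, y, evaluator, rule="most_correlated")
        assert res.deletion_order[0] in (0, 1)

    def test_unknown_rule_rejected(self, evaluator, redundant_pair):
        with pytest.raises(ValueError, match="unknown deletion rule"):
            stage1_decorrelate(redundant_pair, two_class_labels(30),
                               evaluator, rule="best")


def test_assemble_rejects_inconsistent_window_lengths():
    from crossgc.measures import assemble_feature_table
    from crossgc.preprocess import split_hemispheres
    from crossgc.synthetic import SynthConfig, generate_recording

    a = generate_recording(SynthConfig(trial_duration_s=3.0, seed=1), "HAHV",
                           0, return_components=True)[1]
    b = generate_recording(SynthConfig(trial_duration_s=4.5, seed=1), "LALV",
                           1, return_components=True)[1]
    part = split_hemispheres(a.channel_names)
    with pytest.raises(ValueError, match="inconsistent window lengths"):
        assemble_feature_table([(a, "HAHV"), (b, "LALV")], part)
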