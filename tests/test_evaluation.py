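"""Ranking metrics, fold construction, cross-validation, top-n counting."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from tensordr import (
    AssociationMatrix,
    SolverConfig,
    cross_validate,
    generate_dataset,
    grid_search,
    make_folds,
    rank_metrics,
    topn_validated,
)
from tensordr.evaluation import mann_whitney_auc


def exhaustive_auc(scores, labels):
    """Pair-counting AUC oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum(1.0 for p, n in itertools.product(pos, neg) if p > n)
    ties = sum(1.0 for p, n in itertools.product(pos, neg) if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestFolds:
    def _assoc(self, n_pos=20, shape=(8, 10), seed=0):
        rng = np.random.default_rng(seed)
        values = np.zeros(shape)
        pos = rng.choice(shape[0] * shape[1], size=n_pos, replace=False)
        values.flat[pos] = 1.0
        return AssociationMatrix(
            values,
            tuple(f"d{i}" for i in range(shape[0])),
            tuple(f"r{j}" for j in range(shape[1])),
        )

    def test_equal_fold_sizes(self):
        a = self._assoc(n_pos=20)
        plans = make_folds(a, n_folds=10, n_repeats=1, seed=1)
        assert [len(f) for f in plans[0].folds] == [2] * 10

    def test_near_equal_fold_sizes(self):
        a = self._assoc(n_pos=23)
        plans = make_folds(a, n_folds=10, n_repeats=1, seed=1)
        sizes = [len(f) for f in plans[0].folds]
        assert sum(sizes) == 23 and max(sizes) - min(sizes) <= 1

    def test_partition_property(self):
        a = self._assoc(n_pos=20)
        plan = make_folds(a, n_folds=10, n_repeats=1, seed=2)[0]
        cells = [c for fold in plan.folds for c in fold]
        assert len(cells) == len(set(cells)) == 20
        assert set(cells) == {tuple(c) for c in np.argwhere(a.values == 1)}

    def test_seed_reproducibility(self):
        a = self._assoc(n_pos=20)
        p1 = make_folds(a, n_folds=5, n_repeats=3, seed=42)
        p2 = make_folds(a, n_folds=5, n_repeats=3, seed=42)
        assert p1 == p2

    def test_too_few_positives_rejected(self):
        a = self._assoc(n_pos=5)
        with pytest.raises(ValueError, match="positives"):
            make_folds(a, n_folds=10)


class TestRankMetrics:
    def test_perfect_ranking(self):
        scores = np.array([[0.9, 0.8], [0.2, 0.1]])
        metrics = rank_metrics(scores, test_pos={(0, 0), (0, 1)}, train_pos=set())
        assert metrics["auc"] == 1.0
        assert metrics["aupr"] == 1.0
        assert metrics["precision"] == 1.0

    def test_enumerated_four_candidate_ranking(self):
        # positives at ranks 1 and 3 of (0.9, 0.8, 0.2, 0.1)
        scores = np.array([[0.9, 0.8, 0.2, 0.1]])
        test_pos = {(0, 0), (0, 2)}
        metrics = rank_metrics(scores, test_pos, train_pos=set())
        assert metrics["auc"] == pytest.approx(0.75)
        assert metrics["precision"] == pytest.approx(0.5)
        # explicit step sum: AP = mean of precision at each positive hit
        assert metrics["aupr"] == pytest.approx((1.0 / 1 + 2.0 / 3) / 2)

    def test_train_positives_excluded_from_candidates(self):
        scores = np.array([[0.99, 0.8, 0.2, 0.1]])
        metrics = rank_metrics(scores, {(0, 1)}, {(0, 0)})
        assert metrics["auc"] == 1.0  # the 0.99 training cell is not ranked

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(1000):
            scores = rng.random((5, 8)).round(2)  # ties included
            labels = np.zeros((5, 8), dtype=bool)
            pos = rng.choice(40, size=6, replace=False)
            labels.flat[pos] = True
            aucs.append(
                mann_whitney_auc(scores.ravel(), labels.ravel())
            )
        assert abs(np.mean(aucs) - 0.5) <= 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_matches_pair_counting_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40).round(1)  # coarse scores force ties
        labels = rng.random(40) < 0.3
        if not labels.any() or labels.all():
            labels[:2] = [True, False]
        got = mann_whitney_auc(scores, labels)
        assert got == pytest.approx(exhaustive_auc(scores, labels))
        assert got == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.random((4, 6))
        test_pos = {(0, 0), (2, 3), (3, 5)}
        m1 = rank_metrics(scores, test_pos, set())
        m2 = rank_metrics(np.exp(5 * scores), test_pos, set())
        for key in ("auc", "aupr", "precision"):
            assert m1[key] == pytest.approx(m2[key])

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_metrics(np.zeros((2, 2)), set(), set())


@pytest.fixture(scope="module")
def tiny():
    return generate_dataset(n=14, m=20, rank=3, density=0.06, noise=0.05, seed=5)


class TestCrossValidate:

    def test_planted_structure_recovered(self, tiny):
        folds = make_folds(tiny.A, n_folds=4, n_repeats=1, seed=1)
        rep = cross_validate(
            tiny.A, list(tiny.drug_sims), list(tiny.disease_sims), folds,
            k=5, solver_config=SolverConfig(max_iter=250),
        )
        assert rep.auc >= 0.80
        assert len(rep.per_fold) == 4

    def test_training_matrix_as_predictor_is_uninformative(self, tiny):
        # leak control: held-out positives are 0 in the training matrix,
        # so ranking by the training matrix itself cannot find them
        folds = make_folds(tiny.A, n_folds=4, n_repeats=1, seed=1)
        aucs = []
        for fold in folds[0].folds:
            train = tiny.A.values.copy()
            for i, j in fold:
                train[i, j] = 0.0
            train_pos = {tuple(c) for c in np.argwhere(train == 1)}
            aucs.append(rank_metrics(train, set(fold), train_pos)["auc"])
        # all held-out positives tie with the zero background at midrank
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_deterministic_given_seed(self, tiny):
        folds = make_folds(tiny.A, n_folds=3, n_repeats=1, seed=9)
        kw = dict(k=4, solver_config=SolverConfig(max_iter=120))
        r1 = cross_validate(tiny.A, list(tiny.drug_sims),
                            list(tiny.disease_sims), folds, **kw)
        r2 = cross_validate(tiny.A, list(tiny.drug_sims),
                            list(tiny.disease_sims), folds, **kw)
        assert r1.per_fold == r2.per_fold


class TestGridSearch:
    def test_single_cell_grid(self):
        ds = generate_dataset(n=10, m=14, rank=2, density=0.08, noise=0.05, seed=3)
        folds = make_folds(ds.A, n_folds=2, n_repeats=1, seed=1)
        cfg = SolverConfig(max_iter=120)
        table, best = grid_search(
            ds.A, list(ds.drug_sims), list(ds.disease_sims), folds,
            k_grid=[3], p_grid=[0.9], solver_config=cfg,
        )
        assert len(table) == 1
        assert best["k"] == 3 and best["p"] == 0.9
        # the reported cell equals an independent cross_validate run
        rep = cross_validate(
            ds.A, list(ds.drug_sims), list(ds.disease_sims), folds,
            k=3, solver_config=cfg.with_(p=0.9),
        )
        assert best["auc_plus_aupr"] == pytest.approx(rep.auc + rep.aupr)

    def test_argmax_unchanged_by_dominated_cell(self):
        table = [
            {"k": 1, "p": 0.9, "auc_plus_aupr": 1.2},
            {"k": 2, "p": 0.9, "auc_plus_aupr": 0.8},
        ]
        best = max(table, key=lambda r: r["auc_plus_aupr"])
        assert best["k"] == 1


class TestTopN:
    def test_empty_reference(self):
        counts = topn_validated(np.random.default_rng(0).random((4, 3)),
                                train_pos=set(), reference_pos=set())
        assert all(v == 0 for v in counts.values())

    def test_hand_ranked_toy(self):
        # drug 0 ranks diseases (0.9, 0.5, 0.4, 0.1); reference hit at rank 3
        scores = np.array([[0.9, 0.3], [0.5, 0.2], [0.4, 0.8], [0.1, 0.6]])
        counts = topn_validated(scores, train_pos=set(),
                                reference_pos={(2, 0)}, n_values=(1, 2, 3, 5))
        assert counts[1] == 0 and counts[2] == 0
        assert counts[3] == 1 and counts[5] == 1

    def test_counts_non_decreasing_and_training_excluded(self):
        rng = np.random.default_rng(2)
        scores = rng.random((10, 6))
        train = {(0, 0), (1, 1)}
        ref = {(2, 0), (3, 1), (4, 2)}
        counts = topn_validated(scores, train, ref, n_values=(1, 3, 5, 10))
        vals = [counts[n] for n in (1, 3, 5, 10)]
        assert vals == sorted(vals)
        assert counts[10] == 3
        with pytest.raises(ValueError, match="training"):
            topn_validated(scores, train, {(0, 0)})
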