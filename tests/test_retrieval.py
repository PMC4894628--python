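"""Cross-validation splitting, ranking, and retrieval metrics."""

import numpy as np
import pytest

from oracles import average_precision_brute
from tumorcbir import (
    Cohort,
    TumorCase,
    average_precision,
    evaluate_encoded,
    patient_cv_split,
    prec_at_n,
    rank_database,
)
from tumorcbir.pipeline import fit_feature_models


def _tiny_cohort(n_patients=10, slices=2):
    cases = []
    img = np.zeros((8, 8))
    mask = np.zeros((8, 8), bool)
    mask[3:5, 3:5] = True
    for p in range(n_patients):
        for _ in range(slices):
            cases.append(
                TumorCase(image=img, tumor_mask=mask, label=p % 2 + 1,
                          patient_id=f"P{p}")
            )
    return Cohort(cases=cases)


class TestPatientSplit:
    def test_round_robin_balance(self):
        split = patient_cv_split(_tiny_cohort(10), folds=5, seed=0)
        counts = np.bincount(list(split.assignments.values()), minlength=5)
        assert counts.tolist() == [2, 2, 2, 2, 2]

    def test_patients_never_span_folds(self):
        cohort = _tiny_cohort(9, slices=3)
        split = patient_cv_split(cohort, folds=4, seed=1)
        for fold in range(4):
            idx = split.fold_indices(cohort, fold)
            test_pids = {cohort.cases[i].patient_id for i in idx}
            rest = {c.patient_id for j, c in enumerate(cohort) if j not in set(idx)}
            assert not test_pids & rest

    def test_same_seed_same_split(self):
        c = _tiny_cohort(12)
        s1 = patient_cv_split(c, 5, seed=7)
        s2 = patient_cv_split(c, 5, seed=7)
        assert s1.assignments == s2.assignments

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            patient_cv_split(_tiny_cohort(3), folds=5, seed=0)


class TestRanking:
    def test_query_in_database_ranks_first(self, rng):
        db = rng.normal(size=(10, 4))
        r = rank_database(db[6], db)
        assert r.order[0] == 6 and r.distances[0] == 0.0

    def test_hand_sorted_one_dimensional_example(self):
        db = np.array([[1.0], [3.0], [2.0]])
        r = rank_database(np.array([0.0]), db)
        assert r.order.tolist() == [0, 2, 1]
        assert np.allclose(r.distances, [1.0, 2.0, 3.0])

    def test_ties_break_by_database_index(self):
        db = np.array([[1.0], [-1.0], [1.0]])
        r = rank_database(np.array([0.0]), db)
        assert r.order.tolist() == [0, 1, 2]

    def test_permuting_database_permutes_ranking(self, rng):
        db = rng.normal(size=(8, 3))
        q = rng.normal(size=3)
        perm = rng.permutation(8)
        r1 = rank_database(q, db)
        r2 = rank_database(q, db[perm])
        assert np.array_equal(perm[r2.order], r1.order)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            rank_database(np.zeros(2), np.empty((0, 2)))

    def test_labels_fill_relevance_ap_and_prec(self):
        db = np.array([[1.0], [2.0], [3.0]])
        r = rank_database(
            np.array([0.0]), db, query_label=1, database_labels=[1, 2, 1],
            prec_ns=(2,),
        )
        assert r.relevance.tolist() == [True, False, True]
        assert r.ap == pytest.approx((1 + 2 / 3) / 2)
        assert r.prec[2] == pytest.approx(0.5)


class TestMetricDefinitions:
    def test_all_relevant_gives_unit_ap(self):
        assert average_precision(np.ones(7, bool)) == 1.0

    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ([True, False, True], (1 + 2 / 3) / 2),
            ([False, True], 0.5),
            ([True, True, False, True], (1 + 1 + 3 / 4) / 3),
        ],
    )
    def test_hand_computed_patterns(self, pattern, expected):
        assert average_precision(np.array(pattern)) == pytest.approx(expected)

    def test_zero_relevant_raises(self):
        with pytest.raises(ValueError):
            average_precision(np.zeros(4, bool))

    def test_matches_brute_force_on_random_patterns(self, rng):
        for _ in range(200):
            rel = rng.random(rng.integers(1, 30)) < 0.4
            if not rel.any():
                rel[0] = True
            assert average_precision(rel) == pytest.approx(
                average_precision_brute(rel)
            )

    def test_prec_at_n_definitions(self):
        rel = np.array([True, False, True, True])
        assert prec_at_n(rel, 2) == 0.5
        assert prec_at_n(rel, 4) == pytest.approx(rel.mean())  # n = database size
        assert prec_at_n(np.ones(3, bool), 3) == 1.0
        with pytest.raises(ValueError):
            prec_at_n(rel, 5)


class TestEvaluation:
    def test_per_class_maps_average_to_overall(self, ci_encodings, ci_cohort,
                                               ci_config):
        report = evaluate_encoded(ci_encodings, ci_cohort.labels, ci_config)
        for fold in report["metrics"]["cfml"]["folds"]:
            per_class = fold["per_class"]
            weighted = sum(v["mAP"] * v["n_queries"] for v in per_class.values())
            total = sum(v["n_queries"] for v in per_class.values())
            assert weighted / total == pytest.approx(fold["mAP"])

    def test_training_models_ignore_test_fold_content(self, small_cohort,
                                                      small_config):
        """Canary: corrupting held-out images must not change fitted models."""
        split = patient_cv_split(small_cohort, 3, seed=0)
        test_idx = set(split.fold_indices(small_cohort, 0).tolist())
        train = [c for i, c in enumerate(small_cohort) if i not in test_idx]
        m1 = fit_feature_models(train, small_config)
        for i in test_idx:  # inject a marker feature into every test slice
            small_cohort.cases[i].image[:] += 1e6
        try:
            m2 = fit_feature_models(train, small_config)
        finally:
            for i in test_idx:
                small_cohort.cases[i].image[:] -= 1e6
        assert np.array_equal(m1.pca.components, m2.pca.components)
        assert np.array_equal(m1.vocabulary.means, m2.vocabulary.means)

    def test_map_invariant_to_database_ordering(self, rng):
        db = rng.normal(size=(20, 3))
        labels = rng.integers(0, 2, 20)
        q = rng.normal(size=3)
        r1 = rank_database(q, db, query_label=1, database_labels=labels)
        perm = rng.permutation(20)
        r2 = rank_database(q, db[perm], query_label=1, database_labels=labels[perm])
        assert r1.ap == pytest.approx(r2.ap)
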