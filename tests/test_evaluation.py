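import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ilrmr import (
    AssociationMatrix,
    SolverConfig,
    SynthConfig,
    auc_from_scores,
    aupr_from_scores,
    generate_network,
    isolated_disease_eval,
    loocv,
    mask_experiment,
)
from ilrmr.datatypes import SimilarityMatrix


def brute_force_auc(scores, labels):
    """O(P*N) pair-counting oracle: wins + half-ties over all pos-neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_from_scores([0.9, 0.8, 0.3], [1, 1, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_from_scores([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_hand_derived_three_quarters(self):
        assert auc_from_scores([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            auc_from_scores([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            # discretised scores force plenty of ties
            scores = np.round(rng.random(n), 1)
            assert auc_from_scores(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            scores = rng.random(30)
            assert auc_from_scores(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_label_shuffle_centres_at_half(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = np.zeros(200, dtype=int)
        labels[:40] = 1
        aucs = []
        for _ in range(100):
            rng.shuffle(labels)
            aucs.append(auc_from_scores(scores, labels))
        assert abs(np.mean(aucs) - 0.5) < 0.03


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr_from_scores([0.9, 0.1], [1, 0]) == 1.0

    def test_positive_ranked_last(self):
        assert aupr_from_scores([0.1, 0.5, 0.9], [1, 0, 0]) == pytest.approx(1 / 3)

    def test_block_ties_give_prevalence(self):
        # all scores equal: a single threshold block, precision = p/N
        assert aupr_from_scores([0.5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_no_positive_errors(self):
        with pytest.raises(ValueError, match="no positive"):
            aupr_from_scores([0.1, 0.2], [0, 0])


def _small_net(seed=1):
    return generate_network(SynthConfig(m=15, n=10, rank=2, density=0.15, seed=seed))


class TestLoocv:
    def test_oracle_scorer_gives_perfect_auc(self, toy_assoc):
        # scorer that peeks at the full matrix ranks every held-out pair first
        ids_m, ids_d = toy_assoc.mirna_ids, toy_assoc.disease_ids
        fun = SimilarityMatrix(np.eye(3), ids_m, "mirna_functional")
        phe = SimilarityMatrix(np.eye(3), ids_d, "disease_semantic")
        report = loocv(toy_assoc, fun, phe, scorer=lambda train: toy_assoc.values)
        assert report.auc == 1.0

    def test_requires_two_knowns(self):
        assoc = AssociationMatrix(np.array([[1.0, 0.0]]), ["m1"], ["d1", "d2"])
        fun = SimilarityMatrix(np.eye(1), ["m1"], "mirna_functional")
        phe = SimilarityMatrix(np.eye(2), ["d1", "d2"], "disease_semantic")
        with pytest.raises(ValueError, match="at least 2"):
            loocv(assoc, fun, phe)

    def test_roc_endpoints(self):
        assoc, fun, phe, fams, _ = _small_net()
        report = loocv(assoc, fun, phe, fams, scorer=lambda train: assoc.values)
        assert report.roc_points[0] == (0.0, 0.0)
        assert report.roc_points[-1] == (1.0, 1.0)
        fpr = [p[0] for p in report.roc_points]
        tpr = [p[1] for p in report.roc_points]
        assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tpr, tpr[1:]))

    def test_full_model_detects_planted_signal(self, default_net):
        assoc, fun, phe, fams, _ = default_net
        # cheap solver settings keep this a smoke-level check
        report = loocv(assoc, fun, phe, fams, SolverConfig(tol=1e-5))
        assert report.auc > 0.8

    def test_per_disease_pooling_restricts_candidates(self):
        assoc, fun, phe, fams, _ = _small_net()
        rep = loocv(assoc, fun, phe, fams, scorer=lambda train: assoc.values, per_disease=True)
        n_zero_per_col = (assoc.values == 0).sum(axis=0)
        for pair, _, _, n_cand in rep.per_item_records:
            j = assoc.disease_ids.index(pair.split("|")[1])
            assert n_cand == n_zero_per_col[j] + 1


class TestMaskExperiment:
    def test_same_seed_reproduces(self):
        assoc, fun, phe, fams, _ = _small_net()
        cfg = SolverConfig(tol=1e-5)
        a = mask_experiment(assoc, fun, phe, fams, cfg, 0.3, n_repeats=2, seed=9)
        b = mask_experiment(assoc, fun, phe, fams, cfg, 0.3, n_repeats=2, seed=9)
        assert a.per_repeat_auc == b.per_repeat_auc

    def test_mask_count_zero_errors(self):
        assoc, fun, phe, fams, _ = _small_net()
        with pytest.raises(ValueError, match="mask 0"):
            mask_experiment(assoc, fun, phe, fams, mask_ratio=0.001, n_repeats=1)

    def test_no_unknown_pairs_errors(self):
        assoc = AssociationMatrix(np.ones((1, 2)), ["m1"], ["d1", "d2"])
        fun = SimilarityMatrix(np.eye(1), ["m1"], "mirna_functional")
        phe = SimilarityMatrix(np.eye(2), ["d1", "d2"], "disease_semantic")
        with pytest.raises(ValueError, match="no unknown pairs"):
            mask_experiment(assoc, fun, phe, mask_ratio=0.6, n_repeats=1)

    def test_ratio_bounds(self):
        assoc, fun, phe, fams, _ = _small_net()
        with pytest.raises(ValueError, match="mask_ratio"):
            mask_experiment(assoc, fun, phe, fams, mask_ratio=1.5)


class TestIsolatedDisease:
    def test_twin_disease_recovers_interactors(self):
        # d_iso duplicates d_twin's interaction pattern and is semantically close
        m, ids_m = 8, [f"m{i}" for i in range(8)]
        ids_d = ["d_twin", "d_iso", "d_other"]
        A = np.zeros((m, 3))
        A[[0, 1, 2], 0] = 1  # d_twin: m0, m1, m2
        A[[0, 1, 2], 1] = 1  # d_iso: same pattern (to be hidden)
        A[[5, 6], 2] = 1
        assoc = AssociationMatrix(A, ids_m, ids_d)
        fun = SimilarityMatrix(np.eye(m), ids_m, "mirna_functional")
        phe_vals = np.full((3, 3), 0.1)
        np.fill_diagonal(phe_vals, 1.0)
        phe_vals[0, 1] = phe_vals[1, 0] = 0.95
        phe = SimilarityMatrix(phe_vals, ids_d, "disease_semantic")
        rep = isolated_disease_eval(assoc, fun, phe, disease_id="d_iso")
        ranks = [r for _, _, r, _ in rep.per_item_records]
        assert all(r <= m // 2 for r in ranks)
        assert rep.auc > 0.9

    def test_dissimilar_disease_is_chance_level(self, default_net):
        assoc, fun, phe, fams, _ = default_net
        # overwrite the semantic similarity with identity: no cross-disease signal
        phe0 = SimilarityMatrix(np.eye(len(assoc.disease_ids)), assoc.disease_ids,
                                "disease_semantic")
        j = int(np.argmax(assoc.values.sum(axis=0)))
        rep = isolated_disease_eval(
            assoc, fun, phe0, fams, SolverConfig(tol=1e-5),
            disease_id=assoc.disease_ids[j], use_family_and_cosine=False,
        )
        assert abs(rep.auc - 0.5) < 0.15

    def test_unknown_disease_errors(self, default_net):
        assoc, fun, phe, fams, _ = default_net
        with pytest.raises(ValueError, match="unknown disease"):
            isolated_disease_eval(assoc, fun, phe, fams, disease_id="nope")

    def test_other_disease_ranks_unaffected(self):
        # zeroing one column must not change another column's ranking
        assoc, fun, phe, fams, _ = _small_net()
        cols = np.argsort(assoc.values.sum(axis=0))[::-1][:2]
        d0, d1 = (assoc.disease_ids[int(c)] for c in cols)
        cfg = SolverConfig(tol=1e-6)
        rep_before = isolated_disease_eval(assoc, fun, phe, fams, cfg, disease_id=d1)
        hidden = assoc.copy()
        hidden.values[:, assoc.disease_ids.index(d0)] = 0.0
        # d0's column removal happens inside the d1 evaluation of `hidden`
        rep_after = isolated_disease_eval(hidden, fun, phe, fams, cfg, disease_id=d1)
        ranks_before = [r for _, _, r, _ in rep_before.per_item_records]
        ranks_after = [r for _, _, r, _ in rep_after.per_item_records]
        assert len(ranks_before) == len(ranks_after)
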