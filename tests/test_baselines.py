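"""Distance baselines, ROC machinery and the leave-half-out CV harness."""

import numpy as np
import pytest
from scipy.spatial import distance as sp_dist

import phyloloss as pl
from phyloloss.baselines import roc_from_scores

from conftest import random_profile_rows


def make_profile(rows):
    rows = np.asarray(rows, dtype=np.uint8)
    return pl.PhyloProfile(
        tuple(f"g{i}" for i in range(rows.shape[0])),
        tuple(f"S{j}" for j in range(rows.shape[1])),
        rows,
    )


class TestDistanceBaselines:
    def test_hamming_definition(self):
        prof = make_profile([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert pl.hamming_min_score(prof, ["g0"], "g1") == pytest.approx(0.5)
        assert pl.hamming_min_score(prof, ["g0"], "g0") == 0.0

    def test_hamming_min_rule(self):
        prof = make_profile([[1, 1, 1, 1], [1, 1, 0, 0], [1, 1, 1, 0]])
        # distances from g2: to g0 = 1/4, to g1 = 1/4... use distinct rows
        prof = make_profile([[1, 1, 1, 1], [0, 0, 1, 1], [1, 1, 1, 0]])
        d = pl.hamming_min_score(prof, ["g0", "g1"], "g2")
        assert d == pytest.approx(min(1 / 4, 3 / 4))

    def test_jaccard_definition(self):
        prof = make_profile([[1, 1, 0, 0], [0, 1, 1, 0]])
        assert pl.jaccard_max_score(prof, ["g0"], "g1") == pytest.approx(1 / 3)

    def test_jaccard_identical_and_disjoint(self):
        prof = make_profile([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        assert pl.jaccard_max_score(prof, ["g0"], "g1") == 1.0
        assert pl.jaccard_max_score(prof, ["g0"], "g2") == 0.0

    def test_all_zero_rows_count_as_identical(self):
        prof = make_profile([[0, 0, 0], [0, 0, 0]])
        assert pl.jaccard_max_score(prof, ["g0"], "g1") == 1.0

    def test_agree_with_scipy_reference(self, rng):
        rows = random_profile_rows(30, 25, rng, min_presence=0)
        prof = make_profile(rows)
        for _ in range(100):
            i, j = rng.integers(0, 30, size=2)
            gi, gj = f"g{i}", f"g{j}"
            assert pl.hamming_min_score(prof, [gi], gj) == pytest.approx(
                sp_dist.hamming(rows[i], rows[j]), abs=1e-12
            )
            if rows[i].any() or rows[j].any():
                assert pl.jaccard_max_score(prof, [gi], gj) == pytest.approx(
                    1.0 - sp_dist.jaccard(rows[i], rows[j]), abs=1e-12
                )


class TestRocMachinery:
    def test_confusion_identities_fuzz(self, rng):
        """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) for every
        threshold of random score/label draws."""
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            curve = roc_from_scores(scores, labels)
            pos, neg = labels.sum(), (~labels).sum()
            assert ((curve.tp + curve.fn) == pos).all()
            assert ((curve.tn + curve.fp) == neg).all()
            np.testing.assert_allclose(
                curve.sensitivity, curve.tp / (curve.tp + curve.fn)
            )
            np.testing.assert_allclose(
                curve.specificity, curve.tn / (curve.tn + curve.fp)
            )
            # monotone sweep: lowering the threshold never loses a call
            assert (np.diff(curve.tp) >= 0).all()
            assert (np.diff(curve.fp) >= 0).all()

    def test_example_sensitivity(self):
        # 10 positives of which 9 recovered at the top
        scores = np.r_[np.arange(10, 1, -1), 0.5, np.zeros(20)]
        labels = np.r_[np.ones(9), 0, 1, np.zeros(19)].astype(bool)
        curve = roc_from_scores(scores, labels)
        i = int(np.argwhere(curve.thresholds == 2.0)[0][0])
        assert curve.tp[i] == 9 and curve.fn[i] == 1
        assert curve.sensitivity[i] == pytest.approx(0.9)

    def test_perfect_scorer(self):
        curve = roc_from_scores([1, 1, 0, 0], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)
        # a threshold attains sensitivity 1 at specificity 1
        assert any(
            s == 1.0 and sp == 1.0
            for s, sp in zip(curve.sensitivity, curve.specificity)
        )

    def test_diagonal_auc_half(self):
        # scores independent of labels, all distinct, interleaved
        scores = np.arange(10)
        labels = np.array([True, False] * 5)
        assert roc_from_scores(scores, labels).auc == pytest.approx(0.5, abs=0.1)
        # exactly diagonal: single threshold calling everything
        curve = roc_from_scores(np.ones(10), labels)
        assert curve.auc == pytest.approx(0.5)

    def test_hand_built_three_point_curve(self):
        curve = pl.RocCurve(
            thresholds=np.array([3.0, 2.0, 1.0]),
            tp=np.array([5, 8, 10]),
            fp=np.array([0, 5, 10]),
            tn=np.array([10, 5, 0]),
            fn=np.array([5, 2, 0]),
        )
        # points (1-spec, sens): (0,.5), (.5,.8), (1,1); with the (0,0)
        # anchor the trapezoids give 0 + .325 + .45 = 0.775
        assert pl.roc_auc(curve) == pytest.approx(0.775)

    def test_never_predicted_stay_negative(self):
        scores = np.array([2.0, 1.0, -np.inf, -np.inf])
        labels = np.array([True, False, True, False])
        curve = roc_from_scores(scores, labels)
        assert curve.tp.max() == 1  # the -inf positive is never recovered
        assert curve.sensitivity.max() == pytest.approx(0.5)

    def test_sklearn_auc_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        ours = roc_from_scores(scores, labels).auc
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)


class TestLeaveHalfOutCv:
    @pytest.fixture
    def study(self):
        return pl.simulate_study(
            pl.SimulationConfig(
                n_species=16, n_background_genes=120, pathway_sizes=(8, 6), seed=21
            )
        )

    def test_splits_partition_and_reproduce(self, study):
        tree, profile, pathways, _ = study
        scorer = pl.make_hamming_scorer(profile)
        res1 = pl.leave_half_out_cv(
            profile, dict(pathways), scorer, n_repeats=3, seed=42
        )
        res2 = pl.leave_half_out_cv(
            profile, dict(pathways), scorer, n_repeats=3, seed=42
        )
        assert [s for s, _ in res1] == [s for s, _ in res2]
        for split, _ in res1:
            full = set(dict(pathways)[split.pathway_id])
            assert set(split.input_half) | set(split.held_out_half) == full
            assert not set(split.input_half) & set(split.held_out_half)
            assert len(split.input_half) in (len(full) // 2, (len(full) + 1) // 2)

    def test_different_seed_different_splits(self, study):
        tree, profile, pathways, _ = study
        scorer = pl.make_hamming_scorer(profile)
        res1 = pl.leave_half_out_cv(profile, dict(pathways), scorer, n_repeats=3, seed=1)
        res2 = pl.leave_half_out_cv(profile, dict(pathways), scorer, n_repeats=3, seed=2)
        assert [s.input_half for s, _ in res1] != [s.input_half for s, _ in res2]

    def test_oracle_scorer_is_perfect(self, study):
        tree, profile, pathways, truth = study
        members = {pid: set(g) for pid, g in pathways}

        def oracle(input_ids, candidate_ids):
            pid = truth.membership[input_ids[0]]
            return {g: 1.0 if g in members[pid] else 0.0 for g in candidate_ids}

        results = pl.leave_half_out_cv(
            profile, dict(pathways), oracle, n_repeats=2, seed=0
        )
        pooled = pl.pooled_roc(results)
        assert pooled.auc == pytest.approx(1.0)

    def test_small_pathways_skipped(self, study):
        tree, profile, pathways, _ = study
        pw = dict(pathways)
        pw["tiny"] = [profile.gene_ids[0]]
        scorer = pl.make_hamming_scorer(profile)
        results = pl.leave_half_out_cv(profile, pw, scorer, n_repeats=1, seed=0)
        assert all(s.pathway_id != "tiny" for s, _ in results)

    def test_pooled_counts_sum_of_splits(self, study):
        tree, profile, pathways, _ = study
        scorer = pl.make_jaccard_scorer(profile)
        results = pl.leave_half_out_cv(
            profile, dict(pathways), scorer, n_repeats=2, seed=7
        )
        pooled = pl.pooled_roc(results)
        # at the most permissive threshold everything finite is called
        total_pos = sum(int(c.tp[-1] + c.fn[-1]) for _, c in results)
        assert int(pooled.tp[-1] + pooled.fn[-1]) == total_pos
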