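import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from allodyn import evaluation as ev
from allodyn import pdz2
from allodyn.evaluation import (ConfusionCounts, ROCCurve, best_threshold,
                                combine_ranks, confusion, label_residues,
                                roc_from_scores, roc_from_sweep, tpr_fpr)


@pytest.fixture
def pdz2_labels():
    return label_residues(pdz2.FUENTES_POSITIVES, pdz2.EXCLUDED,
                          pdz2.METHYL_UNIVERSE)


class TestLabeling:
    def test_published_exclusions_leave_eleven_negatives(self, pdz2_labels):
        assert len(pdz2_labels.negatives) == 11
        assert len(pdz2_labels.positives) == 14

    def test_empty_exclusions(self):
        labels = label_residues(["a"], [], ["a", "b", "c"])
        assert labels.negatives == {"b", "c"}

    def test_positives_equal_universe(self):
        labels = label_residues(["a", "b"], [], ["a", "b"])
        assert labels.negatives == set()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            label_residues(["a"], ["a"], ["a", "b"])

    def test_labels_file_round_trip(self, tmp_path, pdz2_labels):
        path = tmp_path / "labels.tsv"
        ev.write_labels(pdz2_labels, path)
        back = ev.read_labels(path)
        assert back == pdz2_labels

    def test_without_alanines(self, pdz2_labels):
        stripped = pdz2_labels.without_alanines()
        assert not any(r.startswith("A") for r in stripped.universe)
        assert "A39" in pdz2_labels.positives
        assert "A39" not in stripped.positives


class TestConfusion:
    def test_perfect_prediction(self, pdz2_labels):
        c = confusion(pdz2_labels.positives, pdz2_labels)
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp == len(pdz2_labels.positives)

    def test_empty_prediction(self, pdz2_labels):
        c = confusion(set(), pdz2_labels)
        assert (c.tp, c.fp) == (0, 0)
        assert c.fn == len(pdz2_labels.positives)

    @pytest.mark.parametrize("method", sorted(pdz2.CONFUSION_COUNTS))
    def test_published_prediction_lists_reproduce_counts(self, method,
                                                         pdz2_labels):
        tp, tn, fp, fn = pdz2.CONFUSION_COUNTS[method]
        c = confusion(set(pdz2.PREDICTIONS[method]), pdz2_labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_counts_partition_the_labeling(self, pdz2_labels):
        rng = np.random.default_rng(0)
        universe = sorted(pdz2_labels.universe)
        for _ in range(20):
            pred = set(rng.choice(universe, size=rng.integers(0, 20),
                                  replace=False))
            c = confusion(pred, pdz2_labels)
            assert c.tp + c.fn == len(pdz2_labels.positives)
            assert c.tn + c.fp == len(pdz2_labels.negatives)

    def test_outside_universe_warned_and_ignored(self, pdz2_labels):
        with pytest.warns(UserWarning, match="outside"):
            c = confusion({"Z999"} | pdz2_labels.positives, pdz2_labels)
        assert c.fp == 0


class TestTprFpr:
    @pytest.mark.parametrize("counts,expected", [
        ((11, 9, 2, 3), (0.79, 0.18)),
        ((9, 9, 2, 5), (0.64, 0.18)),
        ((11, 3, 8, 3), (0.79, 0.73)),
        ((6, 6, 5, 8), (0.43, 0.45)),
    ])
    def test_published_cells_at_two_decimals(self, counts, expected):
        tp, tn, fp, fn = counts
        tpr, fpr = tpr_fpr(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert (round(tpr, 2), round(fpr, 2)) == expected

    def test_zero_rates(self):
        tpr, fpr = tpr_fpr(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert (tpr, fpr) == (0.0, 0.0)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="positives"):
            tpr_fpr(ConfusionCounts(tp=0, tn=1, fp=1, fn=0))
        with pytest.raises(ValueError, match="negatives"):
            tpr_fpr(ConfusionCounts(tp=1, tn=0, fp=0, fn=1))


class TestROC:
    def test_perfect_ranking_auc_one(self):
        labels = label_residues(["a", "b"], [], ["a", "b", "c", "d"])
        scores = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
        assert roc_from_scores(scores, labels).auc == pytest.approx(1.0)

    def test_single_diagonal_point_auc_half(self):
        closed, auc = ev._close_and_integrate([(1.0, 0.5, 0.5)])
        assert auc == pytest.approx(0.5)
        assert closed[0][1:] == (0.0, 0.0) and closed[-1][1:] == (1.0, 1.0)

    def test_matches_sklearn_on_continuous_scores(self):
        rng = np.random.default_rng(1)
        residues = [f"r{i}" for i in range(40)]
        truth = rng.random(40) < 0.4
        scores = {r: float(rng.normal(t, 1.0))
                  for r, t in zip(residues, truth)}
        labels = label_residues([r for r, t in zip(residues, truth) if t],
                                [], residues)
        ours = roc_from_scores(scores, labels).auc
        ref = roc_auc_score(truth, [scores[r] for r in residues])
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_random_labelings_mean_auc_half(self):
        rng = np.random.default_rng(2)
        residues = [f"r{i}" for i in range(25)]
        scores = {r: float(rng.random()) for r in residues}
        aucs = []
        for _ in range(1000):
            pos = rng.choice(residues, size=10, replace=False)
            labels = label_residues(list(pos), [], residues)
            aucs.append(roc_from_scores(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        residues = [f"r{i}" for i in range(30)]
        scores = {r: float(rng.normal()) for r in residues}
        labels = label_residues(residues[:12], [], residues)
        a = roc_from_scores(scores, labels).auc
        b = roc_from_scores({r: math.exp(3 * s) for r, s in scores.items()},
                            labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_sweep_on_planted_matrix_separates_blocks(self):
        # residues 0-3 coupled (positives), 4-9 uncoupled (negatives)
        n = 10
        m = np.zeros((n, n))
        for i in range(4):
            for j in range(4):
                if i != j:
                    m[i, j] = 0.5
        ids = list(range(n))
        labels = label_residues([0, 1, 2, 3], [], ids)
        roc = roc_from_sweep(m, ids, labels, np.linspace(0.6, 0.01, 20))
        assert roc.auc == pytest.approx(1.0)
        t, fpr, tpr = roc.best
        assert (fpr, tpr) == (0.0, 1.0)


class TestBestThreshold:
    def _curve(self, pts):
        closed = ([(math.inf, 0.0, 0.0)] + pts + [(-math.inf, 1.0, 1.0)])
        return ROCCurve(points=closed, auc=0.0)

    def test_perfect_corner_wins(self):
        roc = self._curve([(0.3, 0.2, 0.6), (0.2, 0.0, 1.0)])
        assert best_threshold(roc)[0] == 0.2

    def test_distance_arithmetic(self):
        roc = self._curve([(0.023, 0.18, 0.79), (0.01, 0.64, 0.45)])
        t, fpr, tpr = best_threshold(roc)
        assert (fpr, tpr) == (0.18, 0.79)

    def test_diagonal_points_middle_wins(self):
        roc = self._curve([(f, f, f) for f in (0.1, 0.3, 0.5, 0.7, 0.9)])
        assert best_threshold(roc)[1] == pytest.approx(0.5)

    def test_tie_prefers_larger_threshold(self):
        roc = self._curve([(0.5, 0.2, 0.8), (0.1, 0.2, 0.8)])
        assert best_threshold(roc)[0] == 0.5


class TestCombineRanks:
    def test_weighted_sum(self):
        cr = combine_ranks({"a": 1, "b": 2}, {"a": 1, "b": 4})
        assert cr.score["a"] == pytest.approx(2.5)
        assert cr.score["b"] == pytest.approx(7.0)
        assert cr.order == ["a", "b"]

    def test_alpha_zero_reduces_to_backbone_order(self):
        rng = np.random.default_rng(4)
        residues = [f"r{i}" for i in range(15)]
        sc = {r: int(v) for r, v in
              zip(residues, rng.permutation(15) + 1)}
        bb = {r: int(v) for r, v in
              zip(residues, rng.permutation(15) + 1)}
        cr = combine_ranks(sc, bb, alpha=0.0, beta=1.0)
        assert cr.order == sorted(residues, key=lambda r: bb[r])

    def test_ties_broken_reproducibly(self):
        sc = {"a": 1, "b": 1}
        bb = {"a": 1, "b": 1}
        first = combine_ranks(sc, bb, seed=5).order
        again = combine_ranks(sc, bb, seed=5).order
        assert first == again

    def test_residue_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_ranks({"a": 1}, {"b": 1})
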