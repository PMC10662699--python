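"""Splits, metrics, DeLong comparison and ensemble voting."""

import itertools

import numpy as np
import pandas as pd
import pytest

import glycoprm as g
from glycoprm.evaluate import _structural_components


def auc_concordance_oracle(scores, y):
    """Brute-force Mann-Whitney AUC: pairwise concordance count."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def delong_oracle(scores_a, scores_b, y):
    """Exhaustive structural-components DeLong: explicit V10/V01 loops."""
    def components(s):
        pos = [x for x, t in zip(s, y) if t == 1]
        neg = [x for x, t in zip(s, y) if t == 0]
        v10 = [np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for n in neg]) for p in pos]
        v01 = [np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for p in pos]) for n in neg]
        return np.array(v10), np.array(v01)

    v10a, v01a = components(scores_a)
    v10b, v01b = components(scores_b)
    m, n = len(v10a), len(v01a)
    var = np.var(v10a - v10b, ddof=1) / m + np.var(v01a - v01b, ddof=1) / n
    return float(v10a.mean()), float(v10b.mean()), var


class TestSplit:
    def test_study_partition_sizes(self, study_matrix):
        matrix, _, _ = study_matrix
        parts = g.split(matrix, g.SplitSpec(seed=0))
        assert len(parts["greyzone"]) == 20
        assert len(parts["train"]) == 100
        assert len(parts["test"]) == 43
        build = pd.concat([parts["train"], parts["test"]])
        assert len(build) == 143

    def test_greyzone_drawn_from_range_only(self, study_matrix):
        matrix, _, _ = study_matrix
        parts = g.split(matrix, g.SplitSpec(seed=1))
        assert parts["greyzone"]["tpsa"].between(4, 10).all()

    def test_partitions_disjoint_and_exhaustive(self, study_matrix):
        matrix, _, _ = study_matrix
        parts = g.split(matrix, g.SplitSpec(seed=2))
        idx = [set(p.index) for p in parts.values()]
        assert not (idx[0] & idx[1]) and not (idx[0] & idx[2]) and not (idx[1] & idx[2])
        assert idx[0] | idx[1] | idx[2] == set(matrix.index)

    def test_deterministic(self, study_matrix):
        matrix, _, _ = study_matrix
        a = g.split(matrix, g.SplitSpec(seed=3))
        b = g.split(matrix, g.SplitSpec(seed=3))
        for key in a:
            assert list(a[key].index) == list(b[key].index)

    def test_insufficient_greyzone_candidates(self, study_matrix):
        matrix, _, _ = study_matrix
        with pytest.raises(ValueError, match="requested"):
            g.split(matrix, g.SplitSpec(holdout_greyzone=500))


class TestAUC:
    def test_matches_concordance_oracle_on_small_vectors(self):
        rng = np.random.default_rng(0)
        for n in (5, 12, 30):
            for _ in range(5):
                y = rng.integers(0, 2, size=n)
                if y.sum() in (0, n):
                    y[0], y[-1] = 0, 1
                scores = np.round(rng.normal(size=n), 1)  # force some ties
                v10, _ = _structural_components(scores, y)
                assert v10.mean() == pytest.approx(
                    auc_concordance_oracle(scores, y), abs=1e-12
                )


class TestDeLong:
    def test_identical_scores(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([0.1, 0.9, 0.3, 0.8, 0.6, 0.2])
        out = g.delong_compare(s, s, y)
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_variance_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for n in (6, 9, 12):
            for _ in range(10):
                y = rng.integers(0, 2, size=n)
                if y.sum() in (0, n):
                    y[0], y[-1] = 0, 1
                a = rng.normal(size=n)
                b = rng.normal(size=n)
                out = g.delong_compare(a, b, y)
                auc_a, auc_b, var = delong_oracle(a, b, y)
                assert out["auc_a"] == pytest.approx(auc_a, abs=1e-10)
                assert out["auc_b"] == pytest.approx(auc_b, abs=1e-10)
                if var > 0:
                    z = (auc_a - auc_b) / np.sqrt(var)
                    assert out["z"] == pytest.approx(z, abs=1e-10)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=40)
        y[:5], y[-5:] = 0, 1
        a, b = rng.normal(size=40), rng.normal(size=40)
        ref = g.delong_compare(a, b, y)
        warped = g.delong_compare(np.exp(a), np.arctan(b) * 7 + 2, y)
        assert warped["z"] == pytest.approx(ref["z"], abs=1e-12)
        assert warped["p"] == pytest.approx(ref["p"], abs=1e-12)

    def test_perfect_and_antiperfect(self):
        y = np.array([0, 1] * 10)
        perfect = y.astype(float)
        anti = 1.0 - y
        out = g.delong_compare(perfect, anti, y)
        assert out["auc_a"] == 1.0 and out["auc_b"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            g.delong_compare([1, 2], [2, 1], [1, 1])


class TestVoting:
    def test_hard_vote_matches_majority_oracle_on_all_patterns(self):
        for pattern in itertools.product(["PCa", "BPH"], repeat=5):
            cls, agreement = g.hard_vote(list(pattern), positive="PCa")
            n_pos = pattern.count("PCa")
            expected = "PCa" if n_pos >= 3 else "BPH"
            assert cls == expected
            assert agreement == max(n_pos, 5 - n_pos)

    def test_even_split_breaks_toward_positive(self):
        cls, agreement = g.hard_vote(["PCa", "PCa", "BPH", "BPH"])
        assert cls == "PCa" and agreement == 2

    def test_soft_vote_with_equal_weights_reduces_to_hard_vote(self):
        w = {f"m{i}": 0.7 for i in range(5)}
        for pattern in itertools.product(["PCa", "BPH"], repeat=5):
            preds = {f"m{i}": p for i, p in enumerate(pattern)}
            assert g.soft_vote(preds, w) == g.hard_vote(preds)[0]

    def test_dominant_weight_wins(self):
        preds = {"a": "PCa", "b": "BPH", "c": "BPH", "d": "BPH", "e": "BPH"}
        weights = {"a": 0.9, "b": 0.1, "c": 0.1, "d": 0.1, "e": 0.1}
        assert g.soft_vote(preds, weights) == "PCa"

    def test_zero_weight_model_never_changes_outcome(self):
        weights = {"a": 0.5, "b": 0.4, "c": 0.0}
        for pattern in itertools.product(["PCa", "BPH"], repeat=3):
            preds = dict(zip("abc", pattern))
            flipped = dict(preds)
            flipped["c"] = "PCa" if preds["c"] == "BPH" else "BPH"
            assert g.soft_vote(preds, weights) == g.soft_vote(flipped, weights)

    def test_vote_validation(self):
        with pytest.raises(ValueError):
            g.hard_vote(["PCa"])
        with pytest.raises(ValueError):
            g.soft_vote({"a": "PCa"}, {"a": 0.0})
        with pytest.raises(ValueError):
            g.soft_vote({"a": "PCa"}, {"b": 1.0})


def _separable_frames(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["PCa", "BPH"] * (n // 2))
    df = pd.DataFrame(
        {
            "diagnosis": y,
            "marker": np.where(y == "PCa", 10.0, 0.0) + rng.normal(0, 0.1, n),
            "tpsa": rng.lognormal(1, 0.5, n),
        }
    )
    return df.iloc[: n // 2], df.iloc[n // 2 :]


class TestTrainAndScore:
    def test_perfectly_separable_data(self):
        train, test = _separable_frames()
        report = g.train_and_score(train, test, ["marker"], seed=0, n_boot=50)
        rf = report.models["random_forest"]
        assert rf.metrics["auc"] == 1.0
        assert rf.metrics["sensitivity"] == 1.0

    def test_metric_identities_from_confusion_matrix(self):
        train, test = _separable_frames(seed=3)
        report = g.train_and_score(train, test, ["marker", "tpsa"], seed=1, n_boot=0)
        for ms in report.models.values():
            (tn, fp), (fn, tp) = ms.confusion
            n = tn + fp + fn + tp
            assert n == len(test)
            assert ms.metrics["accuracy"] == pytest.approx((tp + tn) / n)
            assert ms.metrics["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert ms.metrics["specificity"] == pytest.approx(tn / (tn + fp))

    def test_ci_brackets_point_estimate(self):
        train, test = _separable_frames(seed=4)
        report = g.train_and_score(train, test, ["marker"], seed=2, n_boot=200)
        for ms in report.models.values():
            for key, (lo, hi) in ms.ci.items():
                val = ms.metrics[key]
                assert lo - 1e-9 <= val <= hi + 1e-9

    def test_single_class_training_rejected(self):
        train, test = _separable_frames()
        train = train[train["diagnosis"] == "PCa"]
        with pytest.raises(ValueError, match="single class"):
            g.train_and_score(train, test, ["marker"])

    def test_unknown_feature_rejected(self):
        train, test = _separable_frames()
        with pytest.raises(KeyError):
            g.train_and_score(train, test, ["missing_col"])

    def test_shuffled_labels_give_chance_level(self, study_matrix, feature_columns):
        """Permuting training+test labels pushes every model toward AUC 0.5
        (central envelope checked over 3 seeded permutations)."""
        matrix, _, _ = study_matrix
        rng = np.random.default_rng(99)
        aucs = []
        for seed in range(3):
            shuffled = matrix.copy()
            shuffled["diagnosis"] = rng.permutation(shuffled["diagnosis"].to_numpy())
            try:
                parts = g.split(shuffled, g.SplitSpec(seed=seed))
            except ValueError:
                continue
            report = g.train_and_score(
                parts["train"], parts["test"], feature_columns, seed=seed, n_boot=0
            )
            aucs.extend(ms.metrics["auc"] for ms in report.models.values())
        assert abs(np.median(aucs) - 0.5) < 0.15
        assert all(0.2 < a < 0.8 for a in aucs)


class TestAggressiveness:
    def test_split_sizes_and_envelope(self, study_matrix):
        """79 PCa at 70% -> 55 train / 24 test; with the planted moderate
        AG effects the forest lands in a mid-range AUC band."""
        matrix, _, truth = study_matrix
        ag_informative = [
            p for p, fc in truth["ag_fold_changes"].items() if fc != 1.0
        ]
        aucs = []
        for seed in range(3):
            report = g.run_aggressiveness(
                matrix, ag_informative + ["propsa"], seed=seed, n_boot=0
            )
            assert len(report.y_test) == 24
            assert report.positive_label == "AG"
            assert set(report.models) == {
                "random_forest", "logistic", "knn", "decision_tree"
            }
            aucs.append(report.models["random_forest"].metrics["auc"])
        assert 0.6 <= float(np.median(aucs)) <= 0.85

    def test_null_ag_effects_give_chance_auc(self, panel):
        unit = {p: 1.0 for p in panel["peptide_id"]}
        sig = g.SignalConfig(ag_fold_changes=unit, frac_discordant_runs=0.0)
        cohort, runs, truth = g.generate_dataset(signal=sig, seed=31)
        retained, _ = g.qc_filter(runs)
        matrix = g.assemble_matrix(retained, cohort, panel)
        peptides = list(panel["peptide_id"])
        report = g.run_aggressiveness(matrix, peptides, seed=0, n_boot=0)
        assert abs(report.models["random_forest"].metrics["auc"] - 0.5) < 0.2
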