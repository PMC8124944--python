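import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirpanel import PanelModel, choose_cutoff, confusion_metrics, roc_auc, trend_by_group
from mirpanel.evaluate import evaluate_frozen
from mirpanel._stats import candidate_thresholds, jonckheere_statistic


def brute_force_auc(pos, neg):
    wins = sum(1 for a in pos for b in neg if a > b)
    ties = sum(1 for a in pos for b in neg if a == b)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def wilson_interval(x, n, z=1.959963984540054):
    """Independent closed-form Wilson 95% interval."""
    p = x / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return centre - half, centre + half


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], ["malignant", "malignant", "benign", "benign"])
        assert auc == 1.0

    def test_constant_scores(self):
        auc, _ = roc_auc([0.5] * 6, ["malignant"] * 3 + ["benign"] * 3)
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["benign", "benign"])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        n_pos = int(rng.integers(1, n - 1))
        scores = np.round(rng.normal(size=n), 1)
        labels = ["malignant"] * n_pos + ["benign"] * (n - n_pos)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores[:n_pos], scores[n_pos:]), abs=1e-12)

    def test_curve_endpoints(self):
        _, curve = roc_auc([0.9, 0.3, 0.6, 0.2], ["malignant", "benign", "malignant", "benign"])
        first, last = curve.iloc[0], curve.iloc[-1]
        assert (first["fpr"], first["tpr"]) == (1.0, 1.0)  # threshold -inf
        assert (last["fpr"], last["tpr"]) == (0.0, 0.0)  # threshold +inf

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = ["malignant"] * 15 + ["benign"] * 25
        auc1, _ = roc_auc(scores, labels)
        auc2, _ = roc_auc(np.exp(scores), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)


class TestChooseCutoff:
    def test_separable_perfect_specificity(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = ["malignant", "malignant", "benign", "benign"]
        cut = choose_cutoff(scores, labels, "high_specificity", 1.0)
        assert 0.2 < cut < 0.8
        rep = confusion_metrics(scores, labels, cut)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0

    def test_threshold_sweep_oracle(self):
        # independent enumeration of all midpoint thresholds
        scores = np.array([0.1, 0.2, 0.35, 0.4, 0.55, 0.7, 0.9])
        labels = np.array(["benign", "benign", "malignant", "benign", "malignant", "malignant", "malignant"])
        positive = labels == "malignant"
        n_pos, n_neg = positive.sum(), (~positive).sum()
        best = None
        for t in sorted(candidate_thresholds(scores)):
            if not np.isfinite(t):
                continue
            spec = ((scores < t) & ~positive).sum() / n_neg
            if spec >= 2 / 3 and best is None:
                best = t
        got = choose_cutoff(scores, labels, "high_specificity", 2 / 3)
        assert got == pytest.approx(best)

    def test_high_sensitivity_mode(self):
        scores = np.array([0.1, 0.2, 0.35, 0.4, 0.55, 0.7, 0.9])
        labels = np.array(["benign", "benign", "malignant", "benign", "malignant", "malignant", "malignant"])
        cut = choose_cutoff(scores, labels, "high_sensitivity", 0.75)
        rep = confusion_metrics(scores, labels, cut)
        assert rep.sensitivity >= 0.75
        # largest such threshold: raising it further must break the target
        higher = scores[scores >= cut].min()
        rep2 = confusion_metrics(scores, labels, higher + 1e-9)
        assert rep2.sensitivity < 0.75

    def test_unreachable_target_names_best(self):
        scores = [0.5, 0.5, 0.5, 0.5]
        labels = ["malignant", "benign", "malignant", "benign"]
        with pytest.raises(ValueError, match="best attainable"):
            choose_cutoff(scores, labels, "high_specificity", 0.99)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            choose_cutoff([0.1, 0.9], ["benign", "malignant"], "nope", 0.5)

    def test_monotonicity_of_sens_spec_over_sweep(self):
        rng = np.random.default_rng(5)
        scores = rng.random(60)
        labels = np.where(rng.random(60) < 0.4, "malignant", "benign")
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        sens, spec = [], []
        for t in candidate_thresholds(scores):
            rep = confusion_metrics(scores, labels, t)
            sens.append(rep.sensitivity)
            spec.append(rep.specificity)
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))  # non-increasing
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))  # non-decreasing


class TestConfusionMetrics:
    def test_arithmetic_example(self):
        # TP=3, FN=1, TN=4, FP=2 by construction
        scores = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        labels = ["malignant"] * 4 + ["benign"] * 6
        rep = confusion_metrics(scores, labels, cutoff=0.5)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (3, 1, 4, 2)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(2 / 3)
        assert rep.ppv == pytest.approx(0.6)
        assert rep.npv == pytest.approx(0.8)

    def test_cutoff_below_all(self):
        rep = confusion_metrics([0.2, 0.8], ["benign", "malignant"], cutoff=-1.0)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0

    def test_bayes_identity(self):
        rng = np.random.default_rng(7)
        scores = rng.random(50)
        labels = np.where(rng.random(50) < 0.3, "malignant", "benign")
        rep = confusion_metrics(scores, labels, 0.5)
        n = 50
        prev = (labels == "malignant").sum() / n
        if rep.ppv is not None:
            lhs = rep.ppv * ((rep.tp + rep.fp) / n)
            rhs = rep.sensitivity * prev
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_wilson_interval_closed_form(self):
        scores = [1] * 30 + [0] * 10 + [1] * 5 + [0] * 55
        labels = ["malignant"] * 40 + ["benign"] * 60
        rep = confusion_metrics(scores, labels, 0.5)
        lo, hi = wilson_interval(30, 40)
        assert rep.ci["sensitivity"][0] == pytest.approx(lo, abs=1e-9)
        assert rep.ci["sensitivity"][1] == pytest.approx(hi, abs=1e-9)

    def test_empty_class_flagged_not_nan(self):
        rep = confusion_metrics([0.9, 0.8], ["malignant", "malignant"], 0.5)
        assert rep.specificity is None
        assert "specificity" in rep.undefined


class TestTrend:
    def test_hand_countable_statistic(self):
        # groups g1={1,2}, g2={3,4}, g3={5,6}: every cross-pair increases
        # => statistic = 3 pairs-of-groups x 4 pairs = 12
        values = [1, 2, 3, 4, 5, 6]
        groups = [0, 0, 1, 1, 2, 2]
        assert jonckheere_statistic(np.array(values, float), np.array(groups)) == 12.0

    def test_statistic_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(11)
        values = rng.integers(0, 5, size=15).astype(float)
        groups = np.repeat([0, 1, 2], 5)
        by = [values[groups == g] for g in (0, 1, 2)]
        expected = 0.0
        for i, j in itertools.combinations(range(3), 2):
            for a in by[i]:
                for b in by[j]:
                    expected += 1.0 if b > a else 0.5 if b == a else 0.0
        assert jonckheere_statistic(values, groups) == pytest.approx(expected)

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(m, 0.3, 30) for m in (0.0, 0.5, 1.0)])
        groups = np.repeat([0, 1, 2], 30)
        rep = trend_by_group(values, groups, n_permutations=2000, seed=4)
        assert rep.p_value < 0.01
        assert rep.summaries["median"].is_monotonic_increasing

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for rep_i in range(40):
            values = rng.normal(size=24)
            groups = np.repeat([0, 1, 2], 8)
            rep = trend_by_group(values, groups, n_permutations=200, seed=rep_i)
            ps.append(rep.p_value)
        ps = np.array(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.05).mean() < 0.25

    def test_missing_groups_excluded_and_counted(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = pd.Series([0, 0, 1, 1, None, None])
        rep = trend_by_group(values, groups, n_permutations=100, seed=0)
        assert rep.n_excluded == 2
        assert rep.summaries["n"].sum() == 4

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            trend_by_group(np.arange(4.0), np.zeros(4), n_permutations=10, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=30)
        groups = np.repeat([0, 1, 2], 10)
        a = trend_by_group(values, groups, n_permutations=500, seed=3)
        b = trend_by_group(values, groups, n_permutations=500, seed=3)
        assert a.p_value == b.p_value


class TestEvaluateFrozen:
    @staticmethod
    def _setup(seed=0, n=60):
        rng = np.random.default_rng(seed)
        norm = pd.DataFrame(
            rng.normal(size=(n, 3)),
            columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(n)],
        )
        labels = pd.Series(
            np.where(rng.random(n) < 0.4, "malignant", "benign"), index=norm.index
        )
        norm.loc[labels == "malignant", "a"] += 1.5
        model = PanelModel(["a", "b"], np.array([1.2, 0.1]), -0.3, np.zeros(2), np.ones(2))
        return norm, labels, model

    def test_resubstitution_idempotence(self):
        norm, labels, model = self._setup()
        res1 = evaluate_frozen(model, norm, labels)
        res2 = evaluate_frozen(model, norm, labels)
        assert res1.auc == res2.auc
        auc_direct, _ = roc_auc(model.score(norm).to_numpy(), labels)
        assert res1.auc == pytest.approx(auc_direct, abs=1e-12)

    def test_control_definition_switch(self):
        norm, labels, model = self._setup(seed=1)
        labels.iloc[:10] = "normal"
        benign_only = evaluate_frozen(model, norm, labels, include_normals=False)
        with_normals = evaluate_frozen(model, norm, labels, include_normals=True)
        assert benign_only.control_definition == "benign"
        assert with_normals.control_definition == "benign+normal"
        assert len(with_normals.scores) == len(benign_only.scores) + 10

    def test_easy_normals_do_not_decrease_auc(self):
        norm, labels, model = self._setup(seed=2)
        # construct normals scoring below every benign sample on feature 'a'
        normals = norm.copy().iloc[:12]
        normals.index = [f"n{i}" for i in range(12)]
        normals["a"] = norm.loc[labels == "benign", "a"].min() - 5.0
        all_norm = pd.concat([norm, normals])
        all_labels = pd.concat([labels, pd.Series("normal", index=normals.index)])
        base = evaluate_frozen(model, norm, labels, include_normals=False)
        widened = evaluate_frozen(model, all_norm, all_labels, include_normals=True)
        assert widened.auc >= base.auc - 1e-12

    def test_missing_panel_mirna_errors(self):
        norm, labels, model = self._setup(seed=3)
        with pytest.raises(KeyError):
            evaluate_frozen(model, norm.drop(columns=["a"]), labels)
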