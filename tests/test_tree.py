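import json

import numpy as np
import pandas as pd
import pytest

from exonflow import (
    TreeConfig,
    association_pvalue,
    best_split,
    grow_tree,
    select_variable,
    suggest_groups,
)

CFG = TreeConfig(n_permutations=999, seed=42)


def _samples(n):
    return pd.Index([f"S{i}" for i in range(n)])


class TestAssociation:
    def test_perfect_association_hits_floor(self):
        idx = _samples(30)
        y = pd.Series(np.arange(30, dtype=float), index=idx)
        p = association_pvalue(y, y, CFG)
        assert p == 1 / (CFG.n_permutations + 1)

    def test_constant_covariate_untestable(self):
        idx = _samples(20)
        y = pd.Series(np.random.default_rng(0).normal(size=20), index=idx)
        assert association_pvalue(y, pd.Series(1.0, index=idx), CFG) == 1.0
        assert association_pvalue(y, pd.Series("M", index=idx), CFG) == 1.0

    def test_binary_covariate_with_strong_effect(self, rng):
        idx = _samples(40)
        g = pd.Series(["M"] * 20 + ["F"] * 20, index=idx)
        y = pd.Series(np.where(g == "M", 3.0, 0.0) + rng.normal(0, 0.5, 40), index=idx)
        assert association_pvalue(y, g, CFG) < 0.01

    def test_type_one_error_calibrated(self, rng):
        cfg = TreeConfig(n_permutations=199, seed=0)
        idx = _samples(25)
        x = pd.Series(rng.normal(size=25), index=idx)
        rejections = 0
        n_sim = 1000
        for i in range(n_sim):
            y = pd.Series(rng.normal(size=25), index=idx)
            rejections += association_pvalue(y, x, cfg, rng=rng) <= 0.05
        assert 0.035 <= rejections / n_sim <= 0.065


class TestSelectVariable:
    def test_single_covariate_adjustment_is_identity(self, rng):
        idx = _samples(30)
        x = pd.Series(rng.normal(size=30), index=idx)
        y = pd.Series(x + rng.normal(0, 0.3, 30), index=idx)
        cov = pd.DataFrame({"x": x})
        seeded = np.random.default_rng(1)
        raw = association_pvalue(y, x, CFG, rng=np.random.default_rng(1))
        name, adj = select_variable(y, cov, CFG, rng=seeded)
        assert name == "x" and adj == raw

    def test_strong_covariate_wins(self, rng):
        idx = _samples(60)
        sigma = 1.0
        cov = pd.DataFrame(
            {
                "a": rng.normal(size=60),
                "signal": rng.normal(size=60),
                "b": rng.normal(size=60),
            },
            index=idx,
        )
        y = pd.Series(3 * sigma * cov["signal"] + rng.normal(0, sigma, 60), index=idx)
        name, adj = select_variable(y, cov, CFG)
        assert name == "signal" and adj < 0.05

    def test_noise_usually_stops(self, rng):
        idx = _samples(30)
        cov = pd.DataFrame({"x": rng.normal(size=30), "g": rng.choice(["a", "b"], 30)},
                           index=idx)
        cfg = TreeConfig(n_permutations=199, seed=0)
        stops = sum(
            select_variable(pd.Series(rng.normal(size=30), index=idx), cov, cfg, rng=rng)
            is None
            for _ in range(200)
        )
        assert stops / 200 > 0.90


class TestBestSplit:
    def test_binary_covariate_splits_by_value(self, rng):
        idx = _samples(20)
        g = pd.Series(["M"] * 10 + ["F"] * 10, index=idx)
        y = pd.Series(np.where(g == "M", 1.0, 0.0) + rng.normal(0, 0.1, 20), index=idx)
        split = best_split(y, g, CFG)
        assert split.kind == "categorical"
        assert {split.left_levels, split.right_levels} == {("F",), ("M",)}

    def test_numeric_threshold_matches_enumeration(self, rng):
        cfg = TreeConfig(n_permutations=999, min_leaf_size=1, seed=0)
        idx = _samples(6)
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=idx)
        y = pd.Series([0.1, 0.2, 0.3, 1.1, 1.2, 1.3], index=idx)
        split = best_split(y, x, cfg)

        def f_of(thr):
            left = x <= thr
            a, b = y[left], y[~left]
            grand = y.mean()
            ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return ssb / (ssw / (len(y) - 2)) if ssw > 0 else np.inf

        thresholds = [1.5, 2.5, 3.5, 4.5, 5.5]
        best = max(thresholds, key=f_of)
        assert split.threshold == best == 3.5

    def test_age_step_recovered(self, rng):
        idx = _samples(60)
        age = pd.Series(rng.integers(40, 81, 60).astype(float), index=idx)
        y = pd.Series(2.0 * (age > 60) + rng.normal(0, 0.1, 60), index=idx)
        split = best_split(y, age, CFG)
        assert 58 <= split.threshold <= 62

    def test_min_leaf_size_respected(self):
        idx = _samples(8)
        x = pd.Series(np.arange(8, dtype=float), index=idx)
        y = pd.Series([0.0] * 4 + [1.0] * 4, index=idx)
        split = best_split(y, x, TreeConfig(min_leaf_size=5, seed=0))
        assert split is None


class TestGrowTree:
    def test_planted_gender_effect_gives_depth_one_tree(self, rng):
        idx = _samples(60)
        gender = pd.Series(rng.choice(["M", "F"], 60), index=idx)
        age = pd.Series(rng.integers(40, 81, 60).astype(float), index=idx)
        y = pd.Series(np.where(gender == "M", 2.0, 0.0) + rng.normal(0, 0.5, 60), index=idx)
        cov = pd.DataFrame({"gender": gender, "age": age})
        tree = grow_tree(y, cov, CFG)
        assert tree.variable == "gender"
        assert tree.adjusted_p <= CFG.alpha
        assert tree.left.kind == "leaf" and tree.right.kind == "leaf"

    def test_leaves_partition_root_samples(self, rng):
        idx = _samples(120)
        cov = pd.DataFrame(
            {
                "condition": rng.choice(["normal", "pathological"], 120),
                "age": rng.integers(40, 81, 120).astype(float),
            },
            index=idx,
        )
        y = pd.Series(
            2.0 * (cov["condition"] == "pathological")
            + 2.0 * (cov["age"] > 60)
            + rng.normal(0, 0.5, 120),
            index=idx,
        )
        tree = grow_tree(y, cov, CFG)
        labels, _ = suggest_groups(tree, cov)
        assert labels.notna().all()
        counts = labels.value_counts()
        assert counts.sum() == 120
        assert counts.min() >= CFG.min_leaf_size

    def test_determinism_given_seed(self, rng):
        idx = _samples(50)
        cov = pd.DataFrame(
            {"gender": rng.choice(["M", "F"], 50), "age": rng.normal(60, 10, 50)},
            index=idx,
        )
        y = pd.Series(2.0 * (cov["gender"] == "M") + rng.normal(0, 1, 50), index=idx)
        t1 = grow_tree(y, cov, CFG)
        t2 = grow_tree(y, cov, CFG)
        assert json.loads(t1.to_json()) == json.loads(t2.to_json())

    def test_tiny_root_yields_single_leaf(self, rng):
        idx = _samples(6)
        cov = pd.DataFrame({"age": rng.normal(60, 5, 6)}, index=idx)
        y = pd.Series(rng.normal(size=6), index=idx)
        tree = grow_tree(y, cov, CFG)
        assert tree.kind == "leaf" and tree.n == 6

    def test_missing_covariate_values_follow_larger_child(self, rng):
        idx = _samples(60)
        gender = pd.Series(rng.choice(["M", "F"], 60), index=idx)
        y = pd.Series(np.where(gender == "M", 3.0, 0.0) + rng.normal(0, 0.5, 60), index=idx)
        gender_missing = gender.copy()
        gender_missing.iloc[:3] = None
        cov = pd.DataFrame({"gender": gender_missing})
        tree = grow_tree(y, cov, CFG)
        labels, _ = suggest_groups(tree, cov)
        assert labels.notna().all()
        assert tree.left.n + tree.right.n == 60


class TestSuggestGroups:
    def test_single_leaf_tree_labels_everyone_all(self, rng):
        idx = _samples(20)
        cov = pd.DataFrame({"age": rng.normal(60, 5, 20)}, index=idx)
        y = pd.Series(rng.normal(size=20), index=idx)
        tree = grow_tree(y, cov, CFG)
        labels, rules = suggest_groups(tree, cov)
        assert labels.nunique() == 1
        assert rules == {tree.node_id: "all"}

    def test_depth_one_gender_tree_matches_gender(self, rng):
        idx = _samples(60)
        gender = pd.Series(rng.choice(["M", "F"], 60), index=idx)
        y = pd.Series(np.where(gender == "M", 3.0, 0.0) + rng.normal(0, 0.3, 60), index=idx)
        cov = pd.DataFrame({"gender": gender})
        tree = grow_tree(y, cov, CFG)
        labels, rules = suggest_groups(tree, cov)
        rendered = labels.map(rules)
        assert (rendered == "gender=" + gender).all()

    def test_rule_replay_matches_assignment(self, rng):
        """Re-evaluating the printed rules by hand reproduces every
        sample's group."""
        idx = _samples(120)
        gender = pd.Series(rng.choice(["M", "F"], 120), index=idx)
        age = pd.Series(rng.integers(40, 81, 120).astype(float), index=idx)
        y = pd.Series(
            3.0 * (gender == "M") + 2.0 * (age > 60) + rng.normal(0, 0.5, 120),
            index=idx,
        )
        cov = pd.DataFrame({"gender": gender, "age": age})
        tree = grow_tree(y, cov, CFG)
        assert tree.max_depth() >= 2
        labels, rules = suggest_groups(tree, cov)

        def holds(clause, sample):
            if clause == "all":
                return True
            name, op, value = None, None, None
            for cand_op in ("<=", ">", "="):
                if cand_op in clause:
                    name, _, value = clause.partition(cand_op)
                    op = cand_op
                    break
            v = cov.at[sample, name]
            if op == "<=":
                return v <= float(value)
            if op == ">":
                return v > float(value)
            return str(v) in value.split(",")

        for sample in idx:
            rule = rules[labels[sample]]
            assert all(holds(c, sample) for c in rule.split(" AND "))
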