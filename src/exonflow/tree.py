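"""Multivariate splicing analysis by conditional-inference trees.

For a probeset of interest, the tree regresses its cluster-normalized
expression on the available clinical covariates (condition, gender, age
of onset, stage, ...) by binary recursive partitioning in a conditional
inference framework:

1. test the global null hypothesis of independence between the response
   and every covariate; stop when it cannot be rejected;
2. select the covariate with the strongest association (smallest
   Bonferroni-adjusted permutation p-value);
3. split on that covariate — at its two values for a binary variable, at
   the ANOVA-F-optimal threshold for a numeric one — and recurse into
   both children.

Association p-values come from permutation tests of the response
(statistic: |Pearson correlation| for numeric covariates, maximum
absolute standardized group-mean deviation for categorical ones), so
numeric and symbolic covariates are handled in one framework and the
variable-selection step is separated from split-point search, avoiding
selection bias toward many-valued covariates.  Node generation and
stopping are therefore ANOVA/permutation based: a node becomes a leaf
when the adjusted p-value exceeds ``alpha``, when it is too small to
split, or at ``max_depth``.

Everything is deterministic given ``TreeConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeConfig",
    "Split",
    "TreeNode",
    "association_pvalue",
    "select_variable",
    "best_split",
    "grow_tree",
    "suggest_groups",
]


@dataclass(frozen=True)
class TreeConfig:
    """Tuning parameters of the tree.

    alpha: significance level for the global independence test at each
    node.  n_permutations: Monte-Carlo permutations per association test
    (the smallest attainable p is 1/(n_permutations+1)).  min_node_size:
    do not attempt to split smaller nodes; min_leaf_size: smallest
    admissible child.  seed: drives all permutation draws.
    """

    alpha: float = 0.05
    n_permutations: int = 9999
    min_node_size: int = 10
    min_leaf_size: int = 5
    max_depth: int = 4
    seed: int = 0

    def validate(self) -> "TreeConfig":
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        return self


@dataclass(frozen=True)
class Split:
    """A binary split: numeric threshold (go left when value <= threshold)
    or a two-group partition of categorical levels."""

    kind: str  # "numeric" | "categorical"
    threshold: float | None = None
    left_levels: tuple[str, ...] = ()
    right_levels: tuple[str, ...] = ()

    def goes_left(self, values: pd.Series) -> pd.Series:
        if self.kind == "numeric":
            return pd.to_numeric(values, errors="coerce") <= self.threshold
        return values.isin(self.left_levels)

    def describe(self, variable: str) -> tuple[str, str]:
        if self.kind == "numeric":
            return f"{variable}<={self.threshold:g}", f"{variable}>{self.threshold:g}"
        left = ",".join(self.left_levels)
        right = ",".join(self.right_levels)
        return f"{variable}={left}", f"{variable}={right}"


@dataclass
class TreeNode:
    node_id: int
    n: int
    mean: float
    variance: float
    depth: int
    variable: str | None = None
    adjusted_p: float | None = None
    split: Split | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def kind(self) -> str:
        return "leaf" if self.split is None else "internal"

    def leaves(self) -> list["TreeNode"]:
        if self.kind == "leaf":
            return [self]
        return self.left.leaves() + self.right.leaves()

    def max_depth(self) -> int:
        if self.kind == "leaf":
            return self.depth
        return max(self.left.max_depth(), self.right.max_depth())

    def to_dict(self) -> dict:
        out = {
            "node_id": self.node_id,
            "kind": self.kind,
            "n": self.n,
            "mean": self.mean,
            "variance": self.variance,
        }
        if self.kind == "internal":
            out["variable"] = self.variable
            out["adjusted_p"] = self.adjusted_p
            if self.split.kind == "numeric":
                out["split"] = {"kind": "numeric", "threshold": self.split.threshold}
            else:
                out["split"] = {
                    "kind": "categorical",
                    "left_levels": list(self.split.left_levels),
                    "right_levels": list(self.split.right_levels),
                }
            out["left"] = self.left.to_dict()
            out["right"] = self.right.to_dict()
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _is_numeric(covariate: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(covariate)


def _permutation_matrix(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    """n_perm independent permutations of range(n), one per row."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def association_pvalue(
    response: np.ndarray | pd.Series,
    covariate: pd.Series,
    config: TreeConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for association between response and one
    covariate.

    Statistic: |Pearson r| (numeric covariate) or the maximum over
    levels of |group mean - grand mean| * sqrt(n_level) / sd (categorical).
    p = (1 + #{permuted >= observed}) / (n_permutations + 1).  A constant
    covariate (or constant response) is untestable and returns p = 1.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n < 3:
        return 1.0
    sy = y.std()
    if sy == 0:
        return 1.0
    yc = (y - y.mean()) / sy

    if _is_numeric(covariate):
        x = np.asarray(covariate, dtype=float)
        sx = x.std()
        if sx == 0:
            return 1.0
        xc = (x - x.mean()) / sx
        observed = abs(float(yc @ xc)) / n
        perms = _permutation_matrix(rng, config.n_permutations, n)
        stats = np.abs(yc[perms] @ xc) / n
    else:
        codes, _ = pd.factorize(covariate, sort=True)
        levels = np.unique(codes)
        if len(levels) < 2:
            return 1.0
        onehot = (codes[:, None] == levels[None, :]).astype(float)
        counts = onehot.sum(axis=0)
        scale = np.sqrt(counts)
        observed = float(np.max(np.abs(yc @ onehot / counts) * scale))
        perms = _permutation_matrix(rng, config.n_permutations, n)
        group_means = yc[perms] @ onehot / counts
        stats = np.max(np.abs(group_means) * scale, axis=1)

    exceed = int((stats >= observed - 1e-12).sum())
    return (1 + exceed) / (config.n_permutations + 1)


def _testable(covariate: pd.Series) -> bool:
    non_missing = covariate.dropna()
    return non_missing.nunique() >= 2


def select_variable(
    response: pd.Series,
    covariates: pd.DataFrame,
    config: TreeConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, float] | None:
    """Global independence test at a node.

    Each testable covariate gets a permutation p-value (samples missing
    that covariate are excluded from its test); p-values are Bonferroni
    adjusted by the number of testable covariates.  Returns the
    (variable, adjusted p) with the smallest adjusted p when it is <=
    alpha, ties broken by declared covariate order; otherwise ``None``
    (the stop signal).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    testable = [c for c in covariates.columns if _testable(covariates[c])]
    if not testable:
        return None
    raw: dict[str, float] = {}
    for name in testable:
        col = covariates[name]
        mask = col.notna().to_numpy()
        raw[name] = association_pvalue(
            response.to_numpy()[mask], col[mask], config, rng=rng
        )
    m = len(testable)
    adjusted = {name: min(1.0, p * m) for name, p in raw.items()}
    best = min(testable, key=lambda name: adjusted[name])
    if adjusted[best] > config.alpha:
        return None
    return best, adjusted[best]


def _anova_f(y: np.ndarray, left: np.ndarray) -> float:
    """Two-sample one-way ANOVA F for a candidate binary partition."""
    a, b = y[left], y[~left]
    na, nb = len(a), len(b)
    grand = y.mean()
    ssb = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return float(ssb / (ssw / (na + nb - 2)))


def best_split(
    response: pd.Series,
    covariate: pd.Series,
    config: TreeConfig,
) -> Split | None:
    """ANOVA-F-optimal binary split on an already-selected covariate.

    Numeric: candidate thresholds are midpoints between consecutive
    sorted unique values; the F-maximizing threshold wins, smallest
    threshold on ties, subject to both children holding at least
    ``min_leaf_size`` samples.  Categorical with two levels: split by
    value.  With k in (2, 8] levels: the best of all 2^(k-1) - 1 binary
    partitions.  Returns ``None`` when no admissible split exists.
    """
    y = np.asarray(response, dtype=float)
    if _is_numeric(covariate):
        x = np.asarray(covariate, dtype=float)
        uniq = np.unique(x)
        if len(uniq) < 2:
            return None
        thresholds = (uniq[:-1] + uniq[1:]) / 2.0
        best_f, best_thr = -np.inf, None
        for thr in thresholds:
            left = x <= thr
            if left.sum() < config.min_leaf_size or (~left).sum() < config.min_leaf_size:
                continue
            f = _anova_f(y, left)
            if f > best_f:  # strict: ties keep the smallest threshold
                best_f, best_thr = f, thr
        if best_thr is None:
            return None
        return Split(kind="numeric", threshold=float(best_thr))

    levels = sorted(covariate.dropna().unique(), key=str)
    k = len(levels)
    if k < 2:
        return None
    if k > 8:
        raise ValueError(f"categorical covariate with {k} > 8 levels is not supported")
    codes = pd.Categorical(covariate, categories=levels).codes
    best_f, best_part = -np.inf, None
    # enumerate binary partitions; fix level 0 on the left to halve the count
    for pattern in range(2 ** (k - 1)):
        left_set = [0] + [i for i in range(1, k) if (pattern >> (i - 1)) & 1]
        if len(left_set) == k:
            continue
        left = np.isin(codes, left_set)
        if left.sum() < config.min_leaf_size or (~left).sum() < config.min_leaf_size:
            continue
        f = _anova_f(y, left)
        if f > best_f:
            best_f, best_part = f, left_set
    if best_part is None:
        return None
    left_levels = tuple(levels[i] for i in best_part)
    right_levels = tuple(l for i, l in enumerate(levels) if i not in best_part)
    return Split(kind="categorical", left_levels=left_levels, right_levels=right_levels)


def grow_tree(
    response: pd.Series,
    covariates: pd.DataFrame,
    config: TreeConfig = TreeConfig(),
) -> TreeNode:
    """Fit a conditional-inference tree for one probeset's normalized
    expression against the clinical covariates.

    ``response`` and ``covariates`` share their sample index.  Samples
    missing a covariate's value are excluded from that covariate's test
    and, if it is chosen for splitting, assigned to the larger child.
    A root that cannot be split (too few samples, or independence not
    rejected) yields a single-leaf tree — a valid outcome.
    """
    config.validate()
    covariates = covariates.loc[response.index]
    counter = {"next_id": 0}
    # one child seed per split attempt; a depth-4 binary tree has < 64 nodes
    seeds = iter(np.random.SeedSequence(config.seed).spawn(64))

    def build(idx: pd.Index, depth: int) -> TreeNode:
        y = response.loc[idx]
        node = TreeNode(
            node_id=counter["next_id"],
            n=len(idx),
            mean=float(y.mean()) if len(idx) else float("nan"),
            variance=float(y.var(ddof=1)) if len(idx) > 1 else 0.0,
            depth=depth,
        )
        counter["next_id"] += 1
        if len(idx) < config.min_node_size or depth >= config.max_depth:
            return node
        rng = np.random.default_rng(next(seeds))
        chosen = select_variable(y, covariates.loc[idx], config, rng=rng)
        if chosen is None:
            return node
        variable, adj_p = chosen
        col = covariates.loc[idx, variable]
        present = col.notna()
        split = best_split(y.loc[present[present].index], col.dropna(), config)
        if split is None:
            return node
        left_mask = split.goes_left(col)
        left_idx = idx[(left_mask & present).to_numpy()]
        right_idx = idx[(~left_mask & present).to_numpy()]
        missing_idx = idx[(~present).to_numpy()]
        if len(missing_idx):
            if len(left_idx) >= len(right_idx):
                left_idx = left_idx.append(missing_idx)
            else:
                right_idx = right_idx.append(missing_idx)
        if len(left_idx) < config.min_leaf_size or len(right_idx) < config.min_leaf_size:
            return node
        node.variable = variable
        node.adjusted_p = adj_p
        node.split = split
        node.left = build(left_idx, depth + 1)
        node.right = build(right_idx, depth + 1)
        return node

    return build(response.index, 0)


def suggest_groups(
    tree: TreeNode,
    covariates: pd.DataFrame,
) -> tuple[pd.Series, dict[int, str]]:
    """Assign every sample to its leaf and render the leaf rules.

    Returns (labels, rules): ``labels`` maps sample id -> leaf node id
    (a single-leaf tree labels every sample with the root), ``rules``
    maps leaf id -> a human-readable conjunction such as
    ``"gender=M AND age>60"`` (the root rule is ``"all"``).  The labels
    are usable as experimental groups for re-running exon statistics.
    """
    labels = pd.Series(index=covariates.index, dtype=object)
    rules: dict[int, str] = {}

    def walk(node: TreeNode, idx: pd.Index, clauses: list[str]) -> None:
        if node.kind == "leaf":
            labels.loc[idx] = node.node_id
            rules[node.node_id] = " AND ".join(clauses) if clauses else "all"
            return
        col = covariates.loc[idx, node.variable]
        present = col.notna()
        left_mask = node.split.goes_left(col)
        left_idx = idx[(left_mask & present).to_numpy()]
        right_idx = idx[(~left_mask & present).to_numpy()]
        missing_idx = idx[(~present).to_numpy()]
        if len(missing_idx):
            if node.left.n >= node.right.n:
                left_idx = left_idx.append(missing_idx)
            else:
                right_idx = right_idx.append(missing_idx)
        left_desc, right_desc = node.split.describe(node.variable)
        walk(node.left, left_idx, clauses + [left_desc])
        walk(node.right, right_idx, clauses + [right_desc])

    walk(tree, covariates.index, [])
    return labels, rules
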