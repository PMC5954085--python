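"""Entropy-based classification trees with boosting over two features.

Features are the fuzzy name-similarity score and the percent energy
difference (which may be missing).  Trees split on gain ratio with midpoint
thresholds, are pruned with a pessimistic binomial error estimate, and are
combined by deterministic adaptive boosting.  The ensemble outputs the
probability that a candidate match is plausible.

Missing feature values are routed down both branches with fractional
weight, so the model stays usable when energy content is unknown.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import beta as _beta_dist

__all__ = [
    "TrainingPair",
    "TreeNode",
    "BoostedTreeModel",
    "SplitCandidate",
    "entropy",
    "best_split",
    "grow_tree",
    "prune",
    "fit_boosted",
    "fit_or_rule_boundary",
    "predict_proba",
]

FEATURES = ("fuzzy_score", "ediff")
LABELS = ("non_plausible", "plausible")


@dataclass(frozen=True)
class TrainingPair:
    """One annotated (query, candidate) pair: two features and a label."""

    fuzzy_score: float
    ediff: Optional[float]  # None/NaN when undefined
    label: str  # "plausible" or "non_plausible"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a class-count vector; 0*log0 = 0."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an empty (all-zero) count vector is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


class SplitCandidate(NamedTuple):
    threshold: float
    gain_ratio: float
    gain: float


@dataclass
class TreeNode:
    """A node of a binary decision tree.

    Every node carries the weighted per-class counts of the training
    records that reached it ([non_plausible, plausible]).  Internal nodes
    test ``feature <= threshold`` (left on true) and remember the fraction
    of defined-feature weight routed left, used for missing values.
    """

    counts: np.ndarray
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    left_frac: float = 0.5

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()

    def leaf_probability(self) -> float:
        """Laplace-corrected fraction of the plausible class."""
        c0, c1 = float(self.counts[0]), float(self.counts[1])
        return (c1 + 1.0) / (c0 + c1 + 2.0)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"counts": [float(c) for c in self.counts]}
        return {
            "counts": [float(c) for c in self.counts],
            "feature": FEATURES[self.feature],
            "threshold": float(self.threshold),
            "left_frac": float(self.left_frac),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        counts = np.asarray(d["counts"], dtype=float)
        if "feature" not in d:
            return cls(counts=counts)
        return cls(
            counts=counts,
            feature=FEATURES.index(d["feature"]),
            threshold=float(d["threshold"]),
            left_frac=float(d.get("left_frac", 0.5)),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _as_arrays(
    pairs: Iterable[TrainingPair | tuple],
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 2) feature matrix with NaN for missing, and 0/1 label vector."""
    X, y = [], []
    for p in pairs:
        if isinstance(p, TrainingPair):
            fuzzy, ediff, label = p.fuzzy_score, p.ediff, p.label
        else:
            fuzzy, ediff, label = p
        e = math.nan if ediff is None else float(ediff)
        X.append((float(fuzzy), e))
        y.append(label if isinstance(label, (int, np.integer)) else LABELS.index(label))
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def best_split(
    x: np.ndarray,
    y: np.ndarray,
    w: Optional[np.ndarray] = None,
    min_cases: float = 2.0,
) -> Optional[SplitCandidate]:
    """Best binary split of one feature by gain ratio.

    Records where ``x`` is NaN are ignored.  Candidate thresholds are the
    midpoints between consecutive distinct sorted values; both children
    must carry at least ``min_cases`` weight.  Ties break to the smaller
    threshold.  Returns None when no candidate threshold exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    defined = ~np.isnan(x)
    x, y, w = x[defined], y[defined], w[defined]
    if x.size < 2:
        return None
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    cum1 = np.cumsum(ws * (ys == 1))
    cum0 = np.cumsum(ws * (ys == 0))
    tot0, tot1 = cum0[-1], cum1[-1]
    W = tot0 + tot1
    parent_h = entropy([tot0, tot1])
    boundaries = np.nonzero(xs[:-1] != xs[1:])[0]
    if boundaries.size == 0:
        return None
    wl0, wl1 = cum0[boundaries], cum1[boundaries]
    wl = wl0 + wl1
    wr = W - wl
    ok = (wl >= min_cases) & (wr >= min_cases)
    if not np.any(ok):
        return None
    boundaries, wl0, wl1, wl, wr = boundaries[ok], wl0[ok], wl1[ok], wl[ok], wr[ok]

    def _plogp(p: np.ndarray) -> np.ndarray:
        out = np.zeros_like(p)
        np.log2(p, out=out, where=p > 0)
        return p * out

    def _h2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        tot = np.maximum(a + b, 1e-300)
        return -(_plogp(a / tot) + _plogp(b / tot))

    gain = parent_h - (wl * _h2(wl0, wl1) + wr * _h2(tot0 - wl0, tot1 - wl1)) / W
    split_info = _h2(wl, wr)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(split_info > 0, gain / split_info, 0.0)
    # argmax takes the first (= smallest threshold) among near-ties
    i_best = int(np.argmax(ratio > ratio.max() - 1e-12))
    i = boundaries[i_best]
    return SplitCandidate(
        threshold=float((xs[i] + xs[i + 1]) / 2.0),
        gain_ratio=float(ratio[i_best]),
        gain=float(gain[i_best]),
    )


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    w: Optional[np.ndarray] = None,
    min_cases: float = 2.0,
    max_depth: Optional[int] = None,
    _depth: int = 0,
) -> TreeNode:
    """Grow an unpruned tree by recursive gain-ratio splitting.

    Stops on purity, ``min_cases``, ``max_depth`` or when no split has
    positive gain ratio.  Records missing the chosen feature descend both
    branches with weight proportional to the defined branch weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    w = np.ones(len(y), dtype=float) if w is None else np.asarray(w, dtype=float)
    counts = np.array([w[y == 0].sum(), w[y == 1].sum()])
    node = TreeNode(counts=counts)
    if counts.min() == 0 or counts.sum() < 2 * min_cases:
        return node
    if max_depth is not None and _depth >= max_depth:
        return node
    best_feature, best_cand = None, None
    for f in range(X.shape[1]):
        cand = best_split(X[:, f], y, w, min_cases=min_cases)
        if cand is None or cand.gain_ratio <= 1e-12:
            continue
        if best_cand is None or cand.gain_ratio > best_cand.gain_ratio + 1e-12:
            best_feature, best_cand = f, cand
    if best_cand is None:
        return node
    xf = X[:, best_feature]
    missing = np.isnan(xf)
    go_left = xf <= best_cand.threshold
    wl_def = w[~missing & go_left].sum()
    wr_def = w[~missing & ~go_left].sum()
    left_frac = wl_def / (wl_def + wr_def)

    def _branch(side_mask: np.ndarray, frac: float):
        keep = (side_mask & ~missing) | missing
        wb = w[keep].copy()
        wb[np.isnan(xf[keep])] *= frac
        return X[keep], y[keep], wb

    Xl, yl, wl = _branch(go_left, left_frac)
    Xr, yr, wr = _branch(~go_left, 1.0 - left_frac)
    node.feature = best_feature
    node.threshold = best_cand.threshold
    node.left_frac = float(left_frac)
    node.left = grow_tree(Xl, yl, wl, min_cases, max_depth, _depth + 1)
    node.right = grow_tree(Xr, yr, wr, min_cases, max_depth, _depth + 1)
    return node


def _upper_error_rate(errors: float, n: float, confidence: float) -> float:
    """Pessimistic (binomial upper-limit) error rate of a leaf.

    ``confidence`` is the tail probability: smaller values are more
    pessimistic; 1.0 reduces to the empirical rate.
    """
    if n <= 0:
        return 0.0
    empirical = errors / n
    if n - errors <= 0:
        return 1.0
    upper = float(_beta_dist.ppf(1.0 - confidence, errors + 1.0, n - errors))
    return max(empirical, upper)


def _estimated_errors(node: TreeNode, confidence: float) -> float:
    n = float(node.counts.sum())
    e = n - float(node.counts.max())
    return n * _upper_error_rate(e, n, confidence)


def _subtree_estimated_errors(node: TreeNode, confidence: float) -> float:
    if node.is_leaf:
        return _estimated_errors(node, confidence)
    return _subtree_estimated_errors(node.left, confidence) + _subtree_estimated_errors(
        node.right, confidence
    )


def prune(tree: TreeNode, confidence: float = 0.25) -> TreeNode:
    """Pessimistic-error pruning (bottom-up subtree collapse).

    A subtree becomes a leaf when the collapsed leaf's estimated errors do
    not exceed the sum of its leaves' estimates.
    """
    if tree.is_leaf:
        return tree
    tree.left = prune(tree.left, confidence)
    tree.right = prune(tree.right, confidence)
    if _estimated_errors(tree, confidence) <= _subtree_estimated_errors(tree, confidence) + 1e-12:
        return TreeNode(counts=tree.counts)
    return tree


def _tree_proba(node: TreeNode, fuzzy: float, ediff: float) -> float:
    """P(plausible) from one tree, with fractional missing-value routing."""
    if node.is_leaf:
        return node.leaf_probability()
    x = fuzzy if node.feature == 0 else ediff
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return node.left_frac * _tree_proba(node.left, fuzzy, ediff) + (
            1.0 - node.left_frac
        ) * _tree_proba(node.right, fuzzy, ediff)
    if x <= node.threshold:
        return _tree_proba(node.left, fuzzy, ediff)
    return _tree_proba(node.right, fuzzy, ediff)


@dataclass
class BoostedTreeModel:
    """Ordered ensemble of pruned trees with positive stage weights."""

    trees: list = field(default_factory=list)
    stage_weights: list = field(default_factory=list)
    n_trials: int = 10
    name_variant: str = "original"
    params: dict = field(default_factory=dict)

    def predict_proba(self, fuzzy: float, ediff: Optional[float]) -> float:
        return predict_proba(self, fuzzy, ediff)

    def predict_proba_many(
        self, fuzzy: Sequence[float], ediff: Sequence[Optional[float]]
    ) -> np.ndarray:
        return np.array([predict_proba(self, f, e) for f, e in zip(fuzzy, ediff)])

    def to_json(self, indent: int = 2) -> str:
        doc = {
            "format": "fctmap-boosted-tree",
            "version": 1,
            "name_variant": self.name_variant,
            "n_trials": self.n_trials,
            "params": self.params,
            "stage_weights": [float(a) for a in self.stage_weights],
            "trees": [t.to_dict() for t in self.trees],
        }
        return json.dumps(doc, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BoostedTreeModel":
        doc = json.loads(text)
        if doc.get("format") != "fctmap-boosted-tree":
            raise ValueError("not a fctmap model document")
        return cls(
            trees=[TreeNode.from_dict(t) for t in doc["trees"]],
            stage_weights=list(doc["stage_weights"]),
            n_trials=int(doc["n_trials"]),
            name_variant=doc["name_variant"],
            params=doc.get("params", {}),
        )


def fit_boosted(
    pairs: Iterable[TrainingPair | tuple],
    n_trials: int = 10,
    min_cases: float = 2.0,
    max_depth: Optional[int] = None,
    confidence: float = 0.25,
    name_variant: str = "original",
) -> BoostedTreeModel:
    """Fit a boosted tree ensemble by deterministic adaptive reweighting.

    Each stage fits a pruned tree on the weighted data, is weighted by
    ``log((1 - err) / err)`` and multiplies the weight of misclassified
    records by ``exp(stage_weight)``.  Stops early when a stage's weighted
    error reaches 0 (perfect) or 0.5 (uninformative).  No randomness: the
    result depends only on the data order and the parameters.
    """
    X, y = _as_arrays(pairs)
    if len(y) == 0:
        raise ValueError("no training pairs")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    n = len(y)
    w = np.ones(n, dtype=float)
    model = BoostedTreeModel(
        n_trials=n_trials,
        name_variant=name_variant,
        params={"min_cases": min_cases, "max_depth": max_depth, "confidence": confidence},
    )
    for _ in range(n_trials):
        tree = prune(grow_tree(X, y, w, min_cases=min_cases, max_depth=max_depth), confidence)
        proba = np.array([_tree_proba(tree, X[i, 0], X[i, 1]) for i in range(n)])
        pred = (proba >= 0.5).astype(int)
        err = float(w[pred != y].sum() / w.sum())
        if err >= 0.5:
            if not model.trees:  # keep something usable, equivalent to one tree
                model.trees.append(tree)
                model.stage_weights.append(1.0)
            break
        if err == 0.0:
            model.trees.append(tree)
            model.stage_weights.append(math.log((1.0 - 1e-10) / 1e-10))
            break
        alpha = math.log((1.0 - err) / err)
        model.trees.append(tree)
        model.stage_weights.append(alpha)
        w = w * np.exp(alpha * (pred != y))
        w *= n / w.sum()
    return model


def fit_or_rule_boundary(model: BoostedTreeModel, step: float = 1.0) -> tuple[float, float]:
    """Best (t1, t2) such that the model's decisions match the rule
    ``plausible iff (fuzzy > t1) or (ediff < t2)`` on a dense feature grid.

    Model-inspection utility: evaluates the fitted decision surface on a
    regular grid and minimizes grid disagreement with the two-threshold OR
    rule (the rule's complement is the rectangle fuzzy <= t1, ediff >= t2,
    so the search is a vectorized prefix-sum scan).
    """
    grid = np.arange(0.0, 100.0 + step, step)
    pred = np.empty((grid.size, grid.size))
    for i, f in enumerate(grid):
        for j, e in enumerate(grid):
            pred[i, j] = predict_proba(model, float(f), float(e)) >= 0.5
    total = pred.sum()
    n_cells = pred.size
    # rect_p[i, j] = sum of pred over {fuzzy <= grid[i], ediff >= grid[j]}
    rect_p = np.cumsum(pred, axis=0)[:, ::-1].cumsum(axis=1)[:, ::-1]
    rows = np.arange(1, grid.size + 1)[:, None]
    cols = np.arange(grid.size, 0, -1)[None, :]
    rect_n = rows * cols
    mismatch = (n_cells - rect_n) - (total - rect_p) + rect_p
    i1, j2 = np.unravel_index(int(np.argmin(mismatch)), mismatch.shape)
    return float(grid[i1]), float(grid[j2])


def predict_proba(model: BoostedTreeModel, fuzzy: float, ediff: Optional[float]) -> float:
    """Stage-weight-normalized average of the trees' leaf probabilities."""
    if not model.trees:
        raise ValueError("model has no trees; fit it first")
    e = math.nan if ediff is None else float(ediff)
    total_w = sum(model.stage_weights)
    p = sum(
        a * _tree_proba(t, float(fuzzy), e) for t, a in zip(model.trees, model.stage_weights)
    )
    return float(p / total_w)
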