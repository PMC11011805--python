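"""Local decision-tree surrogate on the latent neighborhood.

A CART tree is fitted to (latents, black-box labels); the factual rule
r is the root-to-leaf path of z with per-feature bounds merged, and the
counterfactual rules Phi are the path rules of every leaf predicting a
different class, ordered by how few of their premises z violates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier

from .neighborhood import Neighborhood

__all__ = [
    "PremiseCondition", "DecisionRule", "LatentSurrogateTree",
    "fit_surrogate", "extract_rule", "extract_counterfactual_rules",
    "surrogate_fidelity",
]


@dataclass(frozen=True)
class PremiseCondition:
    """One split condition: latent feature `op` threshold."""

    feature_index: int
    op: str                  # "<=" or ">"
    threshold: float

    def __post_init__(self):
        if self.op not in ("<=", ">"):
            raise ValueError("op must be '<=' or '>'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.feature_index < 0:
            raise ValueError("feature_index must be >= 0")

    def satisfied_by(self, z: np.ndarray) -> bool:
        v = z[self.feature_index]
        return v <= self.threshold if self.op == "<=" else v > self.threshold

    def to_dict(self) -> dict:
        return {"f": self.feature_index, "op": self.op, "t": self.threshold}

    @classmethod
    def from_dict(cls, d: dict) -> "PremiseCondition":
        return cls(int(d["f"]), str(d["op"]), float(d["t"]))


@dataclass(frozen=True)
class DecisionRule:
    """Conjunction of premises implying a class."""

    premises: tuple[PremiseCondition, ...]
    outcome: int

    def __post_init__(self):
        lo: dict[int, float] = {}
        hi: dict[int, float] = {}
        for p in self.premises:
            if p.op == ">":
                lo[p.feature_index] = max(lo.get(p.feature_index, -np.inf),
                                          p.threshold)
            else:
                hi[p.feature_index] = min(hi.get(p.feature_index, np.inf),
                                          p.threshold)
        for f in set(lo) & set(hi):
            if lo[f] >= hi[f]:
                raise ValueError(f"contradictory premises on feature {f}")

    def satisfied_by(self, z: np.ndarray) -> bool:
        return all(p.satisfied_by(z) for p in self.premises)

    def n_violated(self, z: np.ndarray) -> int:
        return sum(not p.satisfied_by(z) for p in self.premises)

    def boundary_distance(self, z: np.ndarray) -> float:
        """Euclidean distance from z to the rule's satisfying box
        (clamped projection onto the axis-aligned region)."""
        d2 = 0.0
        for p in self.premises:
            if not p.satisfied_by(z):
                d2 += (z[p.feature_index] - p.threshold) ** 2
        return float(np.sqrt(d2))

    def to_dict(self) -> dict:
        return {"premises": [p.to_dict() for p in self.premises],
                "class": int(self.outcome)}

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionRule":
        return cls(tuple(PremiseCondition.from_dict(p)
                         for p in d["premises"]), int(d["class"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def __str__(self) -> str:
        conds = ", ".join(
            f"{p.feature_index}{p.op}{p.threshold:.2f}" for p in self.premises)
        return f"{{{conds}}} -> {{class: {self.outcome}}}"


class LatentSurrogateTree(BaseEstimator, ClassifierMixin):
    """Decision-tree surrogate of the black box on a latent neighborhood.

    Wraps a CART classifier (Gini impurity, depth <= 8, >= 3 samples
    per leaf) and exposes rule extraction off its paths.
    """

    def __init__(self, max_depth: int = 8, min_samples_leaf: int = 3,
                 random_state: int = 0):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LatentSurrogateTree":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError(
                "single-label neighborhood: surrogate cannot be fitted")
        self.tree_ = DecisionTreeClassifier(
            criterion="gini", max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state).fit(X, y)
        self.classes_ = self.tree_.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree_.predict(np.atleast_2d(X))

    def rule_for(self, z: np.ndarray) -> DecisionRule:
        return extract_rule(self, z)

    def counterfactuals_for(self, z: np.ndarray,
                            r: DecisionRule | None = None
                            ) -> list[DecisionRule]:
        return extract_counterfactual_rules(self, z, r or self.rule_for(z))


def fit_surrogate(nbr: Neighborhood, seed: int,
                  max_depth: int = 8,
                  min_samples_leaf: int = 3) -> LatentSurrogateTree:
    """Fit the surrogate tree on a neighborhood's latents and labels."""
    return LatentSurrogateTree(
        max_depth=max_depth, min_samples_leaf=min_samples_leaf,
        random_state=seed).fit(nbr.latents, nbr.labels)


def _sk_tree(tree):
    t = tree.tree_ if isinstance(tree, LatentSurrogateTree) else tree
    if not hasattr(t, "tree_"):
        raise ValueError("tree is not fitted")
    return t


def _merge(conds: list[tuple[int, str, float]]) -> tuple[PremiseCondition, ...]:
    """Tightest per-feature bounds along a path, ordered by feature."""
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}
    for f, op, t in conds:
        if op == ">":
            lo[f] = max(lo.get(f, -np.inf), t)
        else:
            hi[f] = min(hi.get(f, np.inf), t)
    out = []
    for f in sorted(set(lo) | set(hi)):
        if f in lo:
            out.append(PremiseCondition(f, ">", lo[f]))
        if f in hi:
            out.append(PremiseCondition(f, "<=", hi[f]))
    return tuple(out)


def extract_rule(tree, z: np.ndarray) -> DecisionRule:
    """Factual rule: merged conditions on z's root-to-leaf path."""
    t = _sk_tree(tree)
    s = t.tree_
    z = np.asarray(z, dtype=float)
    node = 0
    conds: list[tuple[int, str, float]] = []
    while s.children_left[node] != -1:
        f, thr = int(s.feature[node]), float(s.threshold[node])
        if z[f] <= thr:
            conds.append((f, "<=", thr))
            node = s.children_left[node]
        else:
            conds.append((f, ">", thr))
            node = s.children_right[node]
    outcome = int(t.classes_[np.argmax(s.value[node])])
    return DecisionRule(_merge(conds), outcome)


def _leaf_rules(t) -> list[tuple[int, DecisionRule]]:
    """(leaf_index, path rule) for every leaf, in node order."""
    s = t.tree_
    out: list[tuple[int, DecisionRule]] = []

    def walk(node: int, conds: list) -> None:
        if s.children_left[node] == -1:
            outcome = int(t.classes_[np.argmax(s.value[node])])
            out.append((node, DecisionRule(_merge(conds), outcome)))
            return
        f, thr = int(s.feature[node]), float(s.threshold[node])
        walk(s.children_left[node], conds + [(f, "<=", thr)])
        walk(s.children_right[node], conds + [(f, ">", thr)])

    walk(0, [])
    return out


def extract_counterfactual_rules(tree, z: np.ndarray,
                                 r: DecisionRule) -> list[DecisionRule]:
    """Counterfactual rules Phi, fewest-violated-premises first.

    Ties are broken by smaller distance from z to the rule's satisfying
    region, then by leaf index.  An empty list signals a single-class
    locality.
    """
    t = _sk_tree(tree)
    z = np.asarray(z, dtype=float)
    candidates = [(rule.n_violated(z), rule.boundary_distance(z), leaf, rule)
                  for leaf, rule in _leaf_rules(t)
                  if rule.outcome != r.outcome]
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return [rule for _, _, _, rule in candidates]


def rules_for_class(tree, z: np.ndarray, cls: int) -> list[DecisionRule]:
    """Path rules of every leaf predicting ``cls``, nearest-to-z first
    (same ordering as the counterfactual ranking)."""
    t = _sk_tree(tree)
    z = np.asarray(z, dtype=float)
    candidates = [(rule.n_violated(z), rule.boundary_distance(z), leaf, rule)
                  for leaf, rule in _leaf_rules(t)
                  if rule.outcome == int(cls)]
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return [rule for _, _, _, rule in candidates]


def surrogate_fidelity(tree, nbr: Neighborhood) -> float:
    """Fraction of neighborhood instances where the tree matches the
    black-box label."""
    if len(nbr.latents) == 0:
        raise ValueError("empty neighborhood")
    pred = np.asarray(tree.predict(nbr.latents))
    return float(np.mean(pred == nbr.labels))
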