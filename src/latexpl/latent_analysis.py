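"""Latent-space structure analysis: MDS projection and pairwise class
separability.

Encoded datasets are projected to 2D/3D by metric MDS (SMACOF with a
classical-scaling start) on Euclidean latent distances; how well two
classes separate in the projection is quantified by the cross-validated
accuracy of a Random Forest (500 trees by default), mirroring how
latent class structure is probed at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import smacof
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = ["EmbeddingResult", "project_mds", "separation_accuracy"]

_MAX_POINTS = 2000   # MDS cost is O(n^2); subsample beyond this


@dataclass
class EmbeddingResult:
    coords: np.ndarray        # (n, d)
    stress: float             # normalised (Kruskal stress-1-like)
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("embedding dimension must be 2 or 3")
        if self.stress < 0:
            raise ValueError("stress must be >= 0")


def _classical_scaling(D: np.ndarray, d: int) -> np.ndarray:
    """Torgerson classical MDS: eigendecomposition of the double-centred
    squared-distance matrix; the deterministic SMACOF start."""
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:d]
    w_top = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w_top)[None, :]


def _normalised_stress(D: np.ndarray, raw_stress: float) -> float:
    total = (D ** 2).sum() / 2.0
    return float(np.sqrt(raw_stress / total)) if total > 0 else 0.0


def project_mds(latents: np.ndarray, d: int = 2,
                seed: int = 0, labels: np.ndarray | None = None,
                max_points: int = _MAX_POINTS) -> EmbeddingResult:
    """Metric MDS of latent vectors onto d in {2, 3} dimensions.

    Uses SMACOF started from the classical-scaling solution (plus, for
    d=3, a second start padding the 2D solution with a zero column so
    added dimensions can only improve the fit).  Deterministic under
    ``seed``; inputs larger than ``max_points`` are seeded-subsampled.
    """
    latents = np.asarray(latents, dtype=float)
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    n = len(latents)
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points for a {d}D embedding")
    if labels is not None:
        labels = np.asarray(labels)
    if n > max_points:
        keep = np.random.default_rng(seed).choice(n, max_points,
                                                  replace=False)
        keep.sort()
        latents = latents[keep]
        labels = labels[keep] if labels is not None else None

    D = squareform(pdist(latents))
    inits = [_classical_scaling(D, d)]
    if d == 3:
        pad = np.zeros((len(D), 1))
        c2, s2 = _smacof(D, np.hstack([_classical_scaling(D, 2), pad]))
        inits.append(c2)
    best_coords, best_stress = None, np.inf
    for init in inits:
        coords, stress = _smacof(D, init)
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    return EmbeddingResult(best_coords, _normalised_stress(D, best_stress),
                           labels)


def _smacof(D: np.ndarray, init: np.ndarray):
    coords, stress = smacof(
        D, metric=True, n_components=init.shape[1], init=init, n_init=1,
        max_iter=300, eps=1e-9, random_state=0, normalized_stress=False)
    return coords, float(stress)


def separation_accuracy(emb: EmbeddingResult, class_a: int, class_b: int,
                        n_trees: int = 500, seed: int = 0,
                        n_folds: int = 5) -> float:
    """Stratified cross-validated Random-Forest accuracy separating two
    classes in the embedding; symmetric in (class_a, class_b)."""
    if emb.labels is None:
        raise ValueError("embedding carries no labels")
    a, b = sorted((int(class_a), int(class_b)))
    mask = np.isin(emb.labels, [a, b])
    X, y = emb.coords[mask], emb.labels[mask]
    for c in (a, b):
        if (y == c).sum() < 10:
            raise ValueError(f"class {c} has fewer than 10 members")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return float(cross_val_score(rf, X, y, cv=cv).mean())
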